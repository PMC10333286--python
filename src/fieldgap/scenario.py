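"""Ideal-management counterfactuals: how much of the yield gap can close.

The driver forest predicts yield gap from management, weather and soil.
Overriding the management columns (sowing date, irrigation count) with
their PDP-optimal values and re-predicting gives a counterfactual yield
gap YG' per field. Because yield potential Yp is fixed within a year,
YG = Yp - Ymean implies that a reduction in predicted gap is exactly a
gain in yield:

    gain = YG_baseline - YG',

where the baseline is the model's own prediction on the unmodified table
(so that a no-op override yields exactly zero gain). The headline number
is the closure percent, 100 * mean gain / mean observed yield gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .drivers import DRIVER_PREDICTORS, RESPONSE, partial_dependence, optimal_management, _design

__all__ = ["ScenarioResult", "simulate_ideal", "run_scenarios"]

_MANAGEMENT = ("dos", "irrigations")


@dataclass
class ScenarioResult:
    """Per-field and mean yield gains under one management override."""

    label: str
    overrides: dict
    counterfactual_yg: np.ndarray
    gain: np.ndarray  # per-field yield gain kg/ha
    mean_gain: float
    closure_percent: float
    table: pd.DataFrame = dc_field(default=None, repr=False)


def simulate_ideal(
    model,
    table: pd.DataFrame,
    overrides: dict,
    label: str = "scenario",
    clip_to_support: bool = True,
) -> ScenarioResult:
    """Predict counterfactual yield gaps under partial management overrides.

    ``overrides`` maps a subset of {"dos", "irrigations"} to the value
    every field is moved to. Values outside the training support are
    clipped to it by default (forests extrapolate poorly); with
    ``clip_to_support=False`` they are rejected instead.
    """
    bad = set(overrides) - set(_MANAGEMENT)
    if bad:
        raise ValueError(f"overrides may touch only {_MANAGEMENT}, got {sorted(bad)}")
    predictors = tuple(getattr(model, "_driver_predictors", DRIVER_PREDICTORS))
    X = _design(table, predictors)
    baseline = model.predict(X)
    support = getattr(model, "_driver_support", None)
    Xc = X.copy()
    applied = {}
    for name, value in overrides.items():
        j = predictors.index(name)
        # training support, not the (possibly degenerate) evaluation table's
        lo, hi = support[name] if support else (X[:, j].min(), X[:, j].max())
        if not lo <= value <= hi:
            if not clip_to_support:
                raise ValueError(
                    f"override {name}={value} outside training support [{lo}, {hi}]"
                )
            value = float(np.clip(value, lo, hi))
        applied[name] = value
        Xc[:, j] = value
    counterfactual = model.predict(Xc)
    gain = baseline - counterfactual
    observed_gap = table[RESPONSE].to_numpy(dtype=float)
    mean_gap = observed_gap.mean()
    closure = 100.0 * gain.mean() / mean_gap if mean_gap != 0 else np.nan
    out = pd.DataFrame(
        {
            "field_id": table["field_id"].to_numpy()
            if "field_id" in table
            else np.arange(len(table)),
            "year": table["year"].to_numpy() if "year" in table else 0,
            "baseline_yg_pred": baseline,
            "counterfactual_yg": counterfactual,
            "gain_kgha": gain,
        }
    )
    return ScenarioResult(
        label=label,
        overrides=applied,
        counterfactual_yg=counterfactual,
        gain=gain,
        mean_gain=float(gain.mean()),
        closure_percent=float(closure),
        table=out,
    )


def run_scenarios(model, table: pd.DataFrame, dos_star=None, irrig_star=None) -> dict:
    """Run the three ideal-management scenarios with PDP-derived optima.

    Returns ``{"ideal_dos": ..., "ideal_irrig": ..., "ideal_both": ...}``;
    the comparison table mirroring the scenario figure is attached as
    ``results["summary"]``. Optima are taken from the DOS and irrigation
    partial-dependence curves unless passed explicitly.
    """
    if dos_star is None or irrig_star is None:
        pdp_dos = partial_dependence(model, table, "dos")
        pdp_irrig = partial_dependence(model, table, "irrigations")
        auto_dos, auto_irrig = optimal_management(pdp_dos, pdp_irrig)
        dos_star = auto_dos if dos_star is None else dos_star
        irrig_star = auto_irrig if irrig_star is None else irrig_star
    results = {
        "ideal_dos": simulate_ideal(model, table, {"dos": dos_star}, label="ideal_dos"),
        "ideal_irrig": simulate_ideal(
            model, table, {"irrigations": irrig_star}, label="ideal_irrig"
        ),
        "ideal_both": simulate_ideal(
            model,
            table,
            {"dos": dos_star, "irrigations": irrig_star},
            label="ideal_both",
        ),
    }
    results["summary"] = pd.DataFrame(
        [
            {
                "scenario": key,
                "mean_gain_kgha": res.mean_gain,
                "closure_percent": res.closure_percent,
                **{f"override_{k}": v for k, v in res.overrides.items()},
            }
            for key, res in results.items()
        ]
    )
    return results
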