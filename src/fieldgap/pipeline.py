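"""Stage orchestration: the whole analysis as reproducible, resumable commands.

``run(command, ...)`` executes one named stage (or ``"all"``) against an
output directory that doubles as the exchange format between stages —
every stage reads its inputs from files the previous stage wrote, so the
chain can be resumed, inspected or re-run piecewise. Commands, in
pipeline order:

    simulate    generate the synthetic landscape (scenes, polygons, tables)
    fit         per-year GCVI features + two-step yield models
    map-yields  per-pixel yield rasters + per-field satellite yields
    gaps        yield potential, per-field yield gaps, per-year summary
    persistence decile table + anomaly persistence percent
    drivers     driver forest, %IncMSE importance, PDP curves
    scenario    ideal-management counterfactuals
    all         everything above, in order

Every numeric output is reproducible from the config + seed alone; a
run-manifest (config hash, seed, package versions) is written alongside.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import pickle
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .drivers import (
    DRIVER_PREDICTORS,
    fit_driver_rf,
    partial_dependence,
    variable_importance,
)
from .geodata import extract_means, read_geojson, write_geojson
from .persistence import YieldPanel, assign_deciles, decile_distributions, persistence_percent
from .preprocess import GCVIStack, compute_gcvi
from .scenario import run_scenarios
from .synth import SyntheticConfig, generate_landscape
from .yieldgap import compute_yield_gaps, summarize_gaps, yield_potential
from .yield_model import YieldRaster, cross_validate, predict_pixel_yields, train_yield_model

__all__ = ["PipelineConfig", "run", "COMMANDS"]

log = logging.getLogger("fieldgap")

COMMANDS = (
    "simulate",
    "fit",
    "map-yields",
    "gaps",
    "persistence",
    "drivers",
    "scenario",
    "all",
)


@dataclasses.dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from a YAML mapping."""

    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    n_trees: int = 500
    cv_repeats: int = 5
    train_fraction: float = 0.7
    percentile: float = 95.0
    base_year: int = 0
    n_permutations: int = 5
    figures: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        synth_d = d.pop("synthetic", {})
        known_s = {f.name for f in dataclasses.fields(SyntheticConfig)}
        bad = set(synth_d) - known_s
        if bad:
            raise ValueError(f"unknown synthetic config fields: {sorted(bad)}")
        known_p = {f.name for f in dataclasses.fields(cls)} - {"synthetic"}
        bad = set(d) - known_p
        if bad:
            raise ValueError(f"unknown pipeline config fields: {sorted(bad)}")
        cfg = cls(synthetic=SyntheticConfig(**synth_d), **d)
        cfg.synthetic.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "PipelineConfig":
        out = dataclasses.replace(self, seed=seed)
        out.synthetic = dataclasses.replace(self.synthetic, seed=seed)
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["scene_dates_per_year"] = list(
            d["synthetic"]["scene_dates_per_year"]
        )
        d["synthetic"]["grid_shape"] = list(d["synthetic"]["grid_shape"])
        return d


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing input {path} — run the '{produced_by}' stage first"
        )
    return path


def _write_manifest(out: Path, cfg: PipelineConfig) -> None:
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    import sklearn  # local import: version stamp only

    fio.write_manifest(
        out / "run_manifest.yml",
        {
            "config": cfg.to_dict(),
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": cfg.seed,
            "versions": {"numpy": np.__version__, "sklearn": sklearn.__version__},
        },
    )


def _scene_path(out: Path, year: int, date) -> Path:
    return out / "scenes" / f"year{year}_day{int(date):03d}.tif"


def _stage_simulate(out: Path, cfg: PipelineConfig) -> None:
    scenes, fields, mask, truth = generate_landscape(cfg.synthetic)
    (out / "scenes").mkdir(exist_ok=True)
    manifest = {}
    for year, year_scenes in scenes.items():
        for sc in year_scenes:
            p = _scene_path(out, year, sc.date)
            fio.write_scene(p, sc)
            manifest.setdefault(year, {})[int(sc.date)] = p.name
    fio.write_manifest(out / "scenes" / "manifest.yml", manifest)
    fio.write_raster(out / "cropland_mask.tif", mask.astype(np.uint8), truth.georef)
    write_geojson(
        out / "fields.geojson",
        [f.polygon for f in fields],
        [{"field_id": f.field_id, **f.covariates} for f in fields],
    )
    truth.table().to_csv(out / "field_table.csv", index=False)
    truth.years.to_csv(out / "years.csv", index=False)
    fio.write_manifest(
        out / "truth.yml",
        {"synthetic": cfg.to_dict()["synthetic"], "yp_true": truth.years["yp_true"].tolist()},
    )


def _load_stacks(out: Path) -> dict[int, GCVIStack]:
    manifest = fio.read_manifest(_require(out / "scenes" / "manifest.yml", "simulate"))
    stacks = {}
    for year, by_date in manifest.items():
        dates = sorted(by_date)
        layers, georef = [], None
        for d in dates:
            sc = fio.read_scene(out / "scenes" / by_date[d])
            georef = sc.georef
            layers.append(compute_gcvi(sc))
        stacks[int(year)] = GCVIStack(dates=dates, layers=np.stack(layers), georef=georef)
    return stacks


def _stage_fit(out: Path, cfg: PipelineConfig) -> None:
    stacks = _load_stacks(out)
    polys, props = read_geojson(_require(out / "fields.geojson", "simulate"))
    table = pd.read_csv(_require(out / "field_table.csv", "simulate"))
    (out / "models").mkdir(exist_ok=True)
    feat_rows, cv_rows, meta = [], [], {}
    for year, stack in sorted(stacks.items()):
        feats = np.column_stack(
            [extract_means(layer, stack.georef, polys) for layer in stack.layers]
        )
        for p, row in zip(props, feats):
            feat_rows.append(
                {"field_id": p["field_id"], "year": year}
                | {f"gcvi_{d}": v for d, v in zip(stack.dates, row)}
            )
        yields = (
            table[table["year"] == year]
            .set_index("field_id")
            .loc[[p["field_id"] for p in props], "yield_kgha"]
            .to_numpy()
        )
        model = train_yield_model(
            pd.DataFrame(feats, columns=stack.dates),
            yields,
            year=year,
            seed=cfg.seed,
            n_trees=cfg.n_trees,
        )
        cv = cross_validate(
            feats, yields, k=cv_repeats(cfg), train_fraction=cfg.train_fraction,
            seed=cfg.seed, n_trees=cfg.n_trees,
        )
        cv.insert(0, "year", year)
        cv_rows.append(cv)
        with open(out / "models" / f"year{year}.pkl", "wb") as fh:
            pickle.dump(model, fh)
        meta[year] = {
            "beta0": model.beta0,
            "beta1": model.beta1,
            "training_r2": model.training_r2,
            "training_rmse": model.training_rmse,
            "pbias_raw": model.pbias_raw,
            "dates": [int(d) for d in model.dates],
        }
    pd.DataFrame(feat_rows).to_csv(out / "field_features.csv", index=False)
    pd.concat(cv_rows, ignore_index=True).to_csv(out / "cross_validation.csv", index=False)
    fio.write_manifest(out / "models" / "metrics.yml", meta)


def cv_repeats(cfg: PipelineConfig) -> int:
    return cfg.cv_repeats


def _stage_map_yields(out: Path, cfg: PipelineConfig) -> None:
    stacks = _load_stacks(out)
    mask, georef, _ = fio.read_raster(_require(out / "cropland_mask.tif", "simulate"))
    polys, props = read_geojson(out / "fields.geojson")
    (out / "yields").mkdir(exist_ok=True)
    rows = []
    for year, stack in sorted(stacks.items()):
        model_p = _require(out / "models" / f"year{year}.pkl", "fit")
        with open(model_p, "rb") as fh:
            model = pickle.load(fh)
        raster = predict_pixel_yields(model, stack, mask.astype(bool))
        fio.write_raster(
            out / "yields" / f"year{year}.tif", raster.values, georef, year=int(year)
        )
        ymean = extract_means(raster.values, georef, polys)
        rows += [
            {"field_id": p["field_id"], "year": year, "ymean": v}
            for p, v in zip(props, ymean)
        ]
    pd.DataFrame(rows).to_csv(out / "field_ymean.csv", index=False)


def _stage_gaps(out: Path, cfg: PipelineConfig) -> None:
    ymean = pd.read_csv(_require(out / "field_ymean.csv", "map-yields"))
    mask, _, _ = fio.read_raster(_require(out / "cropland_mask.tif", "simulate"))
    tables = []
    for year, g in ymean.groupby("year"):
        raster_p = _require(out / "yields" / f"year{year}.tif", "map-yields")
        values, georef, _ = fio.read_raster(raster_p)
        raster = YieldRaster(year=year, values=values, mask=mask.astype(bool), georef=georef)
        yp = yield_potential(raster, cfg.percentile)
        tables.append(
            compute_yield_gaps(g["ymean"].to_numpy(), yp, year, g["field_id"].to_numpy())
        )
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "yield_gaps.csv", index=False)
    summarize_gaps(table).to_csv(out / "yield_gap_summary.csv", index=False)


def _stage_persistence(out: Path, cfg: PipelineConfig) -> None:
    ymean = pd.read_csv(_require(out / "field_ymean.csv", "map-yields"))
    panel = YieldPanel(
        yields=ymean.pivot(index="field_id", columns="year", values="ymean"),
        base_year=cfg.base_year,
    )
    deciles = assign_deciles(panel.yields[panel.base_year].to_numpy())
    table = decile_distributions(panel, deciles)
    pct = persistence_percent(panel, deciles)
    table.to_csv(out / "decile_table.csv", index=False)
    pd.DataFrame([{"base_year": cfg.base_year, "persistence_percent": pct}]).to_csv(
        out / "persistence.csv", index=False
    )
    if cfg.figures:
        from .plots import plot_decile_boxes

        plot_decile_boxes(table, out / "decile_boxplot.png")


def _driver_table(out: Path) -> pd.DataFrame:
    gaps = pd.read_csv(_require(out / "yield_gaps.csv", "gaps"))
    field_table = pd.read_csv(_require(out / "field_table.csv", "simulate"))
    covars = ["field_id", "year"] + list(DRIVER_PREDICTORS)
    return gaps.merge(field_table[covars], on=["field_id", "year"])


def _fit_drivers(out: Path, cfg: PipelineConfig):
    table = _driver_table(out)
    return fit_driver_rf(table, seed=cfg.seed, n_trees=cfg.n_trees), table


def _stage_drivers(out: Path, cfg: PipelineConfig) -> None:
    model, table = _fit_drivers(out, cfg)
    table.to_csv(out / "driver_table.csv", index=False)
    imp = variable_importance(model, n_permutations=cfg.n_permutations, seed=cfg.seed)
    imp.to_csv(out / "importance.csv", index=False)
    curves = [partial_dependence(model, table, p) for p in ("dos", "irrigations")]
    pd.concat(
        [
            pd.DataFrame({"predictor": c.predictor, "grid": c.grid, "yg": c.values})
            for c in curves
        ],
        ignore_index=True,
    ).to_csv(out / "pdp_curves.csv", index=False)
    if cfg.figures:
        from .plots import plot_importance, plot_pdp

        plot_importance(imp, out / "importance.png")
        plot_pdp(curves, out / "pdp.png")


def _stage_scenario(out: Path, cfg: PipelineConfig) -> None:
    _require(out / "driver_table.csv", "drivers")
    model, table = _fit_drivers(out, cfg)  # deterministic refit from the same table
    results = run_scenarios(model, table)
    results["summary"].to_csv(out / "scenario_summary.csv", index=False)
    for key in ("ideal_dos", "ideal_irrig", "ideal_both"):
        results[key].table.to_csv(out / f"scenario_{key}.csv", index=False)
    if cfg.figures:
        from .plots import plot_scenarios

        plot_scenarios(results["summary"], out / "scenarios.png")


_STAGES = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "map-yields": _stage_map_yields,
    "gaps": _stage_gaps,
    "persistence": _stage_persistence,
    "drivers": _stage_drivers,
    "scenario": _stage_scenario,
}


def run(command: str, config=None, out_dir="fieldgap_run", seed: int | None = None) -> Path:
    """Execute one pipeline command (or ``"all"``) into ``out_dir``.

    ``config`` may be a :class:`PipelineConfig`, a mapping, or a path to a
    YAML file; ``seed`` overrides the config's seed everywhere (including
    the synthetic generator). Returns the output directory. On stage
    failure the partial outputs are retained next to a ``FAILED`` marker.
    """
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {COMMANDS}")
    if isinstance(config, PipelineConfig):
        cfg = config
    elif isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    else:
        cfg = PipelineConfig.from_dict(config or {})
    if seed is not None:
        cfg = cfg.with_seed(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_manifest(out, cfg)
    stages = list(_STAGES) if command == "all" else [command]
    for name in stages:
        t0 = time.perf_counter()
        try:
            _STAGES[name](out, cfg)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise
        log.info("stage %-11s done in %.1f s", name, time.perf_counter() - t0)
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return out
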