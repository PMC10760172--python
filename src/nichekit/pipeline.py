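"""Configuration-driven orchestration of the full niche-divergence analysis.

A run goes: simulate (or ingest) -> checklist filter -> spatial thinning ->
group balancing -> target-group background -> environmental extraction ->
VIF variable selection -> maxent fit + replicated validation per group ->
pairwise overlap statistics -> identity and blob range-breaking tests ->
JSON report. Every stage draws its randomness from a seed derived
deterministically from the master seed and the stage name (CRC-32 of the
name XORed into the master seed, mod 2^31), so adding a stage never
perturbs the randomness of earlier ones and a rerun with the same config
and master seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import synthetic
from .env_select import extract_env, select_variables
from .grids import (CATEGORICAL, CONTINUOUS, GridSpec, Layer, RasterStack,
                    read_stack, write_ascii_grid, write_stack)
from .maxent import Maxent, crossvalidate, response_curve
from .occurrences import (FilterConfig, ThinConfig, balance_groups,
                          filter_records, target_group_background, thin_spatial)
from .overlap import overlap_from_suitability
from .similarity import TestConfig, blob_range_break_test, identity_test
from .synthetic import (LayerSpec, MetadataConfig, NicheScenario,
                        attach_checklist_metadata, gaussian_niche_suitability,
                        make_scenario, sample_occurrences)

logger = logging.getLogger("nichekit")

OCCURRENCE_SCHEMA = ["id", "longitude", "latitude", "group", "protocol",
                     "duration_minutes", "effort_distance_km", "start_time",
                     "n_observers", "complete", "date"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (master XOR crc32(stage)) mod 2^31."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# I/O

def read_occurrences(path: str | Path, require_metadata: bool = True) -> pd.DataFrame:
    """Read and validate an occurrence CSV.

    Raises on missing columns, out-of-range coordinates, or duplicate ids,
    naming the offending rows (1-based data line numbers).
    """
    df = pd.read_csv(path, dtype={"id": str})
    required = OCCURRENCE_SCHEMA if require_metadata else OCCURRENCE_SCHEMA[:4]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_lon = ~df["longitude"].between(-180, 180)
    bad_lat = ~df["latitude"].between(-90, 90)
    bad = bad_lon | bad_lat | df["longitude"].isna() | df["latitude"].isna()
    if bad.any():
        lines = (np.where(bad)[0] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: malformed coordinate rows at lines {lines[:10]}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate ids {dupes[:10]}")
    return df


def write_occurrences(path: str | Path, table: pd.DataFrame) -> None:
    cols = [c for c in OCCURRENCE_SCHEMA if c in table.columns]
    table[cols].to_csv(path, index=False)


def _resample_to(values: np.ndarray, src: GridSpec, ref: GridSpec,
                 order: int) -> np.ndarray:
    """Resample a band onto the reference grid (order 0 = nearest, 1 = bilinear)."""
    xs = ref.x_centers()
    ys = ref.y_centers()
    cols = (xs - src.origin_x) / src.cell_size - 0.5
    rows = src.n_rows - 0.5 - (ys - src.origin_y) / src.cell_size
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(values, [rr, cc], order=order, mode="nearest")


def read_rasters(paths: list[str | Path], kinds: dict[str, str] | None = None,
                 crs_label: str = "planar_km", resample: bool = False) -> RasterStack:
    """Read ESRI ASCII grids into a stack; optionally resample misaligned
    rasters onto the first raster's grid (nearest for categorical layers,
    bilinear for continuous)."""
    if not resample:
        return read_stack(paths, kinds, crs_label)
    kinds = kinds or {}
    from .grids import read_ascii_grid

    layers: list[Layer] = []
    ref: GridSpec | None = None
    mask: np.ndarray | None = None
    for path in paths:
        path = Path(path)
        values, g, m = read_ascii_grid(path, crs_label=crs_label)
        kind = kinds.get(path.stem, CONTINUOUS)
        if ref is None:
            ref, mask = g, m
        elif (g.n_rows, g.n_cols, g.origin_x, g.origin_y, g.cell_size) != (
                ref.n_rows, ref.n_cols, ref.origin_x, ref.origin_y, ref.cell_size):
            order = 0 if kind == CATEGORICAL else 1
            values = _resample_to(values, g, ref, order)
            m = _resample_to(m.astype(float), g, ref, 0) > 0.5
        if values.shape == ref.shape:
            mask = mask | m
        layers.append(Layer(path.stem, kind, values))
    return RasterStack(grid=ref, layers=layers, nodata_mask=mask)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SyntheticBlock:
    """Synthetic study-system settings (used when no input paths are given)."""

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1.0          # km (planar)
    layers: list[dict] = field(default_factory=lambda: [
        {"name": "env1", "kind": "continuous", "autocorr_length": 4.0},
        {"name": "env2", "kind": "continuous", "autocorr_length": 4.0},
    ])
    correlation: list[list[float]] | None = None
    scenario_kind: str = "three_group"
    separation: float = 4.0
    sigma: float = 1.0
    n_per_group_raw: int = 6000     # occurrences sampled before filtering
    n_all_species: int = 15000      # pool emulating the all-species dataset
    fail_fraction: float = 0.1      # planted metadata-violation rate


@dataclass
class PipelineConfig:
    """Everything a full run needs; exactly one of synthetic/input paths."""

    synthetic: SyntheticBlock | None = None
    occurrence_csv: str | None = None
    background_csv: str | None = None
    raster_paths: list[str] | None = None
    raster_kinds: dict[str, str] = field(default_factory=dict)
    crs_label: str = "planar_km"
    filter: FilterConfig | None = None
    thin_min_distance: float = 0.5   # km
    thin_repeats: int = 3
    n_per_group: int = 1500
    n_background: int = 10000
    vif_method: str = "both"
    vif_threshold: float = 10.0
    r_threshold: float = 0.9
    feature_classes: tuple[str, ...] = ("linear", "quadratic")
    beta: float = 1.0
    n_replicates: int = 10
    test_fraction: float = 0.2
    n_iter: int = 100
    alpha: float = 0.05
    outdir: str = "nichekit_run"
    master_seed: int = 0

    def __post_init__(self) -> None:
        has_synth = self.synthetic is not None
        has_paths = self.occurrence_csv is not None and self.raster_paths is not None
        if has_synth == has_paths:
            raise ValueError("config needs exactly one of a synthetic block or "
                             "input paths (occurrence_csv + raster_paths)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update(overrides)
        if "synthetic" in payload and payload["synthetic"] is not None:
            payload["synthetic"] = SyntheticBlock(**payload["synthetic"])
        if "filter" in payload and payload["filter"] is not None:
            f = dict(payload["filter"])
            for key in ("allowed_protocols", "months"):
                if key in f:
                    f[key] = frozenset(f[key])
            for key in ("time_window", "year_range", "bbox"):
                if key in f:
                    f[key] = tuple(f[key])
            payload["filter"] = FilterConfig(**f)
        if "feature_classes" in payload:
            payload["feature_classes"] = tuple(payload["feature_classes"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# the run

def _simulate_inputs(cfg: PipelineConfig, outdir: Path):
    synth = cfg.synthetic
    grid = GridSpec(n_rows=synth.n_rows, n_cols=synth.n_cols,
                    cell_size=synth.cell_size, crs_label=cfg.crs_label)
    layer_specs = [LayerSpec(**spec) for spec in synth.layers]
    corr = None if synth.correlation is None else np.asarray(synth.correlation)
    stack = synthetic.generate_landscape(
        grid, layer_specs, corr, seed=stage_seed(cfg.master_seed, "landscape"))
    categorical = {s.name: s.n_classes for s in layer_specs
                   if s.kind == CATEGORICAL}
    scenario = make_scenario(synth.scenario_kind, synth.separation,
                             layer_names=tuple(
                                 s.name for s in layer_specs if s.kind == CONTINUOUS)[:2],
                             sigma=synth.sigma,
                             categorical_classes=categorical or None)
    tables = []
    for k, group in enumerate(scenario.groups):
        suit = gaussian_niche_suitability(scenario, group, stack)
        occ = sample_occurrences(suit, synth.n_per_group_raw, group=group,
                                 seed=stage_seed(cfg.master_seed, f"occ_{group}"))
        occ, _ = attach_checklist_metadata(
            occ, fail_fraction=synth.fail_fraction,
            seed=stage_seed(cfg.master_seed, f"meta_{group}"))
        tables.append(occ)
    occurrences = pd.concat(tables, ignore_index=True)

    # the all-species pool mirrors survey effort: uniform over valid cells here
    uniform = gaussian_niche_suitability(
        NicheScenario(groups=["pool"],
                      optima={"pool": {layer.name: 0.0 for layer in stack.layers
                                       if layer.kind == CONTINUOUS}},
                      breadths={"pool": {layer.name: 1e6 for layer in stack.layers
                                         if layer.kind == CONTINUOUS}},
                      class_weights={"pool": {name: {c: 1.0 for c in range(n)}
                                              for name, n in categorical.items()}}),
        "pool", stack)
    pool = sample_occurrences(uniform, synth.n_all_species, group="all_species",
                              seed=stage_seed(cfg.master_seed, "all_species"))

    write_stack(outdir / "rasters", stack)
    (outdir / "scenario.yaml").write_text(scenario.to_yaml())
    write_occurrences(outdir / "occurrences.csv", occurrences)
    return stack, occurrences, pool, scenario


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole analysis; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    report: dict = {"config": _config_echo(config), "stages": {}}
    try:
        _run_stages(config, outdir, report)
        report["status"] = "ok"
    except Exception as exc:  # partial outputs retained with a failure marker
        report["status"] = "failed"
        report["failure"] = {"stage": report.get("current_stage", "unknown"),
                             "error": str(exc)}
        _write_report(outdir, report)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    report.pop("current_stage", None)
    _write_report(outdir, report)
    return report


def _write_report(outdir: Path, report: dict) -> None:
    report.pop("current_stage", None)
    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n")


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    if echo.get("filter"):
        for key in ("allowed_protocols", "months"):
            echo["filter"][key] = sorted(echo["filter"][key])
        echo["filter"]["id_blacklist"] = sorted(echo["filter"]["id_blacklist"])
    echo["feature_classes"] = list(echo["feature_classes"])
    return echo


def _run_stages(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    report["current_stage"] = "ingest"
    if cfg.synthetic is not None:
        stack, occurrences, pool, _ = _simulate_inputs(cfg, outdir)
        extent = (stack.grid.origin_x,
                  stack.grid.origin_x + stack.grid.n_cols * stack.grid.cell_size,
                  stack.grid.origin_y,
                  stack.grid.origin_y + stack.grid.n_rows * stack.grid.cell_size)
        filt = cfg.filter or FilterConfig(bbox=extent, months=frozenset(range(1, 13)))
        metric = "euclidean" if not stack.grid.is_geographic else "haversine"
    else:
        occurrences = read_occurrences(cfg.occurrence_csv)
        stack = read_rasters(cfg.raster_paths, cfg.raster_kinds, cfg.crs_label,
                             resample=True)
        pool = read_occurrences(cfg.background_csv, require_metadata=False) \
            if cfg.background_csv else occurrences
        filt = cfg.filter or FilterConfig()
        metric = "haversine" if stack.grid.is_geographic else "euclidean"
    groups = sorted(occurrences["group"].unique())
    report["stages"]["ingest"] = {"n_records": len(occurrences), "groups": groups}
    logger.info("ingest: %d records, groups %s", len(occurrences), groups)

    report["current_stage"] = "filter"
    filtered, rejections = filter_records(occurrences, filt)
    report["stages"]["filter"] = {"n_in": len(occurrences), "n_kept": len(filtered),
                                  "rejections": rejections}
    logger.info("filter: kept %d of %d", len(filtered), len(occurrences))

    report["current_stage"] = "thin"
    thinned = {}
    for i, group in enumerate(groups):
        sub = filtered[filtered["group"] == group]
        thinned[group] = thin_spatial(sub, ThinConfig(
            min_distance=cfg.thin_min_distance, n_repeats=cfg.thin_repeats,
            seed=stage_seed(cfg.master_seed, f"thin_{group}"), metric=metric))
    report["stages"]["thin"] = {g: len(t) for g, t in thinned.items()}

    report["current_stage"] = "balance"
    balanced = balance_groups(thinned, cfg.n_per_group,
                              seed=stage_seed(cfg.master_seed, "balance"))
    for group, df in balanced.items():
        write_occurrences(outdir / f"occ_{group}.csv", df)
    report["stages"]["balance"] = {g: len(t) for g, t in balanced.items()}

    report["current_stage"] = "background"
    background = target_group_background(
        pool, cfg.n_background, seed=stage_seed(cfg.master_seed, "background"))
    background.insert(0, "id", [f"bg_{i:06d}" for i in range(len(background))])
    report["stages"]["background"] = {"n": len(background)}

    report["current_stage"] = "select"
    pooled_pts = pd.concat(list(balanced.values()) + [background], ignore_index=True)
    env_all = extract_env(stack, pooled_pts)
    if len(env_all.continuous) >= 2:
        vif_report = select_variables(env_all, cfg.vif_method,
                                      cfg.vif_threshold, cfg.r_threshold)
        variables = vif_report.selected
        report["stages"]["select"] = vif_report.to_dict()
    else:
        variables = list(env_all.values.columns)
        report["stages"]["select"] = {"method": "none", "retained": variables}

    report["current_stage"] = "enm"
    kinds = {v: stack.kinds[v] for v in variables}
    env_bg = extract_env(stack, background).values[variables]
    fitted = {}
    enm_report = {}
    for group, df in balanced.items():
        env_p = extract_env(stack, df).values[variables]
        model = Maxent(env_p, env_bg, kinds, feature_classes=cfg.feature_classes)
        res = model.fit(beta=cfg.beta)
        cv = crossvalidate(env_p, env_bg, kinds, n_replicates=cfg.n_replicates,
                           test_fraction=cfg.test_fraction, beta=cfg.beta,
                           seed=stage_seed(cfg.master_seed, f"cv_{group}"),
                           feature_classes=cfg.feature_classes)
        imp = res.variable_importance(
            seed=stage_seed(cfg.master_seed, f"imp_{group}"))
        suit = res.predict_grid(stack, output="raw")
        # cloglog for mapping; raw is what the overlap statistics consume
        write_ascii_grid(outdir / f"suitability_{group}.asc",
                         res.predict_grid(stack, output="cloglog").values,
                         stack.grid, stack.nodata_mask)
        write_ascii_grid(outdir / f"suitability_{group}_raw.asc",
                         suit.values, stack.grid, stack.nodata_mask)
        fitted[group] = (res, suit)
        enm_report[group] = {
            "auc_mean": cv.mean, "auc_sd": cv.sd, "aucs": cv.aucs,
            "converged": bool(res.converged),
            "percent_contribution": {k: float(v) for k, v in
                                     imp.percent_contribution.items()},
            "permutation_importance": {k: float(v) for k, v in
                                       imp.permutation_importance.items()},
        }
        logger.info("enm %s: AUC %.3f +/- %.3f", group, cv.mean, cv.sd)
    report["stages"]["enm"] = enm_report

    report["current_stage"] = "overlap"
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    overlap_report = {}
    for a, b in pairs:
        ov = overlap_from_suitability(fitted[a][1], fitted[b][1])
        overlap_report[f"{a}|{b}"] = ov.to_dict()
    report["stages"]["overlap"] = overlap_report

    report["current_stage"] = "tests"
    tests_report = {}
    for a, b in pairs:
        tcfg = TestConfig(n_iter=cfg.n_iter, alpha=cfg.alpha,
                          seed=stage_seed(cfg.master_seed, f"test_{a}_{b}"),
                          beta=cfg.beta, feature_classes=cfg.feature_classes,
                          metric=metric)
        ident = identity_test(balanced[a], balanced[b], stack, background, tcfg)
        blob = blob_range_break_test(balanced[a], balanced[b], stack,
                                     background, tcfg)
        tests_report[f"{a}|{b}"] = {"identity": ident.to_dict(),
                                    "blob": blob.to_dict()}
        logger.info("tests %s|%s: identity p_lower D=%.4f, blob p_lower D=%.4f",
                    a, b, ident.p_lower["D"], blob.p_lower["D"])
    report["stages"]["tests"] = tests_report
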