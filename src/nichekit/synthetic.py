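"""Synthetic landscapes, niches, occurrences, and checklist metadata.

This module generates study systems with the statistical structure the
analysis assumes — spatially autocorrelated environmental layers with
controllable inter-layer correlation, Gaussian niche-response surfaces for
two or three taxonomic groups, occurrence points sampled in proportion to
suitability, and eBird-style checklist metadata with known planted
violations of each record-quality criterion — so that every downstream
stage can be exercised and validated without any data download.

Continuous layers are standardized Gaussian random fields (kernel-smoothed
white noise), so niche optima are expressed in layer standard-deviation
units. Inter-layer correlation is induced by linearly mixing shared latent
fields; the achieved correlations approach the target matrix but are
approximate by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .grids import CATEGORICAL, CONTINUOUS, GridSpec, Layer, RasterStack, SuitabilityGrid

__all__ = [
    "LayerSpec",
    "NicheScenario",
    "MetadataConfig",
    "generate_landscape",
    "gaussian_niche_suitability",
    "sample_occurrences",
    "attach_checklist_metadata",
    "make_scenario",
]


@dataclass(frozen=True)
class LayerSpec:
    """Recipe for one synthetic environmental layer.

    ``autocorr_length`` is the Gaussian smoothing bandwidth in cells; the
    effective spatial correlation length of the field is of the same order.
    ``mix_weights``, when given, are this layer's loadings on the shared
    latent fields (an alternative to passing a correlation matrix).
    """

    name: str
    kind: str = CONTINUOUS
    autocorr_length: float = 5.0
    n_classes: int | None = None
    mix_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.autocorr_length < 0:
            raise ValueError("autocorr_length must be nonnegative")
        if self.kind == CATEGORICAL and (self.n_classes is None or self.n_classes < 2):
            raise ValueError("categorical layers need n_classes >= 2")


@dataclass
class NicheScenario:
    """Ground-truth Gaussian niche parameters for each group.

    ``optima[group][variable]`` and ``breadths[group][variable]`` give the
    response optimum and breadth (both in layer units) for each continuous
    variable; ``class_weights[group][layer][code]`` gives the multiplicative
    weight of each categorical class, in [0, 1].
    """

    groups: list[str]
    optima: dict[str, dict[str, float]]
    breadths: dict[str, dict[str, float]]
    class_weights: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group in self.groups:
            for var, sigma in self.breadths.get(group, {}).items():
                if sigma <= 0:
                    raise ValueError(f"breadth for {group}/{var} must be positive")
            for layer, weights in self.class_weights.get(group, {}).items():
                for code, w in weights.items():
                    if not 0 <= w <= 1:
                        raise ValueError(
                            f"class weight for {group}/{layer}/class {code} must be in [0,1]")

    def to_yaml(self) -> str:
        payload = {
            "groups": list(self.groups),
            "optima": {g: dict(v) for g, v in self.optima.items()},
            "breadths": {g: dict(v) for g, v in self.breadths.items()},
            "class_weights": {
                g: {layer: {int(c): float(w) for c, w in weights.items()}
                    for layer, weights in layers.items()}
                for g, layers in self.class_weights.items()
            },
        }
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "NicheScenario":
        payload = yaml.safe_load(text)
        return cls(
            groups=list(payload["groups"]),
            optima=payload["optima"],
            breadths=payload["breadths"],
            class_weights={
                g: {layer: {int(c): float(w) for c, w in weights.items()}
                    for layer, weights in layers.items()}
                for g, layers in payload.get("class_weights", {}).items()
            },
        )


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int],
                       length: float) -> np.ndarray:
    """White noise smoothed to the given length scale, standardized."""
    z = rng.standard_normal(shape)
    if length > 0:
        z = ndimage.gaussian_filter(z, sigma=length, mode="wrap")
    z = z - z.mean()
    sd = z.std()
    if sd > 0:
        z = z / sd
    return z


def _mixing_matrix(layers: list[LayerSpec],
                   correlation: np.ndarray | None) -> np.ndarray:
    k = len(layers)
    if correlation is None:
        if any(spec.mix_weights is not None for spec in layers):
            n_latent = max(len(spec.mix_weights or ()) for spec in layers)
            mix = np.zeros((k, n_latent))
            for i, spec in enumerate(layers):
                w = spec.mix_weights or tuple(1.0 if j == i else 0.0 for j in range(n_latent))
                mix[i, : len(w)] = w
            return mix
        return np.eye(k)
    corr = np.asarray(correlation, dtype=float)
    if corr.shape != (k, k):
        raise ValueError(f"correlation matrix must be {k}x{k}, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-8:
        raise ValueError(
            f"correlation matrix is not positive semi-definite (min eigenvalue {w.min():.3g})")
    return v @ np.diag(np.sqrt(np.clip(w, 0, None)))


def generate_landscape(spec: GridSpec, layers: list[LayerSpec],
                       correlation: np.ndarray | None = None,
                       seed: int = 0) -> RasterStack:
    """Generate a stack of correlated synthetic environmental layers.

    Each layer is driven by its own smoothed, standardized latent field;
    the fields are linearly mixed through a factor of the target correlation
    matrix, so pairwise correlations approach the requested values (the
    match tightens as the grid grows relative to the autocorrelation
    length). Categorical layers are produced by quantile-thresholding their
    mixed field into ``n_classes`` equal-area codes 0..n_classes-1.
    """
    if spec.n_cells == 0:
        raise ValueError("zero-area grid")
    if not layers:
        raise ValueError("at least one LayerSpec required")
    mix = _mixing_matrix(layers, correlation)
    rng = np.random.default_rng(seed)
    latents = np.stack([
        _smooth_unit_field(rng, spec.shape, layer.autocorr_length) for layer in layers
    ])
    out: list[Layer] = []
    for i, layer_spec in enumerate(layers):
        mixed = np.tensordot(mix[i, : latents.shape[0]], latents, axes=1)
        if layer_spec.kind == CATEGORICAL:
            edges = np.quantile(mixed, np.linspace(0, 1, layer_spec.n_classes + 1)[1:-1])
            codes = np.searchsorted(edges, mixed, side="right").astype(float)
            out.append(Layer(layer_spec.name, CATEGORICAL, codes))
        else:
            out.append(Layer(layer_spec.name, CONTINUOUS, mixed))
    return RasterStack(grid=spec, layers=out)


def gaussian_niche_suitability(scenario: NicheScenario, group: str,
                               stack: RasterStack) -> SuitabilityGrid:
    """Ground-truth suitability: a product of independent Gaussian responses.

    For each continuous layer v the factor is exp(-((e_v - mu)/sigma)^2 / 2);
    each categorical layer multiplies in its class weight.
    """
    if group not in scenario.groups:
        raise ValueError(f"unknown group {group!r}; scenario has {scenario.groups}")
    suit = np.ones(stack.grid.shape)
    mus = scenario.optima.get(group, {})
    sigmas = scenario.breadths.get(group, {})
    weights = scenario.class_weights.get(group, {})
    for layer in stack.layers:
        if layer.kind == CONTINUOUS:
            if layer.name not in mus or layer.name not in sigmas:
                raise ValueError(
                    f"scenario lacks (optimum, breadth) for group {group!r}, "
                    f"layer {layer.name!r}")
            z = (layer.values - mus[layer.name]) / sigmas[layer.name]
            suit *= np.exp(-0.5 * z * z)
        else:
            layer_weights = weights.get(layer.name)
            if layer_weights is None:
                raise ValueError(
                    f"scenario lacks class weights for group {group!r}, "
                    f"layer {layer.name!r}")
            codes = layer.values.astype(int)
            present = np.unique(codes[~stack.nodata_mask])
            missing = [c for c in present if c not in layer_weights]
            if missing:
                raise ValueError(
                    f"scenario lacks weights for classes {missing} of layer "
                    f"{layer.name!r} (group {group!r})")
            lookup = np.zeros(codes.max() + 1)
            for code, w in layer_weights.items():
                if code <= codes.max():
                    lookup[code] = w
            suit *= lookup[codes]
    suit[stack.nodata_mask] = 0.0
    return SuitabilityGrid(grid=stack.grid, values=suit, nodata_mask=stack.nodata_mask)


OCCURRENCE_COLUMNS = ["id", "longitude", "latitude", "group"]


def sample_occurrences(suit: SuitabilityGrid, n: int, group: str = "A",
                       jitter: str = "uniform", seed: int = 0) -> pd.DataFrame:
    """Draw n occurrence points multinomially over cells, weighted by suitability.

    ``jitter="uniform"`` places points uniformly within their cell;
    ``jitter="none"`` puts them at cell centers. Coordinate columns are
    named longitude/latitude regardless of whether the grid is geographic.
    """
    if jitter not in ("uniform", "none"):
        raise ValueError("jitter must be 'uniform' or 'none'")
    probs = np.where(suit.nodata_mask, 0.0, suit.values).ravel()
    total = probs.sum()
    if total <= 0:
        raise ValueError("all-zero suitability: nothing to sample from")
    probs = probs / total
    rng = np.random.default_rng(seed)
    cells = rng.choice(probs.size, size=n, p=probs)
    rows, cols = np.unravel_index(cells, suit.grid.shape)
    x, y = suit.grid.cell_center(rows, cols)
    if jitter == "uniform":
        half = suit.grid.cell_size / 2.0
        x = x + rng.uniform(-half, half, size=n)
        y = y + rng.uniform(-half, half, size=n)
    return pd.DataFrame({
        "id": [f"{group}_{i:06d}" for i in range(n)],
        "longitude": x,
        "latitude": y,
        "group": group,
    })


#: criterion keys match the rejection keys of occurrence_prep.filter_records
METADATA_CRITERIA = ("protocol", "duration", "distance", "time", "observers",
                     "complete", "month", "year")


@dataclass(frozen=True)
class MetadataConfig:
    """Distributions for clean and criterion-violating checklist metadata.

    Clean records satisfy the study's record-quality filters: Stationary or
    Traveling protocol, duration < 360 min, distance < 10 km, start time
    06:00-21:00, at most 10 observers, complete checklists, June-July of
    2010-2023. Violating records are drawn just outside each bound.
    """

    protocols: tuple[str, ...] = ("Stationary", "Traveling")
    bad_protocol: str = "Incidental"
    duration_range: tuple[float, float] = (5.0, 300.0)
    bad_duration_range: tuple[float, float] = (360.0, 720.0)
    distance_range: tuple[float, float] = (0.0, 8.0)
    bad_distance_range: tuple[float, float] = (10.0, 50.0)
    hour_range: tuple[int, int] = (6, 20)
    bad_hours: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 22, 23)
    observers_range: tuple[int, int] = (1, 10)
    bad_observers_range: tuple[int, int] = (11, 30)
    months: tuple[int, ...] = (6, 7)
    bad_months: tuple[int, ...] = (1, 2, 3, 4, 11, 12)
    years: tuple[int, int] = (2010, 2023)
    bad_years: tuple[int, int] = (2000, 2009)


def attach_checklist_metadata(table: pd.DataFrame,
                              config: MetadataConfig | None = None,
                              fail_fraction: float | dict[str, float] = 0.0,
                              seed: int = 0
                              ) -> tuple[pd.DataFrame, dict[str, list]]:
    """Add checklist metadata columns, planting known filter violations.

    ``fail_fraction`` (scalar or per-criterion dict with keys from
    METADATA_CRITERIA) is the expected proportion of records made to
    violate each criterion, independently per criterion. Returns the
    augmented table and a ledger mapping each criterion to the record ids
    planted to violate it.
    """
    config = config or MetadataConfig()
    if isinstance(fail_fraction, dict):
        fractions = {c: float(fail_fraction.get(c, 0.0)) for c in METADATA_CRITERIA}
    else:
        fractions = {c: float(fail_fraction) for c in METADATA_CRITERIA}
    for crit, frac in fractions.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"fail_fraction for {crit!r} must be in [0,1]")
    rng = np.random.default_rng(seed)
    n = len(table)
    out = table.copy()
    fails = {c: rng.random(n) < fractions[c] for c in METADATA_CRITERIA}

    out["protocol"] = np.where(fails["protocol"], config.bad_protocol,
                               rng.choice(config.protocols, size=n))
    out["duration_minutes"] = np.where(
        fails["duration"],
        rng.uniform(*config.bad_duration_range, size=n),
        rng.uniform(*config.duration_range, size=n)).round(1)
    out["effort_distance_km"] = np.where(
        fails["distance"],
        rng.uniform(*config.bad_distance_range, size=n),
        rng.uniform(*config.distance_range, size=n)).round(2)
    good_hours = rng.integers(config.hour_range[0], config.hour_range[1] + 1, size=n)
    bad_hours = rng.choice(config.bad_hours, size=n)
    hours = np.where(fails["time"], bad_hours, good_hours)
    minutes = rng.integers(0, 60, size=n)
    out["start_time"] = [f"{h:02d}:{m:02d}" for h, m in zip(hours, minutes)]
    out["n_observers"] = np.where(
        fails["observers"],
        rng.integers(config.bad_observers_range[0], config.bad_observers_range[1] + 1, size=n),
        rng.integers(config.observers_range[0], config.observers_range[1] + 1, size=n))
    out["complete"] = ~fails["complete"]
    months = np.where(fails["month"], rng.choice(config.bad_months, size=n),
                      rng.choice(config.months, size=n))
    years = np.where(fails["year"],
                     rng.integers(config.bad_years[0], config.bad_years[1] + 1, size=n),
                     rng.integers(config.years[0], config.years[1] + 1, size=n))
    days = rng.integers(1, 29, size=n)
    out["date"] = [f"{y:04d}-{mo:02d}-{d:02d}" for y, mo, d in zip(years, months, days)]

    ids = out["id"].to_numpy()
    ledger = {c: ids[fails[c]].tolist() for c in METADATA_CRITERIA}
    return out, ledger


def make_scenario(kind: str, separation: float = 0.0, seed: int = 0,
                  layer_names: tuple[str, str] = ("env1", "env2"),
                  sigma: float = 1.0,
                  categorical_classes: dict[str, int] | None = None
                  ) -> NicheScenario:
    """Build the stock niche scenarios used throughout the test-bed.

    identical   — all groups share one niche (the no-divergence null).
    divergent   — two groups with optima ``separation * sigma`` apart on the
                  first layer.
    three_group — two parental groups at -/+ separation/2 on the first layer
                  and a hybrid whose optimum is displaced on the second
                  layer (not merely intermediate), mirroring a hybrid
                  occupying a transitional niche of its own.

    ``categorical_classes`` maps categorical layer names to class counts;
    every class gets weight 1 (no categorical preference) so categorical
    structure can be layered on by editing the returned scenario.
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    v1, v2 = layer_names
    if kind == "identical":
        groups = ["A", "B"]
        centers = {g: {v1: 0.0, v2: 0.0} for g in groups}
    elif kind == "divergent":
        groups = ["A", "B"]
        half = separation * sigma / 2.0
        centers = {"A": {v1: -half, v2: 0.0}, "B": {v1: +half, v2: 0.0}}
    elif kind == "three_group":
        groups = ["western", "glaucous", "hybrid"]
        half = separation * sigma / 2.0
        centers = {
            "western": {v1: -half, v2: 0.0},
            "glaucous": {v1: +half, v2: 0.0},
            "hybrid": {v1: 0.0, v2: separation * sigma / 2.0},
        }
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    breadths = {g: {v1: sigma, v2: sigma} for g in groups}
    class_weights: dict[str, dict[str, dict[int, float]]] = {}
    if categorical_classes:
        for g in groups:
            class_weights[g] = {
                layer: {code: 1.0 for code in range(n_classes)}
                for layer, n_classes in categorical_classes.items()
            }
    return NicheScenario(groups=groups, optima=centers, breadths=breadths,
                         class_weights=class_weights)
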