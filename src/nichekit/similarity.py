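"""Permutation tests for niche divergence: the niche identity test and the
blob range-breaking test.

Both tests compare the observed overlap (Schoener's D and Warren's I)
between two groups' fitted niche models against a null distribution built
by reassigning the pooled occurrences to pseudo-groups of the original
sizes and refitting both models with identical settings and the same
shared background:

* identity test — pseudo-groups are a uniformly random partition of the
  pool; a lower-tail p below alpha means the groups' niches overlap less
  than exchangeable relabelings allow, i.e. niche divergence.
* blob range-breaking test — each replicate picks one pooled point as an
  origin and assigns the |A| nearest points (great-circle or planar
  distance; ties broken by point id) to pseudo-A; a lower-tail p below
  alpha indicates a sharper boundary than spatially contiguous splits
  produce.

Every null replicate re-extracts its pseudo-groups' environments and
refits both models from scratch — the statistics must vary with the
relabeling, not merely resample fixed predictions. Both tails are always
reported; the lower tail is the divergence direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .env_select import extract_env
from .grids import RasterStack
from .maxent import Maxent
from .occurrences import pairwise_km
from .overlap import normalize_grid, overlap

__all__ = ["TestConfig", "PermutationTestResult", "permutation_p",
           "identity_test", "blob_range_break_test"]


@dataclass(frozen=True)
class TestConfig:
    """Settings shared by both permutation tests."""

    n_iter: int = 100
    alpha: float = 0.05
    seed: int = 0
    beta: float = 1.0
    feature_classes: tuple[str, ...] = ("linear", "quadratic")
    max_iter: int = 500
    tol: float = 1e-7
    metric: str = "haversine"  # blob split distances: haversine | euclidean

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PermutationTestResult:
    """Observed statistics, null distributions, and two-tailed p-values."""

    kind: str                        # identity | blob
    observed: dict[str, float]       # D and I
    null: dict[str, np.ndarray]      # statistic -> n_iter null values
    p_lower: dict[str, float]
    p_upper: dict[str, float]
    alpha: float
    n_excluded: int = 0              # replicates dropped for non-convergence
    seed: int = 0

    def significant(self, statistic: str = "D", tail: str = "lower") -> bool:
        p = (self.p_lower if tail == "lower" else self.p_upper)[statistic]
        return p <= self.alpha

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "observed": {k: float(v) for k, v in self.observed.items()},
            "null": {k: [float(x) for x in v] for k, v in self.null.items()},
            "p_lower": {k: float(v) for k, v in self.p_lower.items()},
            "p_upper": {k: float(v) for k, v in self.p_upper.items()},
            "alpha": self.alpha,
            "n_excluded": self.n_excluded,
            "seed": self.seed,
        }

    def plot(self, statistic: str = "D", ax=None):
        """Null histogram with the observed value as a dashed line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null[statistic], bins=20, color="steelblue", alpha=0.8)
        ax.axvline(self.observed[statistic], color="black", linestyle="--")
        ax.set_xlabel(f"{statistic} ({self.kind} null)")
        ax.set_ylabel("count")
        return ax


def permutation_p(observed: float, null: np.ndarray, tail: str = "lower") -> float:
    """Add-one permutation p-value; ties count toward the tail, so p > 0."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if tail == "lower":
        k = int(np.sum(null <= observed))
    elif tail == "upper":
        k = int(np.sum(null >= observed))
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    return (1 + k) / (null.size + 1)


def _fit_and_predict(env_presence: pd.DataFrame, env_background: pd.DataFrame,
                     stack: RasterStack, config: TestConfig):
    model = Maxent(env_presence, env_background, stack.kinds,
                   feature_classes=config.feature_classes)
    res = model.fit(beta=config.beta, max_iter=config.max_iter, tol=config.tol)
    grid = res.predict_grid(stack, output="raw")
    return res, normalize_grid(grid)


def _overlap_for_split(env_a: pd.DataFrame, env_b: pd.DataFrame,
                       env_bg: pd.DataFrame, stack: RasterStack,
                       config: TestConfig) -> tuple[dict[str, float], bool]:
    res_a, pa = _fit_and_predict(env_a, env_bg, stack, config)
    res_b, pb = _fit_and_predict(env_b, env_bg, stack, config)
    ov = overlap(pa, pb)
    return {"D": ov.D, "I": ov.I}, res_a.converged and res_b.converged


def _run_permutation_test(kind: str, occ_a: pd.DataFrame, occ_b: pd.DataFrame,
                          stack: RasterStack, background: pd.DataFrame,
                          config: TestConfig) -> PermutationTestResult:
    env_bg = extract_env(stack, background).values
    env_a = extract_env(stack, occ_a)
    env_b = extract_env(stack, occ_b)
    observed, _ = _overlap_for_split(env_a.values, env_b.values, env_bg, stack, config)

    pooled = pd.concat([occ_a, occ_b], ignore_index=True)
    env_pool = extract_env(stack, pooled)
    pool_env = env_pool.values.reset_index(drop=True)
    pool_pts = pooled.loc[env_pool.values.index].reset_index(drop=True)
    n_a = len(env_a.values)
    n_pool = len(pool_env)
    if kind == "blob":
        dist = pairwise_km(pool_pts["longitude"].to_numpy(),
                           pool_pts["latitude"].to_numpy(), config.metric)

    rng = np.random.default_rng(config.seed)
    null: dict[str, list[float]] = {"D": [], "I": []}
    n_excluded = 0
    for _ in range(config.n_iter):
        ok = False
        stats: dict[str, float] = {}
        for _attempt in range(2):  # one redraw on non-convergence
            if kind == "identity":
                perm = rng.permutation(n_pool)
                idx_a, idx_b = perm[:n_a], perm[n_a:]
            else:
                origin = rng.integers(n_pool)
                # nearest |A| points to the origin; ties broken by point id
                order = np.lexsort((pool_pts["id"].to_numpy(), dist[origin]))
                idx_a, idx_b = order[:n_a], order[n_a:]
            assert len(idx_a) + len(idx_b) == n_pool
            stats, ok = _overlap_for_split(pool_env.iloc[idx_a], pool_env.iloc[idx_b],
                                           env_bg, stack, config)
            if ok:
                break
        if not ok:
            n_excluded += 1
            continue
        null["D"].append(stats["D"])
        null["I"].append(stats["I"])

    null_arr = {k: np.asarray(v) for k, v in null.items()}
    p_lower = {k: permutation_p(observed[k], v, "lower") for k, v in null_arr.items()}
    p_upper = {k: permutation_p(observed[k], v, "upper") for k, v in null_arr.items()}
    return PermutationTestResult(kind=kind, observed=observed, null=null_arr,
                                 p_lower=p_lower, p_upper=p_upper,
                                 alpha=config.alpha, n_excluded=n_excluded,
                                 seed=config.seed)


def identity_test(occ_a: pd.DataFrame, occ_b: pd.DataFrame, stack: RasterStack,
                  background: pd.DataFrame,
                  config: TestConfig | None = None) -> PermutationTestResult:
    """Niche identity test: random relabeling null for D and I.

    The lower tail asks whether the groups' observed overlap is smaller
    than the randomized controls', i.e. whether the niches diverge.
    """
    return _run_permutation_test("identity", occ_a, occ_b, stack, background,
                                 config or TestConfig())


def blob_range_break_test(occ_a: pd.DataFrame, occ_b: pd.DataFrame,
                          stack: RasterStack, background: pd.DataFrame,
                          config: TestConfig | None = None
                          ) -> PermutationTestResult:
    """Blob range-breaking test: spatially contiguous pseudo-range null.

    Each replicate grows pseudo-A outward from a randomly chosen pooled
    point, so the null captures overlap levels expected from *any* sharp
    spatial boundary; the lower tail asks whether the real boundary is
    sharper still.
    """
    return _run_permutation_test("blob", occ_a, occ_b, stack, background,
                                 config or TestConfig())
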