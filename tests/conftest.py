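"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nichekit as nk


def flat_scenario(layer_names=("env1", "env2"),
                  categorical: dict[str, int] | None = None) -> nk.NicheScenario:
    """A niche so broad it is uniform over any landscape (sampling-effort proxy)."""
    weights = {}
    if categorical:
        weights = {"flat": {name: {c: 1.0 for c in range(n)}
                            for name, n in categorical.items()}}
    return nk.NicheScenario(
        groups=["flat"],
        optima={"flat": {v: 0.0 for v in layer_names}},
        breadths={"flat": {v: 1e6 for v in layer_names}},
        class_weights=weights,
    )


def small_stack(n: int = 40, seed: int = 1, autocorr: float = 3.0,
                corr: float | None = None) -> nk.RasterStack:
    grid = nk.GridSpec(n, n, cell_size=1.0)
    layers = [nk.LayerSpec("env1", autocorr_length=autocorr),
              nk.LayerSpec("env2", autocorr_length=autocorr)]
    matrix = None if corr is None else np.array([[1.0, corr], [corr, 1.0]])
    return nk.generate_landscape(grid, layers, matrix, seed=seed)


def sample_groups(stack: nk.RasterStack, separation: float, seed: int,
                  n_points: int = 100, n_background: int = 200,
                  sigma: float = 1.0):
    """Occurrences for two groups at the given niche separation, plus a
    uniform background sample (two continuous layers, no categorical).

    ``sigma`` is the niche breadth in layer-sd units; small values give a
    specialist niche that is strongly informative against the background.
    """
    rng = np.random.default_rng(seed)
    if separation == 0:
        scenario = nk.make_scenario("identical")
        suit_a = suit_b = nk.gaussian_niche_suitability(scenario, "A", stack)
    else:
        scenario = nk.make_scenario("divergent", separation=separation, sigma=sigma)
        suit_a = nk.gaussian_niche_suitability(scenario, "A", stack)
        suit_b = nk.gaussian_niche_suitability(scenario, "B", stack)
    occ_a = nk.sample_occurrences(suit_a, n_points, group="A",
                                  seed=int(rng.integers(2**31)))
    occ_b = nk.sample_occurrences(suit_b, n_points, group="B",
                                  seed=int(rng.integers(2**31)))
    uniform = nk.gaussian_niche_suitability(flat_scenario(), "flat", stack)
    background = nk.sample_occurrences(uniform, n_background, group="bg",
                                       seed=int(rng.integers(2**31)))
    return occ_a, occ_b, background


def run_identity_sim(seed: int, separation: float, n_points: int = 100,
                     n_background: int = 200, n_iter: int = 99,
                     grid_size: int = 40, kind: str = "identity"
                     ) -> nk.PermutationTestResult:
    """One scaled niche-divergence test on a fresh synthetic landscape."""
    rng = np.random.default_rng(seed)
    stack = small_stack(grid_size, seed=int(rng.integers(2**31)))
    occ_a, occ_b, background = sample_groups(stack, separation,
                                             int(rng.integers(2**31)),
                                             n_points, n_background)
    config = nk.TestConfig(n_iter=n_iter, seed=int(rng.integers(2**31)),
                           metric="euclidean", tol=1e-5, max_iter=200)
    fn = nk.identity_test if kind == "identity" else nk.blob_range_break_test
    return fn(occ_a, occ_b, stack, background, config)


@pytest.fixture(scope="session")
def stack40() -> nk.RasterStack:
    return small_stack(40, seed=11)


@pytest.fixture(scope="session")
def divergent_data(stack40):
    """Strongly separated specialist-niche two-group data (4-sigma apart,
    breadth 0.2 layer-sd) on the shared landscape."""
    return sample_groups(stack40, separation=4.0, seed=21,
                         n_points=150, n_background=300, sigma=0.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
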