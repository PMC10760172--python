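"""Niche-overlap statistics between two normalized suitability surfaces.

Given two probability surfaces p_X and p_Y over the same valid cells:

    Schoener's D   D = 1 - (1/2) * sum_i |p_X,i - p_Y,i|
    Hellinger      H = sqrt( sum_i (sqrt(p_X,i) - sqrt(p_Y,i))^2 )
    Warren's I     I = 1 - H^2/2  (= the Bhattacharyya coefficient
                                     sum_i sqrt(p_X,i * p_Y,i))

Both D and I run from 0 (disjoint niches) to 1 (identical surfaces), and
D <= I always, since total variation distance bounds half the squared
Hellinger distance from above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ProbabilityGrid, SuitabilityGrid


@dataclass(frozen=True)
class OverlapResult:
    D: float
    H: float
    I: float

    def to_dict(self) -> dict:
        return {"D": self.D, "H": self.H, "I": self.I}


def normalize_grid(suit: SuitabilityGrid, shared_mask: np.ndarray | None = None,
                   source_id: str = "") -> ProbabilityGrid:
    """Normalize a suitability surface to sum to one over the shared cells.

    ``shared_mask`` (True = excluded), when given, replaces the grid's own
    nodata mask so two surfaces can be renormalized over their common
    valid-cell set before comparison.
    """
    mask = suit.nodata_mask if shared_mask is None else np.asarray(shared_mask, bool)
    values = np.where(mask, 0.0, suit.values)
    total = values.sum()
    if total <= 0:
        raise ValueError("zero total suitability over the shared cells")
    return ProbabilityGrid(grid=suit.grid, values=values / total,
                           nodata_mask=mask, source_id=source_id)


def _check_comparable(pX: ProbabilityGrid, pY: ProbabilityGrid) -> None:
    if pX.values.shape != pY.values.shape or np.any(pX.nodata_mask != pY.nodata_mask):
        raise ValueError("probability grids must share the same cell set")


def schoener_d(pX: ProbabilityGrid, pY: ProbabilityGrid) -> float:
    """D = 1 - total variation distance; symmetric, in [0, 1]."""
    _check_comparable(pX, pY)
    return float(1.0 - 0.5 * np.abs(pX.flat() - pY.flat()).sum())


def warren_i(pX: ProbabilityGrid, pY: ProbabilityGrid) -> tuple[float, float]:
    """Returns (H, I): Hellinger distance and Warren's I = 1 - H^2/2."""
    _check_comparable(pX, pY)
    h2 = float(((np.sqrt(pX.flat()) - np.sqrt(pY.flat())) ** 2).sum())
    return float(np.sqrt(h2)), float(1.0 - h2 / 2.0)


def overlap(pX: ProbabilityGrid, pY: ProbabilityGrid) -> OverlapResult:
    """All three statistics in one pass."""
    d = schoener_d(pX, pY)
    h, i = warren_i(pX, pY)
    return OverlapResult(D=d, H=h, I=i)


def overlap_from_suitability(sX: SuitabilityGrid, sY: SuitabilityGrid
                             ) -> OverlapResult:
    """Compare two suitability surfaces over the intersection of their valid
    cells, renormalizing both there."""
    shared = sX.nodata_mask | sY.nodata_mask
    return overlap(normalize_grid(sX, shared), normalize_grid(sY, shared))
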