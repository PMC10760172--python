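"""Environmental extraction at occurrence points and collinearity screening.

Variable selection offers the two standard variance-inflation-factor
procedures: a stepwise greedy drop of the worst VIF above a threshold
(default 10) and a pairwise-correlation rule that, whenever two variables
correlate beyond a threshold (default 0.9), drops the member with the
larger VIF. Categorical variables are excluded from VIF arithmetic —
linear VIF is undefined for unordered class codes — but always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import CATEGORICAL, CONTINUOUS, RasterStack

#: VIF above this is reported as exact collinearity
VIF_INFINITE = np.inf
_R2_CAP = 1.0 - 1e-12


@dataclass
class EnvMatrix:
    """Environmental values at points: rows align with surviving points."""

    values: pd.DataFrame               # columns = variables
    kinds: dict[str, str]              # variable -> continuous | categorical
    point_ids: pd.Series
    cell_index: np.ndarray             # flat cell index per row
    n_dropped: int = 0                 # points outside extent or on nodata

    @property
    def continuous(self) -> list[str]:
        return [v for v in self.values.columns if self.kinds[v] == CONTINUOUS]

    @property
    def categorical(self) -> list[str]:
        return [v for v in self.values.columns if self.kinds[v] == CATEGORICAL]

    def subset(self, variables: list[str]) -> "EnvMatrix":
        return EnvMatrix(self.values[variables].copy(),
                         {v: self.kinds[v] for v in variables},
                         self.point_ids, self.cell_index, self.n_dropped)


def extract_env(stack: RasterStack, points: pd.DataFrame) -> EnvMatrix:
    """Nearest-cell (no interpolation) extraction of every layer at each point.

    Cell assignment follows the floor((coord - origin)/cell_size) convention,
    so boundary points deterministically belong to the greater-coordinate
    cell. Points outside the extent or on nodata cells are dropped and
    counted in ``n_dropped``.
    """
    row, col = stack.grid.cell_of(points["longitude"].to_numpy(),
                                  points["latitude"].to_numpy())
    inside = (row >= 0) & (row < stack.grid.n_rows) & (col >= 0) & (col < stack.grid.n_cols)
    r, c = row.copy(), col.copy()
    r[~inside] = 0
    c[~inside] = 0
    on_data = inside & ~stack.nodata_mask[r, c]
    n_dropped = int((~on_data).sum())
    if n_dropped == len(points):
        raise ValueError("every point fell outside the extent or on nodata cells")
    rows, cols = row[on_data], col[on_data]
    data = {layer.name: layer.values[rows, cols] for layer in stack.layers}
    ids = points["id"] if "id" in points.columns else pd.Series(
        np.arange(len(points)), name="id")
    return EnvMatrix(
        values=pd.DataFrame(data, index=points.index[on_data]),
        kinds=stack.kinds,
        point_ids=ids[on_data],
        cell_index=rows * stack.grid.n_cols + cols,
        n_dropped=n_dropped,
    )


def compute_vif(matrix: EnvMatrix | pd.DataFrame,
                variables: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per variable: VIF_j = 1/(1 - R2_j).

    R2_j comes from least squares of variable j on the other listed
    variables plus an intercept. Exact collinearity is reported as +inf.
    """
    df = matrix.values if isinstance(matrix, EnvMatrix) else matrix
    if variables is None:
        variables = (matrix.continuous if isinstance(matrix, EnvMatrix)
                     else list(df.columns))
    if len(variables) < 2:
        raise ValueError("VIF needs at least two continuous variables")
    if len(df) < len(variables) + 2:
        raise ValueError(f"need at least {len(variables) + 2} rows for {len(variables)} variables")
    X = df[variables].to_numpy(dtype=float)
    sds = X.std(axis=0)
    constant = [v for v, s in zip(variables, sds) if s == 0]
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    out = {}
    for j, var in enumerate(variables):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot
        out[var] = VIF_INFINITE if r2 >= _R2_CAP else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class VifReport:
    """Outcome of a collinearity-screening procedure."""

    method: str                          # vifstep | vifcor | intersection
    retained: list[str]                  # continuous survivors, original order
    dropped: list[str]                   # in drop order
    vifs: pd.Series                      # final VIFs of retained variables
    correlations: pd.DataFrame           # pairwise Pearson r of the input variables
    categorical: list[str] = field(default_factory=list)  # carried through untouched

    @property
    def selected(self) -> list[str]:
        """Retained continuous variables plus all categorical ones."""
        return self.retained + self.categorical

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "retained": self.retained,
            "dropped": self.dropped,
            "categorical": self.categorical,
            "vifs": {k: (None if np.isinf(v) else float(v)) for k, v in self.vifs.items()},
            "correlations": {
                a: {b: float(self.correlations.loc[a, b]) for b in self.correlations.columns}
                for a in self.correlations.index
            },
        }


def _finalize(method: str, df: pd.DataFrame, all_vars: list[str], kept: list[str],
              dropped: list[str], categorical: list[str]) -> VifReport:
    if len(kept) >= 2:
        final_vifs = compute_vif(df, kept)
    else:
        final_vifs = pd.Series({v: 1.0 for v in kept})
    return VifReport(method=method, retained=kept, dropped=dropped, vifs=final_vifs,
                     correlations=df[all_vars].corr(), categorical=categorical)


def vifstep_select(matrix: EnvMatrix | pd.DataFrame, threshold: float = 10.0
                   ) -> VifReport:
    """Iteratively drop the worst-VIF variable while it exceeds the threshold.

    Ties on the maximal VIF break alphabetically; VIFs are recomputed after
    every drop, so the report's drop order is the exact greedy path.
    """
    df = matrix.values if isinstance(matrix, EnvMatrix) else matrix
    variables = (matrix.continuous if isinstance(matrix, EnvMatrix) else list(df.columns))
    categorical = matrix.categorical if isinstance(matrix, EnvMatrix) else []
    kept = list(variables)
    dropped: list[str] = []
    while len(kept) >= 2:
        vifs = compute_vif(df, kept)
        worst = vifs.max()
        if worst <= threshold:
            break
        candidates = sorted(v for v in kept if vifs[v] == worst)
        victim = candidates[0]
        kept.remove(victim)
        dropped.append(victim)
    return _finalize("vifstep", df, variables, kept, dropped, categorical)


def vifcor_select(matrix: EnvMatrix | pd.DataFrame, r_threshold: float = 0.9
                  ) -> VifReport:
    """While any |Pearson r| exceeds the threshold, drop the pair member with
    the larger VIF (tie: alphabetical first), recomputing after each drop."""
    df = matrix.values if isinstance(matrix, EnvMatrix) else matrix
    variables = (matrix.continuous if isinstance(matrix, EnvMatrix) else list(df.columns))
    categorical = matrix.categorical if isinstance(matrix, EnvMatrix) else []
    kept = list(variables)
    dropped: list[str] = []
    while len(kept) >= 2:
        corr = df[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        max_r = corr.values.max()
        if max_r <= r_threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        vifs = compute_vif(df, kept)
        if vifs[a] > vifs[b]:
            victim = a
        elif vifs[b] > vifs[a]:
            victim = b
        else:
            victim = min(a, b)
        kept.remove(victim)
        dropped.append(victim)
    return _finalize("vifcor", df, variables, kept, dropped, categorical)


def select_variables(matrix: EnvMatrix, method: str = "both",
                     vif_threshold: float = 10.0, r_threshold: float = 0.9
                     ) -> VifReport:
    """Run the requested procedure(s); ``both`` retains the intersection.

    The component reports of ``both`` remain available by calling each
    procedure directly.
    """
    if method == "step":
        return vifstep_select(matrix, vif_threshold)
    if method == "cor":
        return vifcor_select(matrix, r_threshold)
    if method != "both":
        raise ValueError("method must be 'step', 'cor', or 'both'")
    step = vifstep_select(matrix, vif_threshold)
    cor = vifcor_select(matrix, r_threshold)
    kept = [v for v in step.retained if v in cor.retained]
    if not kept:
        raise ValueError("intersection of vifstep and vifcor retained sets is empty")
    dropped = step.dropped + [v for v in cor.dropped if v not in step.dropped]
    df = matrix.values
    return _finalize("intersection", df, matrix.continuous, kept, dropped,
                     matrix.categorical)
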