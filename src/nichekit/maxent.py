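"""Presence-background maximum-entropy niche modelling.

The model is the Gibbs distribution q_lambda(i) = exp(lambda . f(i)) / Z
over background cells that maximizes the L1-penalized log-likelihood of the
presence sample,

    J(lambda) = (1/m) sum_presence lambda . f(x_k) - log Z_lambda
                - sum_j beta_j |lambda_j|,

with Z_lambda = sum_background exp(lambda . f) and per-feature penalties
beta_j = beta * s_j / sqrt(m) (s_j the feature's presence-sample standard
deviation, m the presence count). Equivalently it is the most spread-out
(maximum entropy) distribution whose feature expectations match the
presence sample to within the regularization band.

The objective is concave; it is maximized by cyclic coordinate ascent with
a quadratic-approximation soft-threshold step per coordinate, backtracked
against the exact objective so the penalized gain never decreases. The
per-update gain increments, attributed to the updated feature's source
variable, form the training trace from which percent contribution is
computed — an accounting that is path-dependent by nature, matching how
the measure is conventionally defined.

Usage follows the Model/Results pattern::

    model = Maxent(presence_env, background_env, kinds)
    res = model.fit(beta=1.0)
    res.summary()
    grid = res.predict_grid(stack, output="cloglog")
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

from .grids import CATEGORICAL, CONTINUOUS, RasterStack, SuitabilityGrid

__all__ = [
    "Maxent", "MaxentResults", "FeatureMatrix", "build_features",
    "evaluate_auc", "crossvalidate", "EvalResult", "VariableImportance",
    "ResponseCurve",
]

_SD_FLOOR = 1e-3  # lower bound on s_j so no feature is penalty-free by accident


@dataclass(frozen=True)
class _Feature:
    """One model feature: how to compute it from raw environmental values."""

    name: str
    kind: str                 # linear | quadratic | product | hinge | categorical
    sources: tuple[str, ...]  # source variable(s)
    lo: float = 0.0           # scaling constants (min/max over presence+background)
    hi: float = 1.0
    knot: float = 0.0         # hinge knot / categorical class code
    reverse: bool = False     # reverse hinge

    def compute(self, env: pd.DataFrame) -> np.ndarray:
        span = self.hi - self.lo
        if self.kind == "categorical":
            return (env[self.sources[0]].to_numpy() == self.knot).astype(float)
        x = env[self.sources[0]].to_numpy(dtype=float)
        if self.kind == "hinge":
            if self.reverse:
                span = self.knot - self.lo
                v = (self.knot - x) / span if span > 0 else np.zeros_like(x)
            else:
                span = self.hi - self.knot
                v = (x - self.knot) / span if span > 0 else np.zeros_like(x)
            return np.clip(v, 0.0, 1.0)
        scaled = np.clip((x - self.lo) / span, 0.0, 1.0) if span > 0 else np.zeros_like(x)
        if self.kind == "linear":
            return scaled
        if self.kind == "quadratic":
            return scaled ** 2
        if self.kind == "product":
            y = env[self.sources[1]].to_numpy(dtype=float)
            span2 = self.hi2 - self.lo2  # type: ignore[attr-defined]
            scaled2 = np.clip((y - self.lo2) / span2, 0.0, 1.0)  # type: ignore[attr-defined]
            return scaled * scaled2
        raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass(frozen=True)
class _ProductFeature(_Feature):
    lo2: float = 0.0
    hi2: float = 1.0


@dataclass
class FeatureMatrix:
    """Presence and background rows expanded into scaled model features.

    Scaling constants come from the pooled presence+background extremes, so
    every feature lies in [0, 1] on the training data; out-of-range values
    at prediction time are clamped.
    """

    features: list[_Feature]
    presence: np.ndarray      # (m, J)
    background: np.ndarray    # (n, J)
    presence_std: np.ndarray  # s_j over presence rows
    env_presence: pd.DataFrame
    env_background: pd.DataFrame
    kinds: dict[str, str]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def source_variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            for s in f.sources:
                if s not in seen:
                    seen.append(s)
        return seen

    def transform(self, env: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.source_variables if v not in env.columns]
        if missing:
            raise ValueError(f"environment table lacks variables: {missing}")
        if not self.features:
            return np.empty((len(env), 0))
        return np.column_stack([f.compute(env) for f in self.features])


def build_features(env_presence: pd.DataFrame, env_background: pd.DataFrame,
                   kinds: dict[str, str],
                   classes: tuple[str, ...] = ("linear", "quadratic"),
                   n_hinge_knots: int = 5) -> FeatureMatrix:
    """Expand raw environmental columns into scaled maxent features.

    Continuous variables get the requested classes (linear, quadratic,
    product, hinge — hinge knots sit at presence-value quantiles);
    categorical variables always become one-hot class indicators.
    """
    if not classes:
        raise ValueError("at least one feature class required")
    unknown = set(classes) - {"linear", "quadratic", "product", "hinge"}
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    variables = list(env_presence.columns)
    combined = pd.concat([env_presence, env_background], ignore_index=True)
    feats: list[_Feature] = []
    cont = [v for v in variables if kinds.get(v, CONTINUOUS) == CONTINUOUS]
    for v in cont:
        lo = float(combined[v].min())
        hi = float(combined[v].max())
        if "linear" in classes:
            feats.append(_Feature(v, "linear", (v,), lo, hi))
        if "quadratic" in classes:
            feats.append(_Feature(f"{v}^2", "quadratic", (v,), lo, hi))
        if "hinge" in classes and n_hinge_knots > 0:
            qs = np.quantile(env_presence[v], np.linspace(0, 1, n_hinge_knots + 2)[1:-1])
            for k, q in enumerate(np.unique(qs)):
                if lo < q < hi:
                    feats.append(_Feature(f"{v}_hinge_fwd{k}", "hinge", (v,), lo, hi,
                                          knot=float(q)))
                    feats.append(_Feature(f"{v}_hinge_rev{k}", "hinge", (v,), lo, hi,
                                          knot=float(q), reverse=True))
    if "product" in classes:
        for i, a in enumerate(cont):
            for b in cont[i + 1:]:
                feats.append(_ProductFeature(
                    f"{a}*{b}", "product", (a, b),
                    float(combined[a].min()), float(combined[a].max()),
                    lo2=float(combined[b].min()), hi2=float(combined[b].max())))
    for v in variables:
        if kinds.get(v) == CATEGORICAL:
            codes = np.unique(combined[v].to_numpy())
            if len(codes) < 2:
                warnings.warn(f"categorical variable {v!r} has a single class; "
                              "indicator dropped")
                continue
            for code in codes:
                feats.append(_Feature(f"{v}=={code:g}", "categorical", (v,),
                                      knot=float(code)))
    fm = FeatureMatrix(
        features=feats,
        presence=np.empty((len(env_presence), len(feats))),
        background=np.empty((len(env_background), len(feats))),
        presence_std=np.empty(len(feats)),
        env_presence=env_presence.reset_index(drop=True),
        env_background=env_background.reset_index(drop=True),
        kinds=dict(kinds),
    )
    fm.presence = fm.transform(fm.env_presence)
    fm.background = fm.transform(fm.env_background)
    fm.presence_std = fm.presence.std(axis=0)
    return fm


def _objective(lam: np.ndarray, b: np.ndarray, Xb: np.ndarray,
               beta_j: np.ndarray) -> float:
    """Exact penalized gain J(lambda); Z is the *sum* over background rows."""
    return float(lam @ b - logsumexp(Xb @ lam) - beta_j @ np.abs(lam))


def _coordinate_ascent(Xp: np.ndarray, Xb: np.ndarray, beta_j: np.ndarray,
                       max_iter: int, tol: float
                       ) -> tuple[np.ndarray, list[tuple[int, float]], bool, int, float]:
    m, J = Xp.shape
    b = Xp.mean(axis=0)
    lam = np.zeros(J)
    eta = np.zeros(Xb.shape[0])
    obj = _objective(lam, b, Xb, beta_j)
    trace: list[tuple[int, float]] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        obj_start = obj
        for j in range(J):
            xj = Xb[:, j]
            shifted = eta - eta.max()
            w = np.exp(shifted)
            w /= w.sum()
            mu = w @ xj
            var = max(w @ (xj * xj) - mu * mu, 1e-12)
            grad = b[j] - mu
            z = var * lam[j] + grad
            new = np.sign(z) * max(abs(z) - beta_j[j], 0.0) / var
            d = new - lam[j]
            if d == 0.0:
                continue
            lam_rest = lam @ b - lam[j] * b[j]
            pen_rest = beta_j @ np.abs(lam) - beta_j[j] * abs(lam[j])
            accepted = False
            for _ in range(40):
                cand = lam[j] + d
                cand_eta = eta + d * xj
                cand_obj = (lam_rest + cand * b[j] - logsumexp(cand_eta)
                            - pen_rest - beta_j[j] * abs(cand))
                if cand_obj >= obj:
                    accepted = True
                    break
                d *= 0.5
            if not accepted:
                continue
            delta = cand_obj - obj
            lam[j] = cand
            eta = cand_eta
            obj = cand_obj
            if delta > 0:
                trace.append((j, delta))
        if obj - obj_start < tol:
            converged = True
            break
    return lam, trace, converged, it, obj


@dataclass
class EvalResult:
    """Replicated-validation AUC summary."""

    aucs: list[float]
    seeds: list[int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


@dataclass
class VariableImportance:
    """Per-variable contribution measures, each normalized to 100%."""

    percent_contribution: pd.Series
    permutation_importance: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"percent_contribution": self.percent_contribution}
        if self.permutation_importance is not None:
            data["permutation_importance"] = self.permutation_importance
        return pd.DataFrame(data)


@dataclass
class ResponseCurve:
    """Marginal response of predicted suitability to one variable.

    Other continuous variables are held at their presence means and
    categorical ones at their presence mode; the band is the mean +/- a
    normal-theory confidence half-width over replicate models.
    """

    variable: str
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    categorical: bool = False

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.categorical:
            ax.bar(self.grid, self.mean, yerr=[self.mean - self.lower,
                                               self.upper - self.mean], **kwargs)
        else:
            ax.plot(self.grid, self.mean, **kwargs)
            ax.fill_between(self.grid, self.lower, self.upper, alpha=0.3)
        ax.set_xlabel(self.variable)
        ax.set_ylabel("suitability (cloglog)")
        return ax


class Maxent:
    """Presence-background maximum-entropy model of habitat suitability.

    Parameters
    ----------
    env_presence, env_background
        Environmental values at presence and background points (one column
        per variable; identical columns in both).
    kinds
        Variable name -> ``"continuous"`` or ``"categorical"``.
    feature_classes
        Feature expansions for continuous variables. The default
        (linear + quadratic) keeps the optimum verifiable against a
        generic convex solver; hinge features are available but off by
        default.
    """

    def __init__(self, env_presence: pd.DataFrame, env_background: pd.DataFrame,
                 kinds: dict[str, str],
                 feature_classes: tuple[str, ...] = ("linear", "quadratic"),
                 n_hinge_knots: int = 5):
        if len(env_presence) < 1 or len(env_background) < 2:
            raise ValueError("need at least 1 presence and 2 background rows")
        self.features = build_features(env_presence, env_background, kinds,
                                       feature_classes, n_hinge_knots)
        self.kinds = dict(kinds)

    @classmethod
    def from_stack(cls, stack: RasterStack, presence: pd.DataFrame,
                   background: pd.DataFrame, variables: list[str] | None = None,
                   **kwargs) -> "Maxent":
        """Build a model by extracting layer values at presence/background points."""
        from .env_select import extract_env

        env_p = extract_env(stack, presence)
        env_b = extract_env(stack, background)
        cols = variables or list(env_p.values.columns)
        kinds = {v: stack.kinds[v] for v in cols}
        return cls(env_p.values[cols], env_b.values[cols], kinds, **kwargs)

    def fit(self, beta: float = 1.0, max_iter: int = 500, tol: float = 1e-7
            ) -> "MaxentResults":
        """Maximize the penalized gain; returns a results object.

        A model that exhausts ``max_iter`` is still returned, with
        ``converged=False``.
        """
        if beta < 0:
            raise ValueError("beta must be nonnegative")
        m = self.features.presence.shape[0]
        beta_j = beta * np.maximum(self.features.presence_std, _SD_FLOOR) / np.sqrt(m)
        lam, trace, converged, n_iter, obj = _coordinate_ascent(
            self.features.presence, self.features.background, beta_j,
            max_iter, tol)
        return MaxentResults(self, lam, beta, beta_j, trace, converged, n_iter, obj)


class MaxentResults:
    """Fitted maxent model: coefficients, gain trace, and derived surfaces."""

    def __init__(self, model: Maxent, lam: np.ndarray, beta: float,
                 beta_j: np.ndarray, trace: list[tuple[int, float]],
                 converged: bool, n_iter: int, objective: float):
        self.model = model
        self.features = model.features
        self.params = pd.Series(lam, index=self.features.names)
        self.beta = beta
        self.beta_j = pd.Series(beta_j, index=self.features.names)
        self.trace = trace
        self.converged = converged
        self.n_iter = n_iter
        self.objective = objective  # penalized gain J at the optimum
        eta_b = self.features.background @ lam
        self.log_norm = float(logsumexp(eta_b))  # log Z over background rows
        q = np.exp(eta_b - self.log_norm)
        self.entropy = float(-(q * np.log(np.clip(q, 1e-300, None))).sum())

    # -- prediction ---------------------------------------------------------

    def predict_raw(self, env: pd.DataFrame) -> np.ndarray:
        """exp(lambda . f)/Z with Z fixed by the training background."""
        X = self.features.transform(env)
        return np.exp(X @ self.params.to_numpy() - self.log_norm)

    def predict_cloglog(self, env: pd.DataFrame) -> np.ndarray:
        """1 - exp(-e^H * raw): raw rescaled by the background entropy H."""
        return 1.0 - np.exp(-np.exp(self.entropy) * self.predict_raw(env))

    def predict_grid(self, stack: RasterStack, output: str = "raw"
                     ) -> SuitabilityGrid:
        if output not in ("raw", "cloglog"):
            raise ValueError("output must be 'raw' or 'cloglog'")
        missing = [v for v in self.features.source_variables
                   if v not in stack.layer_names]
        if missing:
            raise ValueError(f"stack lacks layers: {missing}")
        valid = stack.valid_mask()
        env = pd.DataFrame({
            layer.name: layer.values[valid] for layer in stack.layers
        })
        scores = (self.predict_raw(env) if output == "raw"
                  else self.predict_cloglog(env))
        values = np.zeros(stack.grid.shape)
        values[valid] = scores
        return SuitabilityGrid(grid=stack.grid, values=values,
                               nodata_mask=stack.nodata_mask)

    # -- variable importance ------------------------------------------------

    def percent_contribution(self) -> pd.Series:
        """Share of positive penalized-gain increments per source variable."""
        sources = self.features.source_variables
        acc = {v: 0.0 for v in sources}
        if not self.trace:
            warnings.warn("empty training trace (all-zero model); contributions are 0")
            return pd.Series(acc)
        for j, delta in self.trace:
            if delta <= 0:
                continue
            srcs = self.features.features[j].sources
            for s in srcs:
                acc[s] += delta / len(srcs)
        total = sum(acc.values())
        if total <= 0:
            return pd.Series(acc)
        return pd.Series({v: 100.0 * a / total for v, a in acc.items()})

    def permutation_importance(self, seed: int = 0) -> pd.Series:
        """Normalized AUC drop when each variable is shuffled across all rows."""
        rng = np.random.default_rng(seed)
        fm = self.features
        env_all = pd.concat([fm.env_presence, fm.env_background], ignore_index=True)
        m = len(fm.env_presence)
        lam = self.params.to_numpy()
        base_scores = np.concatenate([fm.presence @ lam, fm.background @ lam])
        auc0 = evaluate_auc(base_scores[:m], base_scores[m:])
        drops = {}
        for v in fm.source_variables:
            shuffled = env_all.copy()
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
            cols = [i for i, f in enumerate(fm.features) if v in f.sources]
            Xp = fm.presence.copy()
            Xb = fm.background.copy()
            newX = np.column_stack([fm.features[i].compute(shuffled) for i in cols])
            Xp[:, cols] = newX[:m]
            Xb[:, cols] = newX[m:]
            scores = np.concatenate([Xp @ lam, Xb @ lam])
            auc_perm = evaluate_auc(scores[:m], scores[m:])
            drops[v] = max(0.0, auc0 - auc_perm)
        total = sum(drops.values())
        if total <= 0:
            return pd.Series({v: 0.0 for v in drops})
        return pd.Series({v: 100.0 * d / total for v, d in drops.items()})

    def variable_importance(self, seed: int = 0) -> VariableImportance:
        return VariableImportance(self.percent_contribution(),
                                  self.permutation_importance(seed))

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Maximum-entropy niche model",
            "=" * 46,
            f"presence points:    {self.features.presence.shape[0]}",
            f"background points:  {self.features.background.shape[0]}",
            f"features:           {len(self.params)}",
            f"beta multiplier:    {self.beta:g}",
            f"penalized gain:     {self.objective + np.log(self.features.background.shape[0]):.6f}",
            f"log Z:              {self.log_norm:.6f}",
            f"entropy H:          {self.entropy:.6f}",
            f"converged:          {self.converged} ({self.n_iter} sweeps)",
            "-" * 46,
            f"{'feature':<28}{'lambda':>10}{'beta_j':>8}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<28}{self.params[name]:>10.4f}{self.beta_j[name]:>8.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "beta": self.beta,
            "log_norm": self.log_norm,
            "entropy": self.entropy,
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
            "objective": self.objective,
        }


def evaluate_auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney with mid-rank ties): P(presence > background)."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.ones(sp.size), np.zeros(sb.size)])
    scores = np.concatenate([sp, sb])
    if np.all(scores == scores[0]):
        return 0.5
    return float(roc_auc_score(y, scores))


def crossvalidate(env_presence: pd.DataFrame, env_background: pd.DataFrame,
                  kinds: dict[str, str], n_replicates: int = 10,
                  test_fraction: float = 0.2, beta: float = 1.0, seed: int = 0,
                  feature_classes: tuple[str, ...] = ("linear", "quadratic"),
                  max_iter: int = 500, tol: float = 1e-7) -> EvalResult:
    """Replicated random-split validation: fit on 80% of presences, score AUC
    of the held-out 20% against the full (never split) background."""
    m = len(env_presence)
    n_test = int(round(m * test_fraction))
    if n_test < 1:
        raise ValueError("test_fraction leaves no test presences")
    root = np.random.default_rng(seed)
    seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=n_replicates)]
    aucs = []
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(m)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        model = Maxent(env_presence.iloc[train_idx], env_background, kinds,
                       feature_classes=feature_classes)
        res = model.fit(beta=beta, max_iter=max_iter, tol=tol)
        sp = res.predict_raw(env_presence.iloc[test_idx])
        sb = res.predict_raw(env_background)
        aucs.append(evaluate_auc(sp, sb))
    return EvalResult(aucs=aucs, seeds=seeds)


def response_curve(results: "MaxentResults | list[MaxentResults]", variable: str,
                   n_grid: int = 100) -> ResponseCurve:
    """Marginal cloglog response to one variable across replicate models."""
    reps = results if isinstance(results, list) else [results]
    fm = reps[0].features
    if variable not in fm.source_variables:
        raise ValueError(f"variable {variable!r} not in the model")
    env_p = fm.env_presence
    categorical = fm.kinds.get(variable) == CATEGORICAL
    if categorical:
        grid = np.unique(pd.concat([fm.env_presence[variable],
                                    fm.env_background[variable]]).to_numpy())
    else:
        combined = pd.concat([env_p[variable], fm.env_background[variable]])
        grid = np.linspace(combined.min(), combined.max(), n_grid)
    base = {}
    for v in fm.source_variables:
        if fm.kinds.get(v) == CATEGORICAL:
            base[v] = env_p[v].mode().iloc[0]
        else:
            base[v] = env_p[v].mean()
    env_grid = pd.DataFrame({v: np.full(len(grid), base[v]) for v in fm.source_variables})
    env_grid[variable] = grid
    preds = np.stack([r.predict_cloglog(env_grid) for r in reps])
    mean = preds.mean(axis=0)
    if len(reps) > 1:
        half = 1.96 * preds.std(axis=0, ddof=1) / np.sqrt(len(reps))
    else:
        half = np.zeros_like(mean)
    return ResponseCurve(variable=variable, grid=grid, mean=mean,
                         lower=mean - half, upper=mean + half,
                         categorical=categorical)
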