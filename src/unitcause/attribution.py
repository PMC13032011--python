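"""Causal attribution for Isolated and Pure input units.

The effect of an input unit on a class output is estimated under Pearl's
do-operator.  Rather than re-evaluating the network over the whole cohort
for every intervention value, the intervention expectation is approximated
by a second-order Taylor expansion around the (intervened) input mean:

    E[y | do(x_i = α)] ≈ f(μ') + ½·tr(∇²f(μ')·Σ')

where (μ', Σ') are the cohort mean and covariance after the intervention.
For an **Isolated** unit the do-operator simply pins μ'_i = α and removes
the unit's variance.  For a **Pure** unit the intervention also propagates
to downstream mediators: each descendant's mean shifts by the sum over
directed paths of the product of fitted edge coefficients, and the
covariance loses the component carried by the intervened unit.

Both updates are the congruence Σ' = (I − t e_uᵀ) Σ (I − t e_uᵀ)ᵀ with t the
unit's total-effect vector (t_u = 1, zero off the unit's descendants), which
is exactly the covariance of the intervened linear SCM when the unit is a
source, and is positive semidefinite by construction.

Averaging the intervention expectation over a uniform grid on the unit's
intervention interval gives the unit's average causal effect level; the
curve minus its own grid-mean ("centered") is what the attribution figures
display.  For a binary unit the two-point contrast
E[y|do(1)] − E[y|do(0)] is recovered as the span of the curve.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .graph import CausalGraph, UnitCategory, classify_units, enumerate_paths
from .nn import FeedforwardClassifier

__all__ = [
    "GaussianSummary",
    "InterventionGrid",
    "AttributionCurve",
    "PathEffect",
    "fit_gaussian_summary",
    "intervene_summary",
    "taylor_expectation",
    "mc_expectation",
    "ace_isolated",
    "fit_edge_coefficients",
    "total_effect_pure",
    "ace_pure",
]

CLASS_LABELS = ("No", "Yes")


@dataclasses.dataclass(frozen=True)
class GaussianSummary:
    """Mean vector and covariance matrix of the input features (raw scale)."""

    mean: np.ndarray
    cov: np.ndarray
    feature_order: tuple[str, ...]

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, float)
        cov = np.asarray(self.cov, float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (len(mean), len(mean)):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    def index(self, unit: str) -> int:
        try:
            return self.feature_order.index(unit)
        except ValueError:
            raise KeyError(f"unknown unit {unit!r}") from None


@dataclasses.dataclass(frozen=True)
class InterventionGrid:
    """Uniform grid of num intervention values on [low, high], inclusive."""

    unit: str
    low: float
    high: float
    num: int = 10

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low must be < high")
        if self.num < 2:
            raise ValueError("num must be >= 2")

    @property
    def alphas(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.num)

    @classmethod
    def from_cohort(cls, cohort: CohortTable, unit: str, num: int = 10,
                    quantiles: tuple[float, float] = (0.01, 0.99)
                    ) -> "InterventionGrid":
        """Grid between the unit's 1st and 99th cohort percentiles.

        Binary units get the exact {0, 1} two-point grid.
        """
        vals = cohort.frame[unit].to_numpy(dtype=float)
        if cohort.kinds.get(unit) == "binary":
            return cls(unit, 0.0, 1.0, 2)
        lo, hi = np.quantile(vals, quantiles)
        return cls(unit, float(lo), float(hi), num)


@dataclasses.dataclass(frozen=True)
class AttributionCurve:
    """Per-unit intervention-expectation curve for one output class."""

    unit: str
    class_label: str
    alphas: np.ndarray
    expectation: np.ndarray

    @property
    def ace(self) -> float:
        """Grid-average of E[y|do(x=α)] (uniform-grid quadrature)."""
        return float(self.expectation.mean())

    @property
    def centered(self) -> np.ndarray:
        """Expectation minus its grid-mean (what the figures plot)."""
        return self.expectation - self.expectation.mean()

    @property
    def span_effect(self) -> float:
        """E at the top of the grid minus E at the bottom.

        On a {0, 1} grid this is exactly the binary contrast
        E[y|do(1)] − E[y|do(0)].
        """
        return float(self.expectation[-1] - self.expectation[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha": self.alphas,
            "expectation": self.expectation,
            "centered": self.centered,
        })


@dataclasses.dataclass(frozen=True)
class PathEffect:
    """One directed path and its product-of-coefficients effect."""

    path: tuple[str, ...]
    edge_coeffs: tuple[float, ...]
    effect: float


def fit_gaussian_summary(cohort: CohortTable | pd.DataFrame) -> GaussianSummary:
    """Sample mean and covariance of the feature table."""
    frame = cohort.features if isinstance(cohort, CohortTable) else cohort
    X = frame.to_numpy(dtype=float)
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need at least p+1 records for a covariance estimate")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / X.shape[0]
    if np.any(np.diag(cov) <= 0):
        warnings.warn("degenerate covariance: a feature has zero variance")
    return GaussianSummary(mean, cov, tuple(frame.columns))


def intervene_summary(summary: GaussianSummary, unit: str, alpha: float,
                      total_effects: Mapping[str, float] | None = None
                      ) -> GaussianSummary:
    """Moments of the input distribution under do(unit = α).

    ``total_effects`` maps downstream features to the unit's total causal
    effect on them (sum over directed paths of edge-coefficient products);
    omit it for Isolated units.  The intervened unit's mean becomes α and
    its row/column of the covariance vanish; downstream means shift by
    effect·(α − old mean) and the covariance is updated by the congruence
    Σ' = (I − t e_uᵀ) Σ (I − t e_uᵀ)ᵀ, hence stays positive semidefinite.
    """
    u = summary.index(unit)
    d = len(summary.mean)
    t = np.zeros(d)
    t[u] = 1.0
    if total_effects:
        for name, eff in total_effects.items():
            j = summary.index(name)
            if j != u:
                t[j] = float(eff)
    shift = alpha - summary.mean[u]
    new_mean = summary.mean + t * shift
    M = np.eye(d) - np.outer(t, np.eye(d)[u])
    new_cov = M @ summary.cov @ M.T
    new_cov = (new_cov + new_cov.T) / 2.0
    new_cov[u, :] = 0.0
    new_cov[:, u] = 0.0
    return GaussianSummary(new_mean, new_cov, summary.feature_order)


def taylor_expectation(model, summary: GaussianSummary, class_index: int,
                       mode: str = "proba") -> float:
    """Second-order approximation f(μ) + ½·tr(∇²f(μ)·Σ).

    ``model`` needs ``value(point, class_index, mode)`` and
    ``hessian(point, class_index, mode)``; the trained feedforward
    classifier provides both.
    """
    if isinstance(model, FeedforwardClassifier) and \
            tuple(model.feature_order) != tuple(summary.feature_order):
        raise ValueError("model and summary feature orders differ")
    mu = summary.mean
    H = model.hessian(mu, class_index, mode=mode)
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite Hessian entries")
    return float(model.value(mu, class_index, mode=mode)
                 + 0.5 * np.trace(H @ summary.cov))


def mc_expectation(model, summary: GaussianSummary, class_index: int,
                   draws: np.ndarray, mode: str = "proba") -> float:
    """Sampling estimate of E[y] under N(μ, Σ), from standard-normal draws.

    ``draws`` are reusable standard-normal variates (common random numbers
    across a grid keep curves smooth and make a unit the model ignores
    cancel exactly).
    """
    d = len(summary.mean)
    jitter = 1e-12 * max(1.0, float(np.trace(summary.cov)) / d)
    L = np.linalg.cholesky(summary.cov + jitter * np.eye(d))
    X = summary.mean + draws @ L.T
    if mode == "logit":
        vals = model.predict_logits(X)[:, class_index]
    else:
        vals = model.predict_proba(X)[:, class_index]
    return float(vals.mean())


#: activation margin below which the second-order expansion is not trusted
TAYLOR_MARGIN = 3.0


def _expectation_curve(model, summaries, class_index: int, mode: str,
                       method: str, mc_draws: int, mc_seed: int) -> np.ndarray:
    """Intervention expectation at each intervened summary.

    ``method``: "taylor" (second-order expansion), "mc" (Gaussian sampling),
    or "auto" — Taylor when every expansion point keeps a safe distance from
    the ReLU kinks (activation margin ≥ 3 perturbation SDs), sampling
    otherwise.
    """
    from .nn import FeedforwardClassifier, activation_margin

    if method == "auto":
        if isinstance(model, FeedforwardClassifier) and mode == "proba":
            margin = min(activation_margin(model, s.mean, s.cov)
                         for s in summaries)
            if margin < TAYLOR_MARGIN:
                warnings.warn(
                    f"activation margin {margin:.2f} < {TAYLOR_MARGIN}: "
                    "second-order expansion unreliable here; using Gaussian "
                    "sampling for the intervention expectations"
                )
                method = "mc"
            else:
                method = "taylor"
        else:
            method = "taylor"
    if method == "taylor":
        return np.array([taylor_expectation(model, s, class_index, mode=mode)
                         for s in summaries])
    if method == "mc":
        rng = np.random.default_rng(mc_seed)
        draws = rng.standard_normal((mc_draws, len(summaries[0].mean)))
        return np.array([mc_expectation(model, s, class_index, draws, mode)
                         for s in summaries])
    raise ValueError(f"unknown expectation method {method!r}")


def _check_category(graph: CausalGraph | None, unit: str,
                    expected: UnitCategory) -> None:
    if graph is None:
        return
    cats = classify_units(graph, graph.nodes)
    actual = cats.get(unit)
    if actual != expected:
        raise ValueError(
            f"unit {unit!r} is {actual} in the graph, not {expected}: use the "
            f"attribution engine matching its category"
        )


def ace_isolated(model, summary: GaussianSummary, grid: InterventionGrid,
                 class_index: int, graph: CausalGraph | None = None,
                 mode: str = "proba", method: str = "auto",
                 mc_draws: int = 20000, mc_seed: int = 0) -> AttributionCurve:
    """Attribution curve for an Isolated unit over an intervention grid."""
    _check_category(graph, grid.unit, UnitCategory.ISOLATED)
    summaries = [intervene_summary(summary, grid.unit, a)
                 for a in grid.alphas]
    expectations = _expectation_curve(model, summaries, class_index, mode,
                                      method, mc_draws, mc_seed)
    return AttributionCurve(grid.unit, CLASS_LABELS[class_index],
                            grid.alphas, expectations)


def fit_edge_coefficients(cohort: CohortTable | pd.DataFrame,
                          g: CausalGraph) -> dict[tuple[str, str], float]:
    """OLS edge coefficients: each node regressed on all its parents jointly.

    The coefficient on edge (p → c) is the partial slope of p in the joint
    regression of c on its parent set (with intercept).  Collinear parent
    blocks fall back to the pseudo-inverse with a warning.  Undirected edges
    are skipped with a warning (no causal order to regress along).
    """
    frame = cohort.features if isinstance(cohort, CohortTable) else cohort
    if g.undirected_edges:
        warnings.warn(f"{len(g.undirected_edges)} undirected edge(s) excluded "
                      "from coefficient fitting")
    coeffs: dict[tuple[str, str], float] = {}
    for node in sorted(g.nodes):
        parents = sorted(g.parents(node))
        if not parents or node not in frame.columns:
            continue
        X = frame[parents].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(X)), X])
        y = frame[node].to_numpy(dtype=float)
        xtx = X.T @ X
        if np.linalg.cond(xtx) > 1e10:
            warnings.warn(f"collinear parents of {node!r}; using pseudo-inverse")
            beta = np.linalg.pinv(X) @ y
        else:
            beta = np.linalg.solve(xtx, X.T @ y)
        for k, p in enumerate(parents):
            coeffs[(p, node)] = float(beta[k + 1])
    return coeffs


def total_effect_pure(g: CausalGraph,
                      coeffs: Mapping[tuple[str, str], float],
                      unit: str, target: str
                      ) -> tuple[float, list[PathEffect]]:
    """Total causal effect of unit on target: Σ over paths of Π edge coeffs."""
    paths = enumerate_paths(g, unit, target) if target in g.nodes else []
    effects: list[PathEffect] = []
    for path in paths:
        if len(path) < 2:
            continue
        cs = tuple(coeffs[(a, b)] for a, b in zip(path, path[1:]))
        effects.append(PathEffect(tuple(path), cs, float(np.prod(cs))))
    return float(sum(pe.effect for pe in effects)), effects


def ace_pure(model, cohort: CohortTable, g: CausalGraph, unit: str,
             grid: InterventionGrid, class_index: int,
             mode: str = "proba",
             summary: GaussianSummary | None = None,
             coeffs: Mapping[tuple[str, str], float] | None = None,
             method: str = "auto", mc_draws: int = 20000,
             mc_seed: int = 0) -> AttributionCurve:
    """Attribution curve for a Pure unit, propagating through its mediators.

    Edge coefficients come from OLS on the causal structure; each grid value
    α shifts the unit and all its descendants (by path-product total
    effects) before the Taylor expectation is evaluated.
    """
    _check_category(g, unit, UnitCategory.PURE)
    if grid.unit != unit:
        raise ValueError("grid is for a different unit")
    if summary is None:
        summary = fit_gaussian_summary(cohort)
    if coeffs is None:
        coeffs = fit_edge_coefficients(cohort, g)
    totals = {
        d: total_effect_pure(g, coeffs, unit, d)[0]
        for d in sorted(g.descendants(unit))
    }
    summaries = [intervene_summary(summary, unit, a, totals)
                 for a in grid.alphas]
    expectations = _expectation_curve(model, summaries, class_index, mode,
                                      method, mc_draws, mc_seed)
    return AttributionCurve(unit, CLASS_LABELS[class_index],
                            grid.alphas, expectations)


def write_curves_csv(curves: Sequence[AttributionCurve], path) -> None:
    """CSV export: alpha, expectation/centered per class for one unit."""
    by_label = {c.class_label: c for c in curves}
    base = curves[0]
    out = pd.DataFrame({"alpha": base.alphas})
    for label, c in by_label.items():
        out[f"expectation_{label.lower()}"] = c.expectation
        out[f"centered_{label.lower()}"] = c.centered
    out.to_csv(path, index=False)
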