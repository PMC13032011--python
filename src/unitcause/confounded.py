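"""Backdoor-adjusted attribution for Confounded units.

A Confounded unit has parents among the inputs, so its association with the
classifier's output mixes the causal effect with backdoor paths through
those parents.  The engine here:

1. discretizes the unit's values into k ordered groups (equal-width or
   equal-frequency);
2. for each adjacent pair of groups, forms a binary treatment (membership
   in the upper group) among records in either group;
3. adjusts for the unit's backdoor set (its parents in the causal graph)
   with an R-learner: cross-fitted outcome and propensity nuisances, then a
   residual-on-residual fit of the treatment-effect function τ̂(x) with
   weights (T − ê)², using a 10:1 convex ensemble of gradient-boosted trees
   and a random forest;
4. reports the per-pair average causal effect (mean τ̂) and the cumulative
   curve from a zero baseline.

Model quality is scored by R score = 1 − L̂_R / L_base, comparing the
cross-validated R-loss of τ̂ against a constant-average-treatment-effect
baseline.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import CohortTable
from .graph import CausalGraph, backdoor_set

__all__ = [
    "Binning",
    "PropensityModel",
    "TreatmentEffectModel",
    "RScoreReport",
    "ConfoundedCurve",
    "discretize",
    "estimate_propensity",
    "fit_meta_learner",
    "r_score",
    "ace_confounded",
    "graph_with_outcome",
]

PROPENSITY_CLIP = (0.01, 0.99)
DEFAULT_ENSEMBLE_WEIGHTS = (10.0 / 11.0, 1.0 / 11.0)


# -- discretization --------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Binning:
    strategy: str  # {"equal_width", "equal_frequency"}
    k: int
    edges: np.ndarray  # k+1 ascending reals
    assignment: np.ndarray  # fitted values -> bin index in [0, k)

    def assign(self, values) -> np.ndarray:
        """Bin index for new values (right-closed last bin)."""
        v = np.asarray(values, float)
        idx = np.searchsorted(self.edges[1:-1], v, side="right")
        return np.clip(idx, 0, self.k - 1)


def discretize(values, strategy: str = "equal_width", k: int = 10) -> Binning:
    """Split values into k ordered groups.

    ``equal_width``: edges are linspace(min, max, k+1).  ``equal_frequency``:
    edges at the empirical i/k quantiles, with rank-based assignment so group
    sizes differ by at most one.
    """
    v = np.asarray(values, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    distinct = np.unique(v)
    if strategy == "equal_width":
        if len(distinct) < 2:
            raise ValueError("cannot equal-width bin a constant vector")
        edges = np.linspace(v.min(), v.max(), k + 1)
        assignment = np.clip(np.searchsorted(edges[1:-1], v, side="right"),
                             0, k - 1)
    elif strategy == "equal_frequency":
        if len(distinct) < k:
            raise ValueError(
                f"equal-frequency binning needs >= {k} distinct values"
            )
        edges = np.quantile(v, np.linspace(0, 1, k + 1))
        order = np.argsort(v, kind="stable")
        assignment = np.empty(len(v), dtype=int)
        assignment[order] = (np.arange(len(v)) * k) // len(v)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return Binning(strategy, k, edges, assignment)


# -- propensity ------------------------------------------------------------

@dataclasses.dataclass
class PropensityModel:
    covariates: tuple[str, ...]
    scores: np.ndarray  # cross-fitted, clipped
    calibration_slope: float
    _model: object

    def __call__(self, Z) -> np.ndarray:
        p = self._model.predict_proba(np.asarray(Z, float))[:, 1]
        return np.clip(p, *PROPENSITY_CLIP)


def _cross_fit_propensity(Z: np.ndarray, t: np.ndarray, folds: int,
                          seed: int) -> np.ndarray:
    scores = np.empty(len(t), float)
    folds = min(folds, int(np.bincount(t).min())) if len(np.unique(t)) > 1 else 0
    if folds < 2:
        scores[:] = t.mean()
        return np.clip(scores, *PROPENSITY_CLIP)
    kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(Z, t):
        if len(np.unique(t[train])) < 2:
            scores[test] = t[train].mean()
            continue
        clf = LogisticRegression(max_iter=2000)
        clf.fit(Z[train], t[train])
        scores[test] = clf.predict_proba(Z[test])[:, 1]
    return np.clip(scores, *PROPENSITY_CLIP)


def estimate_propensity(data, treatment_indicator, Z: Sequence[str],
                        folds: int = 5, seed: int = 0) -> PropensityModel:
    """Cross-fitted propensity scores e(z) = P(T=1 | Z=z), clipped to [.01, .99]."""
    frame = data.features if isinstance(data, CohortTable) else pd.DataFrame(data)
    Z = tuple(Z)
    if not Z:
        raise ValueError("Z must be nonempty")
    t = np.asarray(treatment_indicator, int)
    if len(np.unique(t)) < 2:
        raise ValueError("treatment indicator is constant")
    Zm = frame[list(Z)].to_numpy(dtype=float)
    scores = _cross_fit_propensity(Zm, t, folds, seed)
    # calibration slope: OLS of T on the cross-fitted score
    sc = scores - scores.mean()
    denom = float(sc @ sc)
    slope = float(sc @ (t - t.mean()) / denom) if denom > 0 else float("nan")
    final = LogisticRegression(max_iter=2000).fit(Zm, t)
    return PropensityModel(Z, scores, slope, final)


# -- R-learner meta-learning ----------------------------------------------

def _make_gbdt(seed: int):
    return HistGradientBoostingRegressor(max_iter=200, max_depth=3,
                                         random_state=seed)


def _make_rf(seed: int):
    return RandomForestRegressor(n_estimators=100, min_samples_leaf=20,
                                 random_state=seed, n_jobs=1)


@dataclasses.dataclass
class TreatmentEffectModel:
    """Fitted τ̂(x) with its cross-fitted nuisances.

    ``tau_learner`` is "ensemble" (GBDT + RF, 10:1) or "constant" (the
    weighted average treatment effect, the R-score baseline).
    """

    covariates: tuple[str, ...]
    ensemble_weights: tuple[float, float]
    tau_learner: str
    X: np.ndarray
    y: np.ndarray
    t: np.ndarray
    e_hat: np.ndarray
    m_hat: np.ndarray
    seed: int
    _tau_fn: Callable[[np.ndarray], np.ndarray]

    def tau(self, X) -> np.ndarray:
        return self._tau_fn(np.asarray(X, float))

    @property
    def ate(self) -> float:
        """Average treatment effect: mean of τ̂ over the sample."""
        return float(np.mean(self.tau(self.X)))


def _fit_tau(kind: str, X, psi, w, weights: tuple[float, float], seed: int
             ) -> Callable[[np.ndarray], np.ndarray]:
    """Fit τ̂ on pseudo-outcomes ψ with weights w."""
    if kind == "constant":
        c = float(np.average(psi, weights=w))
        return lambda Xn: np.full(len(np.atleast_2d(Xn)), c)
    gb = _make_gbdt(seed).fit(X, psi, sample_weight=w)
    rf = _make_rf(seed + 1).fit(X, psi, sample_weight=w)
    wg, wr = weights
    return lambda Xn: wg * gb.predict(Xn) + wr * rf.predict(Xn)


def fit_meta_learner(data, treatment_indicator, outcome,
                     Z: Sequence[str],
                     ensemble_weights: tuple[float, float] = DEFAULT_ENSEMBLE_WEIGHTS,
                     folds: int = 5, seed: int = 0,
                     tau_learner: str = "ensemble") -> TreatmentEffectModel:
    """R-learner with per-arm inverse-propensity outcome models.

    Cross-fitted nuisances: propensity ê(x) by logistic regression and
    outcome m̂(x) = ê·m̂₁ + (1−ê)·m̂₀ from per-arm gradient-boosted models
    trained with inverse-propensity weights.  τ̂ then minimizes the R-loss
    Σ w·[ψ − τ̂(x)]² with ψ = (Y−m̂)/(T−ê) and w = (T−ê)², using a 10:1
    GBDT/random-forest ensemble (or the weighted constant for the
    baseline model).
    """
    frame = data.features if isinstance(data, CohortTable) else pd.DataFrame(data)
    Z = tuple(Z)
    X = frame[list(Z)].to_numpy(dtype=float)
    t = np.asarray(treatment_indicator, int)
    y = np.asarray(outcome, float)
    if abs(sum(ensemble_weights) - 1.0) > 1e-9:
        raise ValueError("ensemble weights must sum to 1")
    if len(np.unique(t)) < 2:
        raise ValueError("treatment indicator is constant")

    e_hat = _cross_fit_propensity(X, t, folds, seed)
    at_bounds = np.mean((e_hat <= PROPENSITY_CLIP[0] + 1e-12)
                        | (e_hat >= PROPENSITY_CLIP[1] - 1e-12))
    if at_bounds > 0.20:
        warnings.warn(
            f"positivity violation: {at_bounds:.0%} of propensity scores at "
            "the clip bounds"
        )

    minority = int(np.bincount(t).min())
    if minority < 2:
        raise ValueError("need at least 2 records in each treatment arm")
    m_hat = np.empty(len(y), float)
    kf = StratifiedKFold(n_splits=max(2, min(folds, minority)), shuffle=True,
                         random_state=seed)
    for f, (train, test) in enumerate(kf.split(X, t)):
        tr_t = t[train]
        e_tr = _cross_fit_propensity(X[train], tr_t, max(2, folds - 1),
                                     seed + 100 + f)
        preds = {}
        for arm, w_arm in ((1, 1.0 / e_tr), (0, 1.0 / (1.0 - e_tr))):
            sel = tr_t == arm
            if sel.sum() < 5:  # degenerate arm: constant fallback
                mean = y[train][sel].mean() if sel.any() else y[train].mean()
                preds[arm] = np.full(len(test), mean)
            else:
                mdl = _make_gbdt(seed + 10 * (arm + 1) + f).fit(
                    X[train][sel], y[train][sel], sample_weight=w_arm[sel])
                preds[arm] = mdl.predict(X[test])
        e_te = e_hat[test]
        m_hat[test] = e_te * preds[1] + (1 - e_te) * preds[0]

    resid_t = t - e_hat
    w = resid_t**2
    psi = (y - m_hat) / resid_t
    tau_fn = _fit_tau(tau_learner, X, psi, w, ensemble_weights, seed)
    return TreatmentEffectModel(
        covariates=Z, ensemble_weights=ensemble_weights,
        tau_learner=tau_learner, X=X, y=y, t=t,
        e_hat=e_hat, m_hat=m_hat, seed=seed, _tau_fn=tau_fn,
    )


@dataclasses.dataclass(frozen=True)
class RScoreReport:
    r_loss: float
    baseline_loss: float
    r_score: float
    folds: int


def r_score(effect_model: TreatmentEffectModel, folds: int = 5) -> RScoreReport:
    """Cross-validated R score = 1 − L̂_R / L_base.

    Per fold, τ̂ is refit on the training part (with the model's own learner
    recipe and the stored cross-fitted nuisances) and the R-loss evaluated
    on the held-out part; the baseline replaces τ̂ by the training part's
    weighted constant treatment effect.  By construction a constant-effect
    model scores exactly 0.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y, t = effect_model.X, effect_model.y, effect_model.t
    e, m = effect_model.e_hat, effect_model.m_hat
    resid_t = t - e
    w = resid_t**2
    psi = (y - m) / resid_t
    kf = KFold(n_splits=folds, shuffle=True, random_state=effect_model.seed)
    lr_terms, lb_terms = [], []
    for train, test in kf.split(X):
        tau = _fit_tau(effect_model.tau_learner, X[train], psi[train],
                       w[train], effect_model.ensemble_weights,
                       effect_model.seed)
        const = _fit_tau("constant", X[train], psi[train], w[train],
                         effect_model.ensemble_weights, effect_model.seed)
        r = (y[test] - m[test]) - tau(X[test]) * resid_t[test]
        b = (y[test] - m[test]) - const(X[test]) * resid_t[test]
        lr_terms.append(r**2)
        lb_terms.append(b**2)
    l_r = float(np.mean(np.concatenate(lr_terms)))
    l_base = float(np.mean(np.concatenate(lb_terms)))
    if l_base == 0:
        warnings.warn("baseline R-loss is zero; R score undefined")
        return RScoreReport(l_r, l_base, float("nan"), folds)
    return RScoreReport(l_r, l_base, 1.0 - l_r / l_base, folds)


# -- confounded-unit attribution -------------------------------------------

def graph_with_outcome(g: CausalGraph, outcome: str = "Myopia",
                       parent: str = "CR") -> CausalGraph:
    """Append the model's outcome node as a child of CR.

    The myopia label is a deterministic function of CR, so the output node
    hangs off CR only; this makes treatment→outcome backdoor queries
    well-posed while keeping discovery on the feature table.
    """
    out = g.copy()
    out.add_node(outcome)
    out.add_directed(parent, outcome)
    return out


@dataclasses.dataclass(frozen=True)
class ConfoundedCurve:
    """Adjacent-group ACEs for a Confounded unit and one output class."""

    unit: str
    class_label: str
    strategy: str
    edges: np.ndarray
    ace: np.ndarray  # effect of moving group j -> j+1, length k-1
    r_scores: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        """Output-neuron trajectory benchmarked at 0: [0, Σ₁, Σ₂, …].

        Pairs whose ACE could not be estimated (NaN) contribute nothing.
        """
        return np.concatenate([[0.0], np.nancumsum(self.ace)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low": self.edges[:-2],
            "bin_high": self.edges[1:-1],
            "next_high": self.edges[2:],
            "ace": self.ace,
            "cumulative": self.cumulative[1:],
            "r_score": self.r_scores,
        })


def ace_confounded(predictor, cohort: CohortTable, g: CausalGraph,
                   unit: str, class_index: int,
                   strategy: str = "equal_width", k: int = 10,
                   ensemble_weights: tuple[float, float] = DEFAULT_ENSEMBLE_WEIGHTS,
                   folds: int = 5, seed: int = 0,
                   outcome: str = "Myopia",
                   use_probability: bool = True,
                   binning: Binning | None = None,
                   compute_r_scores: bool = False) -> ConfoundedCurve:
    """Backdoor-adjusted ACE between adjacent groups of a Confounded unit.

    The outcome is the trained classifier's class probability by default
    (``use_probability=False`` switches to the hard label).  The adjustment
    set is the unit's parents in the graph extended with the outcome node.
    """
    from .graph import UnitCategory, classify_units

    cats = classify_units(g, g.nodes & set(cohort.feature_names))
    if cats.get(unit) != UnitCategory.CONFOUNDED:
        raise ValueError(f"unit {unit!r} is not Confounded in the graph")
    gz = graph_with_outcome(g, outcome=outcome) if outcome not in g.nodes else g
    Z = sorted(backdoor_set(gz, unit, outcome))
    if not Z:
        raise ValueError(f"unit {unit!r} has an empty backdoor set")
    vals = cohort.frame[unit].to_numpy(dtype=float)
    if binning is None:
        binning = discretize(vals, strategy, k)
    bins = binning.assignment
    X = cohort.features.to_numpy(dtype=float)
    if use_probability:
        Y = predictor.predict_proba(X)[:, class_index]
    else:
        Y = (cohort.outcome == class_index).astype(float)

    aces, rss = [], []
    frame = cohort.features
    for j in range(binning.k - 1):
        mask = (bins == j) | (bins == j + 1)
        if not mask.any() or len(np.unique(bins[mask])) < 2:
            raise ValueError(f"empty adjacent group pair ({j}, {j + 1})")
        arm_sizes = ((bins[mask] == j).sum(), (bins[mask] == j + 1).sum())
        if min(arm_sizes) < 2:
            warnings.warn(
                f"group pair ({j}, {j + 1}) of {unit!r} has a degenerate "
                f"arm (sizes {arm_sizes}); ACE reported as NaN — consider "
                "equal_frequency binning or fewer groups"
            )
            aces.append(float("nan"))
            rss.append(float("nan"))
            continue
        model = fit_meta_learner(
            frame.loc[mask], (bins[mask] == j + 1).astype(int), Y[mask], Z,
            ensemble_weights=ensemble_weights, folds=folds,
            seed=seed + j,
        )
        aces.append(model.ate)
        rss.append(r_score(model).r_score if compute_r_scores else float("nan"))
    from .attribution import CLASS_LABELS
    return ConfoundedCurve(unit, CLASS_LABELS[class_index], binning.strategy,
                           np.asarray(binning.edges, float),
                           np.asarray(aces), np.asarray(rss))
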