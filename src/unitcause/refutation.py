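"""Falsification suite for causal-effect estimates.

Five perturbation strategies stress-test an estimator.  Relative strategies
(a valid estimate should be *stable*):

* **BV** — bootstrap validation: resample records with replacement;
* **ARCC** — add random common cause: append standard-normal noise
  covariates;
* **DSV** — data-subset validation: re-estimate on a random subsample;

with error rate |new − estimated| / |estimated|.  Absolute strategies (a
valid estimate should *vanish*):

* **PT** — placebo treatment: the treatment column is randomly permuted;
* **DO** — dummy outcome: the outcome column is replaced by standard-normal
  noise;

with error rate |new effect|.  An estimate passes when relative errors stay
below 10% and absolute placebo/dummy effects below 0.05 (both thresholds
configurable; the relative bar matches the published pass criterion, the
absolute bar is on the probability scale).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable

import numpy as np
import pandas as pd

__all__ = ["RefutationReport", "refute", "refutation_suite", "STRATEGIES"]

STRATEGIES = ("BV", "ARCC", "DSV", "PT", "DO")
RELATIVE_STRATEGIES = ("BV", "ARCC", "DSV")
DEFAULT_RELATIVE_THRESHOLD = 0.10
DEFAULT_ABSOLUTE_THRESHOLD = 0.05

#: estimator protocol: callable(frame: DataFrame, seed: int) -> float
Estimator = Callable[..., float]


@dataclasses.dataclass(frozen=True)
class RefutationReport:
    strategy: str
    estimated_effect: float
    new_effect: float  # mean over repetitions
    err: float
    repetitions: int
    threshold: float
    passed: bool
    undefined: bool = False  # relative error with a zero base estimate
    new_effects: tuple = ()  # per-repetition estimates

    @property
    def new_effect_se(self) -> float:
        """Standard error of the mean perturbed estimate."""
        arr = np.asarray(self.new_effects, float)
        if arr.size < 2:
            return float("nan")
        return float(arr.std(ddof=1) / np.sqrt(arr.size))

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _perturb(frame: pd.DataFrame, strategy: str, rng: np.random.Generator,
             treatment: str | None, outcome: str | None,
             frac: float, n_confounders: int) -> pd.DataFrame:
    n = len(frame)
    if strategy == "BV":
        idx = rng.integers(0, n, size=n)
        return frame.iloc[idx].reset_index(drop=True)
    if strategy == "ARCC":
        out = frame.copy()
        for j in range(n_confounders):
            out[f"_random_common_cause_{j}"] = rng.standard_normal(n)
        return out
    if strategy == "DSV":
        m = max(1, int(round(frac * n)))
        idx = rng.choice(n, size=m, replace=False)
        return frame.iloc[np.sort(idx)].reset_index(drop=True)
    if strategy == "PT":
        if treatment is None:
            raise ValueError("PT needs the treatment column name")
        out = frame.copy()
        out[treatment] = rng.permutation(out[treatment].to_numpy())
        return out
    if strategy == "DO":
        if outcome is None:
            raise ValueError("DO needs the outcome column name")
        out = frame.copy()
        out[outcome] = rng.standard_normal(n)
        return out
    raise ValueError(f"unknown strategy {strategy!r}")


def refute(estimator: Estimator, frame: pd.DataFrame, strategy: str,
           reps: int = 20, seed: int = 0,
           treatment: str | None = None, outcome: str | None = None,
           frac: float = 0.8, n_confounders: int = 1,
           relative_threshold: float = DEFAULT_RELATIVE_THRESHOLD,
           absolute_threshold: float = DEFAULT_ABSOLUTE_THRESHOLD
           ) -> RefutationReport:
    """Run one falsification strategy against an effect estimator.

    ``estimator(frame, seed)`` must return the effect deterministically for
    a fixed frame and seed.  The perturbed estimate is averaged over
    ``reps`` repetitions and converted to the strategy's error rate.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    estimated = float(estimator(frame, seed=int(rng.integers(2**31))))
    news = []
    for _ in range(reps):
        perturbed = _perturb(frame, strategy, rng, treatment, outcome,
                             frac, n_confounders)
        news.append(float(estimator(perturbed, seed=int(rng.integers(2**31)))))
    new_effect = float(np.mean(news))
    news_t = tuple(news)
    if strategy in RELATIVE_STRATEGIES:
        threshold = relative_threshold
        if estimated == 0.0:
            return RefutationReport(strategy, estimated, new_effect,
                                    float("nan"), reps, threshold,
                                    passed=False, undefined=True,
                                    new_effects=news_t)
        err = abs((new_effect - estimated) / estimated)
    else:
        threshold = absolute_threshold
        err = abs(new_effect)
    return RefutationReport(strategy, estimated, new_effect, float(err),
                            reps, threshold, passed=bool(err < threshold),
                            new_effects=news_t)


def refutation_suite(estimator: Estimator, frame: pd.DataFrame,
                     seed: int = 0, reps: int = 20,
                     treatment: str | None = None, outcome: str | None = None,
                     **kw) -> list[RefutationReport]:
    """All five falsification strategies with a shared seed stream."""
    root = np.random.default_rng(seed)
    reports = []
    for strategy in STRATEGIES:
        reports.append(refute(estimator, frame, strategy, reps=reps,
                              seed=int(root.integers(2**31)),
                              treatment=treatment, outcome=outcome, **kw))
    return reports


def suite_table(reports: Iterable[RefutationReport]) -> str:
    """Plain-text strategy × error table."""
    rows = []
    for r in reports:
        err = "undefined" if r.undefined else f"{100 * r.err:.2f}%"
        rows.append(f"{r.strategy:<5} est={r.estimated_effect:+.4f} "
                    f"new={r.new_effect:+.4f} err={err:<10} "
                    f"{'PASS' if r.passed else 'FAIL'}")
    return "\n".join(rows)
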