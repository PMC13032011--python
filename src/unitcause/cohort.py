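"""Synthetic pediatric-myopia cohorts with a known causal structure.

The real cohort behind this framework (a six-year school-based myopia study)
is not publicly deposited, so downstream stages are developed and tested
against cohorts drawn from a documented linear-Gaussian structural causal
model (SCM) that reproduces the published feature schema and causal skeleton:

* 16 features across behavioral, physiological, dietary, environmental and
  hereditary domains (10 continuous, 5 discrete/ordinal, 1 binary);
* six variables (PWG, GENDER, NAR, DAR, K1, K2) are direct causes of both
  axial length (AL) and cycloplegic refraction (CR); HEIGHT and REDM are
  direct causes of AL only; AL is a direct cause of CR — 15 directed edges
  over 10 connected variables;
* six variables (CB, EGG, NW, PULSE, WHIM, DTO) are causally isolated;
* the binary outcome is myopia, labelled by the rule CR ≤ −0.5 D.

Sources are sampled from documented marginals; children are linear in their
parents plus Gaussian noise (the framework's mediation analysis assumes
linear causal relationships, and the generator honours that exactly).  Range
soft-clipping is available but OFF by default, since clipping would break the
linear-Gaussian form the estimators rely on.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import CausalGraph

__all__ = [
    "VariableSpec",
    "GroundTruthSCM",
    "CohortTable",
    "TABLE1_SPECS",
    "FEATURE_NAMES",
    "OUTCOME_NAME",
    "MYOPIA_THRESHOLD_D",
    "default_myopia_scm",
    "generate_cohort",
    "label_myopia",
]

OUTCOME_NAME = "Myopia"
#: Myopia labelling rule: myopic iff cycloplegic refraction ≤ −0.5 diopters.
MYOPIA_THRESHOLD_D = -0.5


@dataclasses.dataclass(frozen=True)
class VariableSpec:
    """Schema entry for one cohort feature."""

    name: str
    kind: str  # {"continuous", "discrete_ordinal", "binary"}
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete_ordinal", "binary"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "binary":
            if (self.low, self.high) != (0, 1):
                raise ValueError("binary variables have {0,1} support")
        elif not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")


# Published feature schema.  The published range for K2 (38–183 mm) is
# physiologically implausible for corneal keratometry; the default spec uses
# a K1-like range instead.
TABLE1_SPECS: tuple[VariableSpec, ...] = (
    VariableSpec("CR", "continuous", -5.4, 8.7, "D"),
    VariableSpec("AL", "continuous", 20.0, 34.0, "mm"),
    VariableSpec("NW", "continuous", 0.0, 102.0, "h"),
    VariableSpec("DTO", "continuous", 0.0, 57.0, "h"),
    VariableSpec("NAR", "continuous", -5.1, 2.2, "D"),
    VariableSpec("DAR", "continuous", -6.6, 4.4, "D"),
    VariableSpec("HEIGHT", "continuous", 97.0, 143.0, "cm"),
    VariableSpec("PULSE", "continuous", 52.0, 140.0, "bpm"),
    VariableSpec("GENDER", "binary", 0, 1, ""),
    VariableSpec("CB", "discrete_ordinal", 1, 5, "times/week"),
    VariableSpec("EGG", "discrete_ordinal", 1, 4, "times/week"),
    VariableSpec("REDM", "discrete_ordinal", 1, 5, "times/week"),
    VariableSpec("WHIM", "discrete_ordinal", 1, 5, "times/week"),
    VariableSpec("PWG", "discrete_ordinal", 0, 2, "persons"),
    VariableSpec("K1", "continuous", 38.0, 71.0, "mm"),
    VariableSpec("K2", "continuous", 38.0, 71.0, "mm"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in TABLE1_SPECS)
_SPEC_BY_NAME: dict[str, VariableSpec] = {s.name: s for s in TABLE1_SPECS}


def label_myopia(cr):
    """Binary myopia label from cycloplegic refraction: 1 iff CR ≤ −0.5 D."""
    arr = np.asarray(cr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("CR values must be finite")
    out = (arr <= MYOPIA_THRESHOLD_D).astype(int)
    return int(out) if np.isscalar(cr) or arr.ndim == 0 else out


@dataclasses.dataclass(frozen=True)
class GroundTruthSCM:
    """Linear-Gaussian SCM over the cohort features.

    ``source_dists`` maps each parentless node to either
    ``("normal", mean, sd)`` or ``("categorical", values, probs)``.
    Children are ``intercept + Σ coeff·parent + N(0, noise_sd²)``.
    """

    graph: CausalGraph
    edge_coeff: Mapping[tuple[str, str], float]
    noise_sd: Mapping[str, float]
    intercepts: Mapping[str, float]
    source_dists: Mapping[str, tuple]

    def __post_init__(self) -> None:
        if not self.graph.is_finalized():
            raise ValueError("SCM graph must be a finalized DAG")
        for edge in self.graph.directed_edges:
            if edge not in self.edge_coeff:
                raise ValueError(f"edge {edge} has no coefficient")
        for node in self.graph.nodes:
            if self.graph.parents(node):
                if node not in self.noise_sd or self.noise_sd[node] <= 0:
                    raise ValueError(f"child {node!r} needs a positive noise sd")
            elif node not in self.source_dists:
                raise ValueError(f"source {node!r} needs a distribution")

    # -- SCM-implied algebra ----------------------------------------------
    def total_effect(self, src: str, dst: str) -> float:
        """Sum over directed paths of the product of edge coefficients."""
        from .graph import enumerate_paths

        if src == dst:
            return 1.0
        total = 0.0
        for path in enumerate_paths(self.graph, src, dst):
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= self.edge_coeff[(a, b)]
            total += prod
        return total

    def _source_moments(self, node: str) -> tuple[float, float]:
        kind, *rest = self.source_dists[node]
        if kind == "normal":
            mu, sd = rest
            return float(mu), float(sd) ** 2
        if kind == "categorical":
            values, probs = np.asarray(rest[0], float), np.asarray(rest[1], float)
            mu = float(values @ probs)
            return mu, float((values - mu) ** 2 @ probs)
        raise ValueError(f"unknown source distribution {kind!r}")

    def implied_moments(self) -> pd.DataFrame:
        """Exact mean and variance of every node under the SCM."""
        order = self.graph.topological_order()
        mean: dict[str, float] = {}
        # exogenous decomposition: node -> {exogenous term -> weight}
        weights: dict[str, dict[str, float]] = {}
        exo_var: dict[str, float] = {}
        for node in order:
            parents = self.graph.parents(node)
            if not parents:
                mu, var = self._source_moments(node)
                mean[node] = mu
                weights[node] = {f"src:{node}": 1.0}
                exo_var[f"src:{node}"] = var
            else:
                mean[node] = self.intercepts.get(node, 0.0) + sum(
                    self.edge_coeff[(p, node)] * mean[p] for p in parents
                )
                w: dict[str, float] = {f"eps:{node}": 1.0}
                exo_var[f"eps:{node}"] = self.noise_sd[node] ** 2
                for p in parents:
                    c = self.edge_coeff[(p, node)]
                    for term, wt in weights[p].items():
                        w[term] = w.get(term, 0.0) + c * wt
                weights[node] = w
        var = {
            node: sum(wt**2 * exo_var[term] for term, wt in weights[node].items())
            for node in order
        }
        return pd.DataFrame({"mean": mean, "var": var}).loc[list(order)]


def _default_source_dists() -> dict[str, tuple]:
    return {
        "NW": ("normal", 45.0, 15.0),
        "DTO": ("normal", 25.0, 9.0),
        "NAR": ("normal", -1.5, 1.0),
        "DAR": ("normal", -1.0, 1.4),
        "HEIGHT": ("normal", 120.0, 7.0),
        "PULSE": ("normal", 90.0, 12.0),
        "K1": ("normal", 43.5, 1.4),
        "K2": ("normal", 44.5, 1.6),
        "GENDER": ("categorical", (0, 1), (0.42, 0.58)),
        "CB": ("categorical", (1, 2, 3, 4, 5), (0.30, 0.30, 0.20, 0.12, 0.08)),
        "EGG": ("categorical", (1, 2, 3, 4), (0.20, 0.35, 0.30, 0.15)),
        "REDM": ("categorical", (1, 2, 3, 4, 5), (0.15, 0.25, 0.30, 0.20, 0.10)),
        "WHIM": ("categorical", (1, 2, 3, 4, 5), (0.15, 0.25, 0.30, 0.20, 0.10)),
        "PWG": ("categorical", (0, 1, 2), (0.45, 0.40, 0.15)),
    }


#: Default edge coefficients (natural units).  Signs follow the published
#: qualitative trends: longer eyes are more myopic (AL→CR negative), taller
#: children have longer eyes (HEIGHT→AL positive), parental myopia and male
#: gender lengthen AL, flatter corneas (larger K) shorten the optical path.
DEFAULT_EDGE_COEFF: dict[tuple[str, str], float] = {
    ("PWG", "AL"): 0.35,
    ("GENDER", "AL"): 0.30,
    ("NAR", "AL"): -0.20,
    ("DAR", "AL"): -0.15,
    ("K1", "AL"): -0.15,
    ("K2", "AL"): -0.12,
    ("HEIGHT", "AL"): 0.030,
    ("REDM", "AL"): 0.08,
    ("AL", "CR"): -0.90,
    ("PWG", "CR"): -0.30,
    ("GENDER", "CR"): -0.15,
    ("NAR", "CR"): -0.25,
    ("DAR", "CR"): -0.20,
    ("K1", "CR"): -0.20,
    ("K2", "CR"): -0.15,
}

#: Intercepts place AL near 23.8 mm and mean CR near −0.35 D, so roughly half
#: the cohort crosses the −0.5 D myopia threshold (both classes trainable).
DEFAULT_INTERCEPTS: dict[str, float] = {"AL": 31.0, "CR": 36.25}
DEFAULT_NOISE_SD: dict[str, float] = {"AL": 0.5, "CR": 0.6}


def default_myopia_scm() -> GroundTruthSCM:
    """The 15-edge ground-truth SCM emulating the published causal graph."""
    graph = CausalGraph(nodes=FEATURE_NAMES,
                        directed_edges=DEFAULT_EDGE_COEFF.keys())
    return GroundTruthSCM(
        graph=graph,
        edge_coeff=dict(DEFAULT_EDGE_COEFF),
        noise_sd=dict(DEFAULT_NOISE_SD),
        intercepts=dict(DEFAULT_INTERCEPTS),
        source_dists=_default_source_dists(),
    )


class CohortTable:
    """n records × 16 typed features plus the binary myopia outcome."""

    def __init__(self, frame: pd.DataFrame,
                 specs: Sequence[VariableSpec] = TABLE1_SPECS) -> None:
        specs = tuple(specs)
        expected = [s.name for s in specs] + [OUTCOME_NAME]
        missing = [c for c in expected if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort is missing columns: {missing}")
        frame = frame[expected].copy()
        if frame.isna().any().any():
            raise ValueError("cohort contains missing values")
        self.frame = frame
        self.specs = specs
        self.feature_names: tuple[str, ...] = tuple(s.name for s in specs)
        self.kinds: dict[str, str] = {s.name: s.kind for s in specs}

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[list(self.feature_names)]

    @property
    def outcome(self) -> np.ndarray:
        return self.frame[OUTCOME_NAME].to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, specs: Sequence[VariableSpec] = TABLE1_SPECS):
        return cls(pd.read_csv(path), specs)


def generate_cohort(scm: GroundTruthSCM, n: int, seed: int,
                    clip_to_ranges: bool = False) -> CohortTable:
    """Draw a cohort by ancestral sampling from the SCM.

    Sources come from their stated marginals; children are linear in their
    parents plus Gaussian noise; the outcome is labelled from CR.  The same
    seed always yields an identical table.  ``clip_to_ranges`` soft-clips
    columns into their schema ranges (off by default — clipping breaks the
    linear-Gaussian form the estimators assume).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = scm.graph.topological_order()
    cols: dict[str, np.ndarray] = {}
    for node in order:
        parents = scm.graph.parents(node)
        if not parents:
            kind, *rest = scm.source_dists[node]
            if kind == "normal":
                mu, sd = rest
                cols[node] = rng.normal(mu, sd, size=n)
            else:
                values, probs = rest
                cols[node] = rng.choice(np.asarray(values, float), size=n,
                                        p=np.asarray(probs, float))
        else:
            x = np.full(n, scm.intercepts.get(node, 0.0))
            for p in sorted(parents):
                x = x + scm.edge_coeff[(p, node)] * cols[p]
            cols[node] = x + rng.normal(0.0, scm.noise_sd[node], size=n)
    frame = pd.DataFrame({name: cols[name] for name in FEATURE_NAMES})
    if clip_to_ranges:
        for s in TABLE1_SPECS:
            frame[s.name] = frame[s.name].clip(s.low, s.high)
    frame[OUTCOME_NAME] = label_myopia(frame["CR"].to_numpy())
    return CohortTable(frame)


def write_scm(scm: GroundTruthSCM, edges_path, coeffs_path) -> None:
    """Write the SCM as an edge list plus a coefficients sidecar (TSV)."""
    from .graph import write_edgelist

    write_edgelist(scm.graph, edges_path)
    with open(coeffs_path, "w") as fh:
        fh.write("parent\tchild\tcoefficient\n")
        for (u, v), c in sorted(scm.edge_coeff.items()):
            fh.write(f"{u}\t{v}\t{c!r}\n")
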