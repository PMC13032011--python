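"""Constraint-based causal structure learning for mixed-type cohorts.

The pipeline is the classical PC algorithm with a conditional-independence
test suitable for mixed continuous/discrete data: each discrete variable is
one-hot embedded (reference level dropped), continuous variables are
standardized, and independence of two variables given a conditioning set is
judged by a Gaussian likelihood-ratio test between the embedded blocks — the
*degenerate Gaussian* likelihood-ratio test (DG-LRT).  Orientation follows
the standard two-stage recipe: unshielded colliders from the recorded
separating sets, then Meek rules R1–R4 to closure.

All iteration orders are lexicographic in variable names, so results are
reproducible on fixed data.

Notes on the test
-----------------
For blocks X, Y and conditioning block Z with joint (degenerate) Gaussian
model, the LR statistic ``2·(ll_full − ll_reduced)`` equals
``n·(log det R(Y|Z) − log det R(Y|Z∪X))`` where ``R(·|·)`` is a residual
covariance.  By the Schur determinant identity this is symmetric in X and Y,
so the two regression directions coincide; the symmetrized p-value (min of
the two directions with a Bonferroni factor of 2) therefore reduces to
doubling the one-sided p-value.  Degrees of freedom are
``dim(X block) × dim(Y block)``.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .graph import CausalGraph

__all__ = [
    "CITestResult",
    "SepsetRecord",
    "DegenerateInputError",
    "CollinearityError",
    "embed_mixed",
    "dg_likelihood_ratio_test",
    "DGTester",
    "pc_skeleton",
    "orient_v_structures",
    "apply_meek_rules",
    "discover",
]


class DegenerateInputError(ValueError):
    """A column is constant (zero variance) and cannot be embedded."""


class CollinearityError(np.linalg.LinAlgError):
    """The embedded design is singular beyond numerical tolerance."""


@dataclasses.dataclass(frozen=True)
class CITestResult:
    statistic: float
    dof: int
    p_value: float


@dataclasses.dataclass(frozen=True)
class SepsetRecord:
    pair: frozenset
    conditioning_set: frozenset
    p_value: float


def _coerce_frame(data) -> tuple[pd.DataFrame, dict[str, str]]:
    """Accept a CohortTable or DataFrame; return (features, kinds)."""
    if isinstance(data, CohortTable):
        return data.features, dict(data.kinds)
    frame = pd.DataFrame(data)
    kinds: dict[str, str] = {}
    for col in frame.columns:
        vals = frame[col].to_numpy(dtype=float)
        uniq = np.unique(vals)
        if len(uniq) <= 10 and np.allclose(uniq, np.round(uniq)):
            kinds[col] = "binary" if len(uniq) <= 2 else "discrete_ordinal"
        else:
            kinds[col] = "continuous"
    return frame, kinds


def embed_mixed(data, columns: Sequence[str] | None = None,
                kinds: Mapping[str, str] | None = None
                ) -> tuple[np.ndarray, dict[str, list[int]]]:
    """One-hot/standardized embedding of a mixed-type table.

    Continuous columns are standardized to mean 0 / SD 1; discrete or binary
    columns become one-hot indicators with the lowest level dropped as the
    reference.  Returns the design matrix and a map from each original
    column name to the indices of its embedded block.

    Raises :class:`DegenerateInputError` for constant columns.
    """
    frame, inferred = _coerce_frame(data)
    kinds = dict(inferred if kinds is None else kinds)
    if columns is None:
        columns = list(frame.columns)
    blocks: dict[str, list[int]] = {}
    mats: list[np.ndarray] = []
    j = 0
    for col in columns:
        vals = frame[col].to_numpy(dtype=float)
        uniq = np.unique(vals)
        if len(uniq) < 2:
            raise DegenerateInputError(f"column {col!r} is constant")
        if kinds.get(col, "continuous") == "continuous":
            sd = vals.std()
            mats.append(((vals - vals.mean()) / sd)[:, None])
            blocks[col] = [j]
            j += 1
        else:
            levels = uniq[1:]  # lowest level is the reference
            ind = (vals[:, None] == levels[None, :]).astype(float)
            mats.append(ind)
            blocks[col] = list(range(j, j + len(levels)))
            j += len(levels)
    return np.hstack(mats), blocks


class DGTester:
    """Degenerate-Gaussian CI tester over a fixed embedded dataset.

    Precomputes the embedded covariance matrix once; each test is then a
    small conditional-covariance (Schur complement) computation, independent
    of n.
    """

    def __init__(self, data, kinds: Mapping[str, str] | None = None,
                 columns: Sequence[str] | None = None) -> None:
        X, self.blocks = embed_mixed(data, columns=columns, kinds=kinds)
        self.n = X.shape[0]
        Xc = X - X.mean(axis=0)
        self.cov = (Xc.T @ Xc) / self.n
        self.columns = list(self.blocks)

    def _resid_logdet(self, target: list[int], given: list[int]
                      ) -> tuple[float, bool]:
        """Log-determinant of the residual covariance of target | given.

        Eigenvalues are floored at a tiny positive value so that an exactly
        deterministic dependence yields a huge (finite) LR statistic rather
        than −inf; the flag reports whether the floor was hit.
        """
        S = self.cov
        R = S[np.ix_(target, target)].copy()
        if given:
            Szz = S[np.ix_(given, given)]
            Szt = S[np.ix_(given, target)]
            try:
                R -= Szt.T @ np.linalg.solve(Szz, Szt)
            except np.linalg.LinAlgError:
                warnings.warn("singular conditioning block; using pseudo-inverse")
                R -= Szt.T @ np.linalg.pinv(Szz) @ Szt
        eig = np.linalg.eigvalsh((R + R.T) / 2.0)
        floor = 1e-12 * max(1.0, float(np.max(np.diag(self.cov))))
        floored = bool(np.any(eig < floor))
        return float(np.sum(np.log(np.maximum(eig, floor)))), floored

    def test(self, x: str, y: str, cond: Iterable[str] = ()) -> CITestResult:
        cond = sorted(set(cond))
        if x == y or x in cond or y in cond:
            raise ValueError("x, y and the conditioning set must be disjoint")
        bx, by = self.blocks[x], self.blocks[y]
        bz: list[int] = [i for c in cond for i in self.blocks[c]]
        dims = len(bx) + len(by) + len(bz)
        if self.n <= dims + 2:
            raise ValueError(
                f"n={self.n} too small for a test of embedded dimension {dims}"
            )
        ld_y_z, red1 = self._resid_logdet(by, bz)
        ld_y_zx, _ = self._resid_logdet(by, bz + bx)
        ld_x_z, red2 = self._resid_logdet(bx, bz)
        ld_x_zy, _ = self._resid_logdet(bx, bz + by)
        if red1 or red2:
            raise CollinearityError(
                "a tested block is already singular given the conditioning "
                "set; embedded design is collinear"
            )
        # the two regression directions; algebraically equal (see module doc)
        stat1 = self.n * (ld_y_z - ld_y_zx)
        stat2 = self.n * (ld_x_z - ld_x_zy)
        dof = len(bx) * len(by)
        p1 = stats.chi2.sf(max(stat1, 0.0), dof)
        p2 = stats.chi2.sf(max(stat2, 0.0), dof)
        p = min(1.0, 2.0 * min(p1, p2))
        return CITestResult(statistic=float(max(stat1, stat2, 0.0)),
                            dof=dof, p_value=float(p))


def dg_likelihood_ratio_test(data, x: str, y: str,
                             cond: Iterable[str] = (),
                             kinds: Mapping[str, str] | None = None
                             ) -> CITestResult:
    """One-shot DG-LRT of x ⊥ y | cond on a mixed-type table."""
    return DGTester(data, kinds=kinds).test(x, y, cond)


def pc_skeleton(data, alpha: float = 0.05,
                max_cond_size: int | None = None,
                kinds: Mapping[str, str] | None = None,
                tester: DGTester | None = None
                ) -> tuple[CausalGraph, dict[frozenset, SepsetRecord]]:
    """PC skeleton phase: prune a complete graph by CI tests.

    Conditioning sets of increasing size are drawn from the *current*
    adjacencies of each endpoint; an edge is removed at the first test with
    p ≥ alpha, and the separating set recorded.  Node and subset iteration is
    lexicographic, so the output is deterministic on fixed data.  Tests whose
    embedded dimension exceeds what n supports are skipped with a one-time
    warning (depth effectively capped by the data).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tester is None:
        tester = DGTester(data, kinds=kinds)
    cols = sorted(tester.columns)
    g = CausalGraph(cols)
    for a, b in itertools.combinations(cols, 2):
        g.add_undirected(a, b)
    sepsets: dict[frozenset, SepsetRecord] = {}
    insufficient = False

    depth = 0
    while True:
        if max_cond_size is not None and depth > max_cond_size:
            break
        any_testable = False
        for x in cols:
            for y in sorted(g.undirected_neighbors(x)):
                if not g.has_edge(x, y):
                    continue  # removed earlier in this sweep
                adj = sorted(g.undirected_neighbors(x) - {y})
                if len(adj) < depth:
                    continue
                any_testable = True
                removed = False
                for subset in itertools.combinations(adj, depth):
                    try:
                        res = tester.test(x, y, subset)
                    except ValueError:
                        insufficient = True
                        continue
                    if res.p_value >= alpha:
                        g.remove_edge(x, y)
                        sepsets[frozenset((x, y))] = SepsetRecord(
                            pair=frozenset((x, y)),
                            conditioning_set=frozenset(subset),
                            p_value=res.p_value,
                        )
                        removed = True
                        break
                if removed:
                    continue
        if not any_testable:
            break
        depth += 1
    if insufficient:
        warnings.warn(
            "sample size too small for some conditioning sets; search depth "
            "was capped by the data"
        )
    return g, sepsets


def orient_v_structures(skeleton: CausalGraph,
                        sepsets: Mapping[frozenset, SepsetRecord]
                        ) -> CausalGraph:
    """Orient unshielded colliders a→c←b from the recorded separating sets.

    For every unshielded triple a—c—b with a, b nonadjacent and c not in
    sepset(a, b), demand the orientations a→c and b→c.  Edges with
    conflicting demands (both directions requested) are left undirected.
    """
    g = skeleton.copy()
    demands: set[tuple[str, str]] = set()
    for c in sorted(g.nodes):
        nbrs = sorted(g.neighbors(c))
        for a, b in itertools.combinations(nbrs, 2):
            if g.has_edge(a, b):
                continue
            rec = sepsets.get(frozenset((a, b)))
            if rec is None:
                continue
            if c not in rec.conditioning_set:
                demands.add((a, c))
                demands.add((b, c))
    for a, c in sorted(demands):
        if (c, a) in demands:
            continue  # conflict: leave undirected
        if frozenset((a, c)) in {frozenset(e) for e in g.undirected_edges}:
            g.orient(a, c)
    return g


def _r1(g: CausalGraph) -> bool:
    for a, b in sorted(g.directed_edges):
        for c in sorted(g.undirected_neighbors(b)):
            if c != a and not g.has_edge(a, c):
                g.orient(b, c)
                return True
    return False


def _r2(g: CausalGraph) -> bool:
    for a, b in sorted(g.undirected_edges) + sorted(
            (b, a) for a, b in g.undirected_edges):
        if g.children(a) & g.parents(b):
            g.orient(a, b)
            return True
    return False


def _r3(g: CausalGraph) -> bool:
    for a, b in sorted(g.undirected_edges) + sorted(
            (b, a) for a, b in g.undirected_edges):
        into_b = g.parents(b) & g.undirected_neighbors(a)
        for c, d in itertools.combinations(sorted(into_b), 2):
            if not g.has_edge(c, d):
                g.orient(a, b)
                return True
    return False


def _r4(g: CausalGraph) -> bool:
    for a, b in sorted(g.undirected_edges) + sorted(
            (b, a) for a, b in g.undirected_edges):
        for c in sorted(g.undirected_neighbors(a)):
            if c == b or g.has_edge(c, b):
                continue
            for d in sorted(g.children(c) & g.parents(b)):
                if g.has_edge(a, d):
                    g.orient(a, b)
                    return True
    return False


def apply_meek_rules(pdag: CausalGraph) -> CausalGraph:
    """Meek rules R1–R4 applied to closure (idempotent, cycle-free)."""
    g = pdag.copy()
    changed = True
    while changed:
        changed = _r1(g) or _r2(g) or _r3(g) or _r4(g)
    if not g.is_acyclic():
        raise AssertionError("orientation produced a directed cycle")
    return g


def _pca_collinearity_screen(frame: pd.DataFrame,
                             kinds: Mapping[str, str],
                             threshold: float = 0.95) -> pd.DataFrame:
    """Replace groups of near-collinear continuous columns by PC scores.

    Groups are connected components of the |r| > threshold graph among the
    continuous columns; within a group each column is substituted by one
    orthogonal principal-component score (testing surrogate only — graph
    nodes keep the original names).
    """
    import networkx as nx

    cont = [c for c in frame.columns if kinds.get(c) == "continuous"]
    if len(cont) < 2:
        return frame
    corr = frame[cont].corr().abs().to_numpy()
    gg = nx.Graph()
    gg.add_nodes_from(cont)
    for i, j in itertools.combinations(range(len(cont)), 2):
        if corr[i, j] > threshold:
            gg.add_edge(cont[i], cont[j])
    out = frame.copy()
    for comp in nx.connected_components(gg):
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        block = frame[comp].to_numpy(dtype=float)
        block = (block - block.mean(axis=0)) / block.std(axis=0)
        _, _, vt = np.linalg.svd(block, full_matrices=False)
        scores = block @ vt.T
        for k, col in enumerate(comp):
            out[col] = scores[:, k]
    return out


def discover(data, alpha: float = 0.05, use_pca: bool = False,
             max_cond_size: int | None = None,
             kinds: Mapping[str, str] | None = None,
             return_details: bool = False):
    """Full discovery pipeline: embed → PC skeleton → colliders → Meek.

    Edges the rules cannot orient are reported as undirected rather than
    arbitrarily oriented.  With ``use_pca=True`` a collinearity screen
    replaces near-duplicate continuous columns by principal-component scores
    for testing only; the returned graph is always over the original names.
    """
    frame, inferred = _coerce_frame(data)
    kinds = dict(inferred if kinds is None else kinds)
    if use_pca:
        frame = _pca_collinearity_screen(frame, kinds)
    tester = DGTester(frame, kinds=kinds)
    skeleton, sepsets = pc_skeleton(frame, alpha=alpha,
                                    max_cond_size=max_cond_size,
                                    kinds=kinds, tester=tester)
    pdag = orient_v_structures(skeleton, sepsets)
    cpdag = apply_meek_rules(pdag)
    if cpdag.undirected_edges:
        warnings.warn(
            f"{len(cpdag.undirected_edges)} edge(s) could not be oriented and "
            "are reported undirected; they are excluded from path-based "
            "attribution"
        )
    if return_details:
        return cpdag, skeleton, sepsets
    return cpdag


def structural_hamming_distance(g: CausalGraph, truth: CausalGraph) -> int:
    """Edge-level edit distance: 1 per adjacency error, 1 per mis-orientation.

    An undirected edge where the truth has a directed one (or vice versa)
    counts as an orientation error.
    """
    def adj(x: CausalGraph) -> set[frozenset]:
        return ({frozenset(e) for e in x.directed_edges}
                | {frozenset(e) for e in x.undirected_edges})

    a, b = adj(g), adj(truth)
    shd = len(a ^ b)
    for pair in a & b:
        u, v = sorted(pair)
        ga = ("u" if (u, v) in g.undirected_edges
              else ("d" if (u, v) in g.directed_edges else "r"))
        tb = ("u" if (u, v) in truth.undirected_edges
              else ("d" if (u, v) in truth.directed_edges else "r"))
        if ga != tb:
            shd += 1
    return shd
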