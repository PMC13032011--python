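"""Causal-graph data model and identification machinery.

A :class:`CausalGraph` is a mixed graph over named variables: directed edges
for causal arrows and (optionally) undirected edges left over from
constraint-based discovery before full orientation.  A *finalized* graph is a
DAG with no undirected edges; only finalized graphs may be used for
identification queries (unit classification, d-separation, backdoor sets).

Input units of a classifier are partitioned into three structural categories
relative to the causal graph over its input features:

* **Isolated** — no causal relation to any other input (degree 0);
* **Pure** — influences other inputs only downstream (children but no
  parents), so every effect on the output is direct or mediated;
* **Confounded** — has at least one parent among the inputs, so a backdoor
  path through that parent exists and adjustment is required.

Any parented node is Confounded regardless of whether it also has children
(precedence Confounded > Pure > Isolated).
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "CausalGraph",
    "UnitCategory",
    "classify_units",
    "enumerate_paths",
    "d_separated",
    "backdoor_set",
    "read_edgelist",
    "write_edgelist",
]


class UnitCategory(str, enum.Enum):
    """Structural role of an input unit in the causal graph."""

    ISOLATED = "Isolated"
    PURE = "Pure"
    CONFOUNDED = "Confounded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class GraphNotFinalizedError(ValueError):
    """Raised when an identification query is run on a non-finalized graph."""


class CausalGraph:
    """Mixed causal graph: directed + undirected edges over named nodes.

    Parameters
    ----------
    nodes
        Iterable of node names.  Nodes mentioned in edges are added
        automatically.
    directed_edges
        Iterable of ``(parent, child)`` pairs.
    undirected_edges
        Iterable of unordered pairs; present only in CPDAG intermediates.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        directed_edges: Iterable[tuple[str, str]] = (),
        undirected_edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        self._nodes: set[str] = set(nodes)
        self._directed: set[tuple[str, str]] = set()
        self._undirected: set[frozenset[str]] = set()
        for u, v in directed_edges:
            self.add_directed(u, v)
        for u, v in undirected_edges:
            self.add_undirected(u, v)

    # -- construction -----------------------------------------------------
    def add_node(self, name: str) -> None:
        self._nodes.add(name)

    def add_directed(self, parent: str, child: str) -> None:
        if parent == child:
            raise ValueError(f"self-loop on {parent!r}")
        if frozenset((parent, child)) in self._undirected:
            raise ValueError(f"{parent!r}-{child!r} already present as undirected")
        self._nodes.update((parent, child))
        self._directed.add((parent, child))

    def add_undirected(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if (a, b) in self._directed or (b, a) in self._directed:
            raise ValueError(f"{a!r}-{b!r} already present as directed")
        self._nodes.update((a, b))
        self._undirected.add(frozenset((a, b)))

    def orient(self, a: str, b: str) -> None:
        """Replace the undirected edge a—b by the arrow a→b."""
        key = frozenset((a, b))
        if key not in self._undirected:
            raise ValueError(f"no undirected edge {a!r}-{b!r}")
        self._undirected.discard(key)
        self._directed.add((a, b))

    def remove_edge(self, a: str, b: str) -> None:
        self._directed.discard((a, b))
        self._directed.discard((b, a))
        self._undirected.discard(frozenset((a, b)))

    def copy(self) -> "CausalGraph":
        return CausalGraph(self._nodes, self._directed,
                           (tuple(sorted(e)) for e in self._undirected))

    # -- accessors ---------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._nodes)

    @property
    def directed_edges(self) -> set[tuple[str, str]]:
        return set(self._directed)

    @property
    def undirected_edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self._undirected}

    def has_edge(self, a: str, b: str) -> bool:
        """Adjacency in the mixed graph (either direction or undirected)."""
        return ((a, b) in self._directed or (b, a) in self._directed
                or frozenset((a, b)) in self._undirected)

    def parents(self, node: str) -> set[str]:
        return {u for (u, v) in self._directed if v == node}

    def children(self, node: str) -> set[str]:
        return {v for (u, v) in self._directed if u == node}

    def neighbors(self, node: str) -> set[str]:
        out = self.parents(node) | self.children(node)
        for e in self._undirected:
            if node in e:
                out.update(e - {node})
        return out

    def undirected_neighbors(self, node: str) -> set[str]:
        out: set[str] = set()
        for e in self._undirected:
            if node in e:
                out.update(e - {node})
        return out

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))

    # -- structure queries -------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self._nodes))
        g.add_edges_from(sorted(self._directed))
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def is_finalized(self) -> bool:
        return not self._undirected and self.is_acyclic()

    def require_finalized(self) -> None:
        if not self.is_finalized():
            raise GraphNotFinalizedError(
                "graph has undirected edges or a directed cycle; finalize "
                "orientation before identification queries"
            )

    def topological_order(self) -> list[str]:
        self.require_finalized()
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def ancestors(self, node: str) -> set[str]:
        return set(nx.ancestors(self.to_networkx(), node))

    def descendants(self, node: str) -> set[str]:
        return set(nx.descendants(self.to_networkx(), node))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        return (self._nodes == other._nodes
                and self._directed == other._directed
                and self._undirected == other._undirected)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CausalGraph({len(self._nodes)} nodes, "
                f"{len(self._directed)} directed, "
                f"{len(self._undirected)} undirected)")


def classify_units(g: CausalGraph, inputs: Iterable[str]) -> dict[str, UnitCategory]:
    """Partition input units into Isolated / Pure / Confounded.

    ``Confounded`` takes precedence: any unit with a parent among the inputs
    has an open backdoor path and must be adjusted; a unit with children but
    no parents is ``Pure``; a degree-0 unit is ``Isolated``.
    """
    g.require_finalized()
    inputs = list(inputs)
    missing = set(inputs) - g.nodes
    if missing:
        raise KeyError(f"inputs not in graph: {sorted(missing)}")
    input_set = set(inputs)
    out: dict[str, UnitCategory] = {}
    for unit in inputs:
        parents_within = g.parents(unit) & input_set
        children_within = g.children(unit) & input_set
        if parents_within:
            out[unit] = UnitCategory.CONFOUNDED
        elif children_within:
            out[unit] = UnitCategory.PURE
        else:
            out[unit] = UnitCategory.ISOLATED
    return out


def enumerate_paths(g: CausalGraph, src: str, dst: str) -> list[list[str]]:
    """All distinct directed paths src→…→dst, lexicographically ordered.

    ``src == dst`` yields the single trivial path ``[src]``.
    """
    for name in (src, dst):
        if name not in g.nodes:
            raise KeyError(f"node {name!r} not in graph")
    if src == dst:
        return [[src]]
    paths: list[list[str]] = []

    def _dfs(node: str, trail: list[str]) -> None:
        if node == dst:
            paths.append(list(trail))
            return
        for child in sorted(g.children(node)):
            if child not in trail:  # DAG, but keep DFS safe
                trail.append(child)
                _dfs(child, trail)
                trail.pop()

    _dfs(src, [src])
    return sorted(paths)


def d_separated(g: CausalGraph, a: str, b: str, cond: Iterable[str] = ()) -> bool:
    """Standard d-separation verdict for a pair given a conditioning set."""
    g.require_finalized()
    cond = set(cond)
    if a == b:
        raise ValueError("a and b must differ")
    if a in cond or b in cond:
        raise ValueError("endpoints may not appear in the conditioning set")
    missing = ({a, b} | cond) - g.nodes
    if missing:
        raise KeyError(f"nodes not in graph: {sorted(missing)}")
    return nx.is_d_separator(g.to_networkx(), {a}, {b}, cond)


def backdoor_set(g: CausalGraph, treatment: str, outcome: str) -> set[str]:
    """Backdoor adjustment set for treatment→outcome: the treatment's parents.

    In a DAG without latent variables the parent set always satisfies the
    backdoor criterion; this is verified by d-separation on the graph with the
    treatment's outgoing edges removed.  Raises if the outcome is an ancestor
    of the treatment (the causal effect is then zero/undefined as a query).
    """
    g.require_finalized()
    if treatment == outcome:
        raise ValueError("treatment and outcome must differ")
    missing = {treatment, outcome} - g.nodes
    if missing:
        raise KeyError(f"nodes not in graph: {sorted(missing)}")
    if outcome in g.ancestors(treatment):
        raise ValueError(
            f"{outcome!r} is an ancestor of {treatment!r}: effect query invalid"
        )
    z = g.parents(treatment)
    pruned = CausalGraph(
        g.nodes,
        {(u, v) for (u, v) in g.directed_edges if u != treatment},
    )
    if outcome not in (z | {treatment}) and not d_separated(pruned, treatment, outcome, z):
        raise AssertionError(
            "parent set failed the backdoor check; graph is not a DAG over "
            "observed variables"
        )
    return z


# -- edge-list round-tripping ---------------------------------------------

def write_edgelist(g: CausalGraph, path, orientation_column: bool = False) -> None:
    """Write tab-separated ``parent\\tchild`` lines (sorted, reproducible).

    With ``orientation_column=True`` a third column {directed, undirected} is
    added and undirected edges are included.
    """
    with open(path, "w") as fh:
        for u, v in sorted(g.directed_edges):
            fh.write(f"{u}\t{v}\tdirected\n" if orientation_column else f"{u}\t{v}\n")
        if orientation_column:
            for u, v in sorted(g.undirected_edges):
                fh.write(f"{u}\t{v}\tundirected\n")


def write_graphml(g: CausalGraph, path) -> None:
    """GraphML export for external viewers (directed edges only)."""
    nx.write_graphml(g.to_networkx(), path)


def read_edgelist(path, nodes: Iterable[str] = ()) -> CausalGraph:
    """Read a graph written by :func:`write_edgelist`."""
    g = CausalGraph(nodes)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2 or parts[2] == "directed":
                g.add_directed(parts[0], parts[1])
            elif parts[2] == "undirected":
                g.add_undirected(parts[0], parts[1])
            else:
                raise ValueError(f"bad orientation field {parts[2]!r}")
    return g
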