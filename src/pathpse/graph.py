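"""Causal DAGs, directed-path enumeration, and per-edge adjustment sets.

A path-specific effect targets one directed path X1 -> X2 -> ... -> Y in a
causal diagram.  Under the local Markov property each node on the path is
confounded with its on-path parent only through the remaining parents of the
child, so the back-door adjustment set for an edge (A, B) is parents(B) \\ {A}.
This module owns the graph representation, path enumeration between an
exposure and an outcome, derivation of the per-edge adjustment plan, and the
structural simplification rule that drops variables with no directed route
into the path or its adjustment sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "CausalDAG",
    "SpecificPath",
    "AdjustmentPlan",
    "GraphError",
    "CycleError",
    "parse_graph",
    "read_graph",
    "enumerate_paths",
    "adjustment_sets",
    "simplify",
]

VAR_KINDS = ("binary", "discrete", "continuous")


class GraphError(ValueError):
    """Invalid graph structure or lookup."""


class CycleError(GraphError):
    """The declared edges contain a directed cycle."""


@dataclass(frozen=True)
class CausalDAG:
    """A directed acyclic graph over named variables.

    Parameters
    ----------
    nodes : ordered tuple of variable names (deterministic order:
        lexicographic within topological generations).
    edges : tuple of (parent, child) pairs.
    var_kind : mapping node -> {"binary", "discrete", "continuous"}.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    var_kind: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_g", self._build())

    def _build(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def nx(self) -> nx.DiGraph:
        return self._g

    def parents(self, node: str) -> tuple[str, ...]:
        self._check(node)
        return tuple(sorted(self._g.predecessors(node)))

    def children(self, node: str) -> tuple[str, ...]:
        self._check(node)
        return tuple(sorted(self._g.successors(node)))

    def kind(self, node: str) -> str:
        self._check(node)
        return self.var_kind.get(node, "continuous")

    def has_edge(self, parent: str, child: str) -> bool:
        return self._g.has_edge(parent, child)

    def topological_order(self) -> tuple[str, ...]:
        return tuple(nx.lexicographical_topological_sort(self._g))

    def _check(self, node: str) -> None:
        if node not in self._g:
            raise GraphError(f"unknown node {node!r}")

    def __contains__(self, node: str) -> bool:
        return node in self._g


@dataclass(frozen=True)
class SpecificPath:
    """An ordered directed path [X1, ..., XK, Y] through a DAG."""

    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise GraphError("a specific path needs at least two nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphError("path nodes must be distinct (paths are simple)")

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.nodes[:-1], self.nodes[1:]))

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def sink(self) -> str:
        return self.nodes[-1]

    def validate(self, dag: CausalDAG) -> None:
        for a, b in self.edges:
            if not dag.has_edge(a, b):
                raise GraphError(f"path edge {a}->{b} is not an edge of the DAG")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return " -> ".join(self.nodes)


@dataclass(frozen=True)
class AdjustmentPlan:
    """Per-edge back-door covariate sets for one specific path.

    ``per_edge[(A, B)]`` is the sorted tuple parents(B) \\ {A}; ``confounders``
    is the union over all edges.
    """

    per_edge: Mapping[tuple[str, str], tuple[str, ...]]

    @property
    def confounders(self) -> tuple[str, ...]:
        out: set[str] = set()
        for cov in self.per_edge.values():
            out.update(cov)
        return tuple(sorted(out))

    def covariates(self, edge: tuple[str, str]) -> tuple[str, ...]:
        return self.per_edge[edge]


def parse_graph(
    edge_records: Iterable[tuple[str, str]],
    var_kinds: Mapping[str, str] | None = None,
    extra_nodes: Iterable[str] = (),
) -> CausalDAG:
    """Validate an edge list into a :class:`CausalDAG`.

    Node order is deterministic: lexicographic refinement of a topological
    order.  Raises :class:`CycleError` naming one cycle if the edges are not
    acyclic, and :class:`GraphError` on duplicate edges, self-loops or empty
    names.
    """
    var_kinds = dict(var_kinds or {})
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for rec in edge_records:
        a, b = rec
        if not isinstance(a, str) or not isinstance(b, str) or not a or not b:
            raise GraphError(f"edge endpoints must be non-empty strings, got {rec!r}")
        if a == b:
            raise GraphError(f"self-loop {a}->{b} is not allowed")
        if (a, b) in seen:
            raise GraphError(f"duplicate edge {a}->{b}")
        seen.add((a, b))
        edges.append((a, b))

    g = nx.DiGraph()
    for n in extra_nodes:
        g.add_node(n)
    g.add_edges_from(edges)
    try:
        order = tuple(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        pretty = " -> ".join([cycle[0][0]] + [e[1] for e in cycle])
        raise CycleError(f"edge list contains a cycle: {pretty}") from None

    for k, v in var_kinds.items():
        if v not in VAR_KINDS:
            raise GraphError(f"unknown variable kind {v!r} for node {k!r}")
    return CausalDAG(nodes=order, edges=tuple(edges), var_kind=var_kinds)


def read_graph(path: str | Path, kinds_path: str | Path | None = None) -> CausalDAG:
    """Read a two-column (tab/comma separated) edge-list file.

    Lines starting with ``#`` are comments; an optional header line
    ``parent<sep>child`` is skipped.  Variable kinds may come from a sidecar
    JSON file mapping node name -> kind (default continuous).
    """
    records: list[tuple[str, str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 2:
            raise GraphError(f"cannot parse edge line {raw!r}")
        if parts[0].lower() == "parent" and parts[1].lower() == "child":
            continue
        records.append((parts[0], parts[1]))
    kinds = None
    if kinds_path is not None:
        kinds = json.loads(Path(kinds_path).read_text())
    return parse_graph(records, var_kinds=kinds)


def adjustment_sets(dag: CausalDAG, path: SpecificPath) -> AdjustmentPlan:
    """Back-door adjustment plan: for each path edge (A, B), parents(B) \\ {A}."""
    path.validate(dag)
    per_edge = {
        (a, b): tuple(sorted(set(dag.parents(b)) - {a})) for a, b in path.edges
    }
    return AdjustmentPlan(per_edge=per_edge)


def enumerate_paths(
    dag: CausalDAG,
    source: str,
    sink: str,
    max_paths: int | None = None,
) -> list[tuple[SpecificPath, AdjustmentPlan]]:
    """All simple directed paths source -> sink with their adjustment plans.

    Ordered deterministically: shortest first, ties broken lexicographically
    on the node sequence.  ``max_paths`` (optional) raises once exceeded.
    """
    dag._check(source)
    dag._check(sink)
    if source == sink:
        raise GraphError("source and sink must differ")
    raw = list(nx.all_simple_paths(dag.nx, source, sink))
    if max_paths is not None and len(raw) > max_paths:
        raise GraphError(
            f"{len(raw)} paths from {source} to {sink} exceed max_paths={max_paths}"
        )
    raw.sort(key=lambda p: (len(p), p))
    out = []
    for p in raw:
        sp = SpecificPath(tuple(p))
        out.append((sp, adjustment_sets(dag, sp)))
    return out


def simplify(dag: CausalDAG, path: SpecificPath) -> CausalDAG:
    """Drop variables irrelevant to one specific path.

    A node is kept iff it has a directed route into some node on the path or
    into some node of the path's adjustment sets (itself included).  Removed
    nodes cannot open a back-door into the path, so the path estimand is
    unchanged on the reduced graph.
    """
    path.validate(dag)
    plan = adjustment_sets(dag, path)
    targets = set(path.nodes) | set(plan.confounders)
    keep: set[str] = set()
    for t in targets:
        keep.add(t)
        keep.update(nx.ancestors(dag.nx, t))
    nodes = tuple(n for n in dag.nodes if n in keep)
    edges = tuple((a, b) for a, b in dag.edges if a in keep and b in keep)
    kinds = {n: k for n, k in dag.var_kind.items() if n in keep}
    return CausalDAG(nodes=nodes, edges=edges, var_kind=kinds)
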