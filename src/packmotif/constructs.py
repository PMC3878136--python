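"""Structure-relationship graphs: structures and SCs as nodes, containment as edges.

The diagram has a strict vertical hierarchy -- 0D constructs at the bottom, then
1D, 2D, 3D, and the crystal structures on top.  A directed edge runs from the
contained element to the containing one, so following edges upward from an SC
node enumerates every structure that exhibits it, and the meet of two structure
nodes (following edges downward) is their highest-level common construct.  Only
covering relations are kept (transitive edges are removed), mirroring the usual
minimal drawing of such diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .similarity import SupramolecularConstruct

__all__ = ["RelationshipGraph", "build_graph", "ancestors_of",
           "common_constructs", "to_dot"]

STRUCTURE_LEVEL = 4


@dataclass
class RelationshipGraph:
    """A DAG over SC ids and structure ids, with a level per node."""

    graph: nx.DiGraph
    levels: dict[str, int]

    @property
    def nodes(self):
        return sorted(self.graph.nodes)

    @property
    def edges(self):
        return sorted(self.graph.edges)

    def is_structure(self, node: str) -> bool:
        return self.levels[node] == STRUCTURE_LEVEL

    def validate(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("relationship graph contains a cycle")
        for a, b in self.graph.edges:
            if self.levels[a] >= self.levels[b]:
                raise ValueError(f"edge {a}->{b} violates the level hierarchy")
        for node in self.graph.nodes:
            if not self.is_structure(node):
                reached = {n for n in nx.descendants(self.graph, node)
                           if self.is_structure(n)}
                if len(reached) < 2:
                    raise ValueError(
                        f"SC {node} connects {len(reached)} structures (needs >= 2)")

    def to_adjacency(self) -> dict:
        return {
            "nodes": [{"id": n, "level": self.levels[n]} for n in self.nodes],
            "edges": [{"from": a, "to": b} for a, b in self.edges],
        }


def build_graph(constructs: list[SupramolecularConstruct],
                structure_ids: list[str]) -> RelationshipGraph:
    """Build the relationship diagram from an SC list.

    Containment edges (sub-construct -> construct) and membership edges
    (construct -> structure) are transitively reduced to covering relations.
    Raises ``ValueError`` for an SC with fewer than two member structures.
    """
    g = nx.DiGraph()
    levels: dict[str, int] = {}
    for sid in structure_ids:
        g.add_node(sid)
        levels[sid] = STRUCTURE_LEVEL
    for sc in constructs:
        if sc.n_structures < 2:
            raise ValueError(
                f"SC {sc.sc_id} has {sc.n_structures} member(s); a construct "
                "must connect at least two structures")
        g.add_node(sc.sc_id)
        levels[sc.sc_id] = sc.dimensionality
    for sc in constructs:
        for sub in sc.sub_constructs:
            g.add_edge(sub, sc.sc_id)
        for member in sc.members:
            g.add_edge(sc.sc_id, member)
    reduced = nx.transitive_reduction(g)
    out = RelationshipGraph(graph=reduced, levels=levels)
    out.validate()
    return out


def ancestors_of(graph: RelationshipGraph, node: str):
    """Upward closure: every element that contains ``node`` (directly or not).

    For an SC this includes the structures exhibiting it.
    """
    if node not in graph.graph:
        raise KeyError(f"unknown node {node!r}")
    return set(nx.descendants(graph.graph, node))


def common_constructs(graph: RelationshipGraph, *nodes: str):
    """Meet of several structures: their maximal common constructs.

    Follows the branches radiating downward from each query node and returns
    the highest-level common elements (those not contained in another common
    element).  Empty set when the structures share nothing.
    """
    common = None
    for node in nodes:
        if node not in graph.graph:
            raise KeyError(f"unknown node {node!r}")
        down = set(nx.ancestors(graph.graph, node))
        common = down if common is None else common & down
    common = common or set()
    maximal = {c for c in common
               if not any(other in nx.descendants(graph.graph, c)
                          for other in common)}
    return maximal


def to_dot(graph: RelationshipGraph) -> str:
    """Deterministic DOT serialization with one rank per hierarchy level."""
    lines = ["digraph relationships {", "  rankdir=BT;"]
    by_level: dict[int, list[str]] = {}
    for n in graph.nodes:
        by_level.setdefault(graph.levels[n], []).append(n)
    for level in sorted(by_level):
        label = "structures" if level == STRUCTURE_LEVEL else f"{level}D"
        lines.append(f'  subgraph "rank_{label}" {{ rank=same; '
                     + " ".join(f'"{n}";' for n in sorted(by_level[level]))
                     + " }")
    for a, b in graph.edges:
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
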