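"""Partial ancestral graph container.

Each edge carries one endpoint mark per side: ``TAIL``, ``ARROW`` or
``CIRCLE``, encoding the four edge types ``->``, ``<->``, ``o->`` and
``o-o`` (plus the fully undirected ``--``).  Separation sets found during
the adjacency search are stored alongside.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

__all__ = ["Endpoint", "PAG"]


class Endpoint(Enum):
    TAIL = "-"
    ARROW = ">"
    CIRCLE = "o"


class PAG:
    """Mixed graph with three-valued endpoint marks."""

    def __init__(self, nodes: Iterable[str]):
        self.nodes: List[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        # edge key: tuple(sorted((u, v))); value: {u: mark at u, v: mark at v}
        self._edges: Dict[Tuple[str, str], Dict[str, Endpoint]] = {}
        self.sepsets: Dict[FrozenSet[str], Set[str]] = {}

    # -- structure ----------------------------------------------------------

    @staticmethod
    def _key(u: str, v: str) -> Tuple[str, str]:
        if u == v:
            raise ValueError("self-edges are not allowed")
        return (u, v) if u < v else (v, u)

    def add_edge(self, u: str, v: str,
                 mark_u: Endpoint = Endpoint.CIRCLE,
                 mark_v: Endpoint = Endpoint.CIRCLE) -> None:
        self._edges[self._key(u, v)] = {u: mark_u, v: mark_v}

    def remove_edge(self, u: str, v: str) -> None:
        self._edges.pop(self._key(u, v), None)

    def has_edge(self, u: str, v: str) -> bool:
        return self._key(u, v) in self._edges

    def adjacent(self, u: str) -> Set[str]:
        out = set()
        for (a, b) in self._edges:
            if a == u:
                out.add(b)
            elif b == u:
                out.add(a)
        return out

    def edges(self) -> List[Tuple[str, str]]:
        return list(self._edges)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    # -- marks --------------------------------------------------------------

    def mark(self, u: str, v: str) -> Endpoint:
        """Endpoint mark at ``v`` on the edge u-v (the mark 'pointing into' v)."""
        return self._edges[self._key(u, v)][v]

    def set_mark(self, u: str, v: str, mark: Endpoint) -> None:
        self._edges[self._key(u, v)][v] = mark

    def edge_type(self, u: str, v: str) -> str:
        """Render the edge as seen from ``u`` to ``v`` (e.g. '->', 'o->')."""
        left = self._edges[self._key(u, v)][u]
        right = self._edges[self._key(u, v)][v]
        lsym = {Endpoint.TAIL: "-", Endpoint.ARROW: "<", Endpoint.CIRCLE: "o"}[left]
        rsym = {Endpoint.TAIL: "-", Endpoint.ARROW: ">", Endpoint.CIRCLE: "o"}[right]
        return f"{lsym}-{rsym}"

    def is_arrow(self, u: str, v: str) -> bool:
        """True when the u-v edge has an arrowhead at v."""
        return self.has_edge(u, v) and self.mark(u, v) is Endpoint.ARROW

    def is_directed(self, u: str, v: str) -> bool:
        """True for u -> v (tail at u, arrow at v)."""
        return (self.has_edge(u, v)
                and self.mark(v, u) is Endpoint.TAIL
                and self.mark(u, v) is Endpoint.ARROW)

    # -- serialization ------------------------------------------------------

    def skeleton(self) -> Set[FrozenSet[str]]:
        return {frozenset(k) for k in self._edges}

    def to_edge_records(self) -> List[dict]:
        recs = []
        for (a, b), marks in sorted(self._edges.items()):
            recs.append({
                "node1": a, "node2": b,
                "mark1": marks[a].name.lower(),
                "mark2": marks[b].name.lower(),
                "type": self.edge_type(a, b),
            })
        return recs

    def to_json(self, path=None) -> Optional[str]:
        payload = {
            "nodes": self.nodes,
            "edges": self.to_edge_records(),
            "sepsets": [{"pair": sorted(k), "sepset": sorted(v)}
                        for k, v in sorted(self.sepsets.items(),
                                           key=lambda kv: sorted(kv[0]))],
        }
        text = json.dumps(payload, indent=2)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def to_networkx(self):
        """Export as an undirected networkx graph with mark attributes."""
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for rec in self.to_edge_records():
            g.add_edge(rec["node1"], rec["node2"], mark1=rec["mark1"],
                       mark2=rec["mark2"], type=rec["type"])
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx
        nx.write_graphml(self.to_networkx(), path)
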