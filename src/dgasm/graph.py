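"""Bidirected string graph container.

Nodes are reads, unitigs or integer sequences; every edge is a dovetail
overlap between oriented node ends. An arc (a, ao) -> (b, bo) and its twin
(b, ~bo) -> (a, ~ao) are two statements of one bidirected edge; the edge is
stored under a canonical key so per-edge attributes (overlap length,
ultra-long support) exist exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Hashable, Iterator, Optional

from .errors import ConsistencyError

Orient = str  # '+' or '-'


def flip(o: Orient) -> Orient:
    return "-" if o == "+" else "+"


@dataclass
class Member:
    """A read placed inside a unitig (forward unitig coordinates)."""

    read_id: Hashable
    orient: Orient
    start: int
    end: int
    contained: bool = False


@dataclass
class Node:
    id: Hashable
    length: int
    seq: Optional[str] = None
    contained: bool = False
    members: Optional[list[Member]] = None
    payload: Any = None  # e.g. oriented unitig elements for integer-space nodes
    origin: Optional[str] = None  # 'contig' | 'residual' in merged graphs


def edge_key(a: Hashable, ao: Orient, b: Hashable, bo: Orient):
    """Canonical identity of the bidirected edge containing arc (a,ao)->(b,bo)."""
    s1 = (str(a), ao, str(b), bo)
    s2 = (str(b), flip(bo), str(a), flip(ao))
    return (a, ao, b, bo) if s1 <= s2 else (b, flip(bo), a, flip(ao))


class StringGraph:
    def __init__(self) -> None:
        self.nodes: dict[Hashable, Node] = {}
        self._out: dict[tuple[Hashable, Orient], dict[tuple[Hashable, Orient], int]] = {}
        self._support: dict[tuple, int] = {}
        self.metadata: dict[str, Any] = {}

    # -- construction -------------------------------------------------------
    def add_node(self, node_id, length=None, seq=None, contained=False,
                 members=None, payload=None, origin=None) -> Node:
        if length is None:
            if seq is None:
                raise ValueError("node needs a length or a sequence")
            length = len(seq)
        node = Node(node_id, length, seq, contained, members, payload, origin)
        self.nodes[node_id] = node
        self._out.setdefault((node_id, "+"), {})
        self._out.setdefault((node_id, "-"), {})
        return node

    def add_edge(self, a, ao: Orient, b, bo: Orient, overlap_len: int) -> None:
        for n in (a, b):
            if n not in self.nodes:
                raise ConsistencyError(f"edge references unknown node {n!r}")
        if overlap_len >= min(self.nodes[a].length, self.nodes[b].length) and a != b:
            raise ConsistencyError(
                f"overlap {overlap_len} not shorter than nodes {a!r},{b!r}")
        self._out[(a, ao)][(b, bo)] = overlap_len
        self._out[(b, flip(bo))][(a, flip(ao))] = overlap_len
        self._support.setdefault(edge_key(a, ao, b, bo), 0)

    # -- queries ------------------------------------------------------------
    def has_node(self, node_id) -> bool:
        return node_id in self.nodes

    def has_edge(self, a, ao, b, bo) -> bool:
        return (b, bo) in self._out.get((a, ao), {})

    def overlap_len(self, a, ao, b, bo) -> int:
        return self._out[(a, ao)][(b, bo)]

    def out_edges(self, node_id, orient: Orient) -> list[tuple[Hashable, Orient, int]]:
        return [(b, bo, ov) for (b, bo), ov in self._out.get((node_id, orient), {}).items()]

    def degree(self, node_id, orient: Orient) -> int:
        return len(self._out.get((node_id, orient), {}))

    def edges(self) -> Iterator[tuple[Hashable, Orient, Hashable, Orient, int]]:
        """Each bidirected edge once, as its canonical arc statement."""
        seen = set()
        for (a, ao), targets in self._out.items():
            for (b, bo), ov in targets.items():
                key = edge_key(a, ao, b, bo)
                if key in seen:
                    continue
                seen.add(key)
                yield (*key, ov)

    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    # -- UL support ---------------------------------------------------------
    def set_support(self, a, ao, b, bo, value: int) -> None:
        self._support[edge_key(a, ao, b, bo)] = value

    def get_support(self, a, ao, b, bo) -> int:
        return self._support.get(edge_key(a, ao, b, bo), 0)

    def reset_support(self) -> None:
        for k in self._support:
            self._support[k] = 0

    # -- mutation -----------------------------------------------------------
    def remove_edge(self, a, ao, b, bo) -> None:
        self._out[(a, ao)].pop((b, bo), None)
        self._out[(b, flip(bo))].pop((a, flip(ao)), None)
        self._support.pop(edge_key(a, ao, b, bo), None)

    def remove_node(self, node_id) -> None:
        for o in "+-":
            for (b, bo) in list(self._out.get((node_id, o), {})):
                self.remove_edge(node_id, o, b, bo)
            self._out.pop((node_id, o), None)
        self.nodes.pop(node_id, None)

    def copy(self) -> "StringGraph":
        g = StringGraph()
        for nid, n in self.nodes.items():
            g.add_node(nid, n.length, n.seq, n.contained,
                       None if n.members is None else list(n.members),
                       n.payload, n.origin)
        for key, targets in self._out.items():
            g._out[key] = dict(targets)
        g._support = dict(self._support)
        g.metadata = dict(self.metadata)
        return g

    # -- global structure ---------------------------------------------------
    def components(self) -> list[set]:
        """Connected components ignoring orientation."""
        seen: set = set()
        comps = []
        for start in self.nodes:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            seen.add(start)
            while stack:
                v = stack.pop()
                for o in "+-":
                    for (b, _bo) in self._out.get((v, o), {}):
                        if b not in seen:
                            seen.add(b)
                            comp.add(b)
                            stack.append(b)
            comps.append(comp)
        return comps

    def n_components(self) -> int:
        return len(self.components())


def maximal_chains(graph: StringGraph) -> list[list[tuple[Hashable, Orient]]]:
    """Maximal non-branching oriented paths covering every node exactly once.

    A chain extends (v, o) -> (w, wo) only when (v, o) has out-degree 1 and
    (w, ~wo) has out-degree 1 (the linking edge is the unique edge on both
    sides). Isolated/branching nodes become singleton chains; one chain per
    cycle is emitted with an arbitrary but deterministic break point.
    """
    assigned: set = set()
    chains: list[list[tuple[Hashable, Orient]]] = []

    def extendable(v, o):
        outs = graph.out_edges(v, o)
        if len(outs) != 1:
            return None
        w, wo, _ = outs[0]
        if graph.degree(w, flip(wo)) != 1:
            return None
        return (w, wo)

    for start in graph.nodes:
        if start in assigned:
            continue
        chain = [(start, "+")]
        used = {start}
        # walk left
        while True:
            v, o = chain[0]
            nxt = extendable(v, flip(o))
            if nxt is None or nxt[0] in assigned or nxt[0] in used:
                break
            w, wo = nxt
            chain.insert(0, (w, flip(wo)))
            used.add(w)
        # walk right
        while True:
            v, o = chain[-1]
            nxt = extendable(v, o)
            if nxt is None or nxt[0] in assigned or nxt[0] in used:
                break
            chain.append(nxt)
            used.add(nxt[0])
        assigned |= used
        chains.append(chain)
    return chains
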