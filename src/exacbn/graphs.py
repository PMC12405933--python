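"""Partially directed graph structures for Bayesian-network learning.

A :class:`NetworkStructure` holds a node set, a set of directed arcs and a set
of undirected edges, and therefore represents DAGs, PDAGs and CPDAGs with one
type.  The module also implements the standard structural operations needed by
constraint-based and consensus learning: v-structure detection, the Meek
orientation rules, the CPDAG (pattern closure) of a DAG, consistent extension
of a PDAG to a DAG (Dor & Tarsi style), and the structural Hamming distance
between partially directed graphs.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

__all__ = [
    "NetworkStructure",
    "CycleError",
    "InextensiblePDAGError",
    "cpdag_of_dag",
    "pdag_to_dag",
    "shd",
]


class CycleError(ValueError):
    """Raised when an operation would create (or requires absence of) a cycle."""


class InextensiblePDAGError(ValueError):
    """Raised when a PDAG admits no consistent extension to a DAG."""


@dataclass
class NetworkStructure:
    """Node set plus directed arcs and undirected edges (no self loops)."""

    nodes: tuple[str, ...]
    arcs: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.arcs = {tuple(a) for a in self.arcs}
        self.undirected = {frozenset(e) for e in self.undirected}
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arcs(cls, nodes, arcs, undirected=()) -> "NetworkStructure":
        return cls(tuple(nodes), set(map(tuple, arcs)),
                   {frozenset(e) for e in undirected})

    def copy(self) -> "NetworkStructure":
        return NetworkStructure(self.nodes, set(self.arcs), set(self.undirected))

    def validate(self) -> None:
        known = set(self.nodes)
        for u, v in self.arcs:
            if u == v:
                raise ValueError(f"self loop on {u!r}")
            if u not in known or v not in known:
                raise ValueError(f"arc {u}->{v} references unknown node")
            if (v, u) in self.arcs:
                raise ValueError(f"both directions present for {u}--{v}")
            if frozenset((u, v)) in self.undirected:
                raise ValueError(f"{u}--{v} is both directed and undirected")
        for e in self.undirected:
            if len(e) != 2:
                raise ValueError("undirected edge must join two distinct nodes")
            if not e <= known:
                raise ValueError(f"edge {set(e)} references unknown node")

    # -- basic queries -----------------------------------------------------
    def adjacent(self, u: str, v: str) -> bool:
        return ((u, v) in self.arcs or (v, u) in self.arcs
                or frozenset((u, v)) in self.undirected)

    def neighbours(self, u: str) -> set[str]:
        out = {v for (a, v) in self.arcs if a == u}
        out |= {a for (a, v) in self.arcs if v == u}
        out |= {next(iter(e - {u})) for e in self.undirected if u in e}
        return out

    def parents(self, v: str) -> set[str]:
        return {a for (a, b) in self.arcs if b == v}

    def children(self, u: str) -> set[str]:
        return {b for (a, b) in self.arcs if a == u}

    def undirected_neighbours(self, u: str) -> set[str]:
        return {next(iter(e - {u})) for e in self.undirected if u in e}

    @property
    def n_edges(self) -> int:
        return len(self.arcs) + len(self.undirected)

    def is_dag(self) -> bool:
        if self.undirected:
            return False
        return not self._directed_has_cycle()

    def _children_map(self) -> dict[str, set[str]]:
        ch: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in self.arcs:
            ch[a].add(b)
        return ch

    def _reaches(self, src: str, dst: str) -> bool:
        ch = self._children_map()
        stack, seen = [src], {src}
        while stack:
            x = stack.pop()
            if x == dst:
                return True
            for y in ch[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return False

    def _directed_has_cycle(self) -> bool:
        ch = self._children_map()
        state: dict[str, int] = {}

        def visit(x: str) -> bool:
            state[x] = 1
            for y in ch[x]:
                s = state.get(y, 0)
                if s == 1 or (s == 0 and visit(y)):
                    return True
            state[x] = 2
            return False

        return any(state.get(n, 0) == 0 and visit(n) for n in self.nodes)

    def assert_acyclic(self) -> None:
        if self._directed_has_cycle():
            g = nx.DiGraph(self.arcs)
            cyc = nx.find_cycle(g)
            raise CycleError(f"directed cycle: {cyc}")

    def would_cycle(self, u: str, v: str) -> bool:
        """Would adding arc u->v close a directed cycle?"""
        if u == v:
            return True
        # cycle iff v already reaches u through directed arcs
        return self._reaches(v, u)

    def topological_order(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        order = list(nx.lexicographical_topological_sort(g))
        return order

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Return (a, c, b) triples with a->c<-b and a, b non-adjacent, a<b."""
        out = set()
        for c in self.nodes:
            ps = sorted(self.parents(c))
            for a, b in combinations(ps, 2):
                if not self.adjacent(a, b):
                    out.add((a, c, b))
        return out

    def skeleton(self) -> set[frozenset[str]]:
        return ({frozenset(a) for a in self.arcs} | set(self.undirected))

    # -- mutation ----------------------------------------------------------
    def add_arc(self, u: str, v: str) -> None:
        self.undirected.discard(frozenset((u, v)))
        self.arcs.discard((v, u))
        self.arcs.add((u, v))

    def remove_edge(self, u: str, v: str) -> None:
        self.arcs.discard((u, v))
        self.arcs.discard((v, u))
        self.undirected.discard(frozenset((u, v)))

    def add_undirected(self, u: str, v: str) -> None:
        if not self.adjacent(u, v):
            self.undirected.add(frozenset((u, v)))

    # -- Meek rules --------------------------------------------------------
    def apply_meek_rules(self) -> "NetworkStructure":
        """Orient undirected edges to closure under Meek's four rules (in place)."""
        changed = True
        while changed:
            changed = False
            for e in sorted(self.undirected, key=sorted):
                x, y = sorted(e)
                for a, b in ((x, y), (y, x)):
                    if self._meek_orients(a, b):
                        self.add_arc(a, b)
                        changed = True
                        break
                if changed:
                    break
        return self

    def _meek_orients(self, a: str, b: str) -> bool:
        # Rule 1: exists c -> a, c not adjacent to b  =>  a -> b
        for c in self.parents(a):
            if not self.adjacent(c, b):
                return True
        # Rule 2: directed path a -> c -> b  =>  a -> b (avoid cycle)
        for c in self.children(a):
            if b in self.children(c):
                return True
        # Rule 3: a - c -> b and a - d -> b with c, d non-adjacent  =>  a -> b
        cands = [c for c in self.undirected_neighbours(a) if b in self.children(c)]
        for c, d in combinations(sorted(cands), 2):
            if not self.adjacent(c, d):
                return True
        # Rule 4: a - d -> c -> b with d, b non-adjacent and a adjacent to c
        for d in self.undirected_neighbours(a):
            for c in self.children(d):
                if b in self.children(c) and not self.adjacent(d, b) \
                        and self.adjacent(a, c):
                    return True
        return False

    # -- serialization -----------------------------------------------------
    def to_dot(self, edge_labels: dict | None = None) -> str:
        """Render as DOT text; undirected edges carry ``dir=none``."""
        lines = ["digraph network {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self.arcs):
            lab = ""
            if edge_labels and (u, v) in edge_labels:
                lab = f' [label="{edge_labels[(u, v)]}"]'
            lines.append(f'  "{u}" -> "{v}"{lab};')
        for e in sorted(self.undirected, key=sorted):
            u, v = sorted(e)
            lab = ' [dir=none]'
            if edge_labels and frozenset((u, v)) in edge_labels:
                lab = f' [dir=none, label="{edge_labels[frozenset((u, v))]}"]'
            lines.append(f'  "{u}" -> "{v}"{lab};')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in self.arcs:
            g.add_edge(u, v, directed=True)
        for e in self.undirected:
            u, v = sorted(e)
            g.add_edge(u, v, directed=False)
        return g

    def to_graphml(self) -> str:
        buf = io.BytesIO()
        nx.write_graphml(self.to_networkx(), buf)
        return buf.getvalue().decode()

    @classmethod
    def from_graphml(cls, text: str) -> "NetworkStructure":
        g = nx.read_graphml(io.BytesIO(text.encode()))
        arcs, und = set(), set()
        for u, v, d in g.edges(data=True):
            if d.get("directed", True):
                arcs.add((u, v))
            else:
                und.add(frozenset((u, v)))
        return cls(tuple(g.nodes()), arcs, und)

    def to_arc_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["from", "to"])
        for u, v in sorted(self.arcs):
            w.writerow([u, v])
        for e in sorted(self.undirected, key=sorted):
            u, v = sorted(e)
            w.writerow([u, v])
            w.writerow([v, u])
        return buf.getvalue()


def cpdag_of_dag(dag: NetworkStructure) -> NetworkStructure:
    """Completed PDAG (Markov-equivalence pattern) of a DAG.

    Skeleton plus v-structures, closed under the Meek rules; edges not
    compelled by the closure are left undirected.
    """
    if not dag.is_dag():
        raise CycleError("input must be a DAG")
    pat = NetworkStructure(dag.nodes)
    vstructs = dag.v_structures()
    directed = set()
    for a, c, b in vstructs:
        directed.add((a, c))
        directed.add((b, c))
    for e in dag.skeleton():
        u, v = sorted(e)
        if (u, v) in directed or (v, u) in directed:
            # orient as in the DAG (v-structure arcs)
            if (u, v) in dag.arcs:
                pat.add_arc(u, v)
            else:
                pat.add_arc(v, u)
        else:
            pat.add_undirected(u, v)
    pat.apply_meek_rules()
    return pat


def pdag_to_dag(pdag: NetworkStructure) -> NetworkStructure:
    """Consistent extension of a PDAG: same skeleton and v-structures.

    Dor & Tarsi's algorithm.  Repeatedly pick a node ``x`` that (i) has no
    out-going directed arc and (ii) every undirected neighbour of ``x`` is
    adjacent to all other neighbours of ``x``; orient all undirected edges of
    ``x`` into ``x`` and remove it.  Deterministic: candidate nodes are taken
    in sorted name order.

    Raises :class:`InextensiblePDAGError` when no consistent extension exists.
    """
    pdag.assert_acyclic()
    work = pdag.copy()
    out = pdag.copy()
    remaining = set(work.nodes)
    while remaining:
        found = None
        for x in sorted(remaining):
            if work.children(x) & remaining:
                continue
            und = work.undirected_neighbours(x) & remaining
            nbrs = (work.neighbours(x) & remaining) - {x}
            ok = all(
                work.adjacent(y, z)
                for y in und for z in nbrs if y != z
            )
            if ok:
                found = x
                break
        if found is None:
            raise InextensiblePDAGError(
                "PDAG admits no consistent extension; offending nodes: "
                f"{sorted(remaining)}")
        for y in sorted(work.undirected_neighbours(found) & remaining):
            out.add_arc(y, found)
        remaining.discard(found)
    out.assert_acyclic()
    if out.v_structures() != pdag.copy().v_structures() and not pdag.undirected:
        # pure-DAG input must round-trip untouched
        raise InextensiblePDAGError("extension altered v-structures")
    return out


def _edge_type(g: NetworkStructure, u: str, v: str) -> str:
    if (u, v) in g.arcs:
        return ">"
    if (v, u) in g.arcs:
        return "<"
    if frozenset((u, v)) in g.undirected:
        return "-"
    return "."


def shd(g1: NetworkStructure, g2: NetworkStructure) -> int:
    """Structural Hamming distance between two partially directed graphs.

    One unit per node pair whose edge status (absent / undirected / either
    direction) differs.
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs must share a node set")
    d = 0
    for u, v in combinations(sorted(g1.nodes), 2):
        if _edge_type(g1, u, v) != _edge_type(g2, u, v):
            d += 1
    return d
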