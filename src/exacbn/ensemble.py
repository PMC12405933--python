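"""Bootstrap, multi-algorithm consensus structure learning.

Each bootstrap replicate resamples the rows with replacement; every algorithm
in the ensemble learns a structure on the replicate.  Learned DAGs are
reduced to their Markov-equivalence pattern (CPDAG) before counting, so
direction frequencies reflect compelled orientations rather than arbitrary
class representatives; undirected edges contribute one half to each
direction.  Frequencies are pooled with equal weight over all
replicate × algorithm graphs.  The averaged network keeps pairs whose
adjacency frequency reaches the selection threshold (default 0.75, the
published operating point) and orients them by simple direction majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data import DiscreteData
from .graphs import CycleError, NetworkStructure, cpdag_of_dag, pdag_to_dag
from .learners import hill_climb, pc_stable, rsmax2, tabu_search

__all__ = ["ArcStrengthTable", "ExpertConstraints", "bootstrap_strengths",
           "averaged_network", "apply_expert_constraints", "ALGORITHMS"]

# the seven learners named for the ensemble; values are (callable, kwargs)
ALGORITHMS = {
    "hc": lambda d, kw: hill_climb(d, **kw),
    "tabu": lambda d, kw: tabu_search(d, **kw),
    "pc_stable": lambda d, kw: pc_stable(d, **kw),
    "gs": lambda d, kw: rsmax2(d, restrict_strategy="grow_shrink", **kw),
    "mmpc": lambda d, kw: rsmax2(d, restrict_strategy="mmpc", **kw),
    "si_hiton_pc": lambda d, kw: rsmax2(d, restrict_strategy="si_hiton_pc", **kw),
    "rsmax2": lambda d, kw: rsmax2(d, **kw),
}


@dataclass
class ExpertConstraints:
    """Arcs that must appear (with direction) and arcs that are forbidden."""
    whitelist: set[tuple[str, str]] = field(default_factory=set)
    blacklist: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        self.whitelist = {tuple(a) for a in self.whitelist}
        self.blacklist = {tuple(a) for a in self.blacklist}
        if self.whitelist & self.blacklist:
            raise ValueError("whitelist and blacklist overlap")
        g = NetworkStructure(
            tuple({n for a in self.whitelist for n in a}), set(self.whitelist))
        g.assert_acyclic()


@dataclass
class ArcStrengthTable:
    """Adjacency and direction frequencies pooled over learned graphs."""
    nodes: tuple[str, ...]
    n_graphs: int
    adjacency: dict[frozenset, float]          # pair -> frequency in [0, 1]
    direction: dict[tuple[str, str], float]    # (u, v) -> P(u->v | adjacent)
    per_algorithm: dict[str, dict[frozenset, float]] = field(default_factory=dict)
    n_failures: int = 0

    def adjacency_frequency(self, u: str, v: str) -> float:
        return self.adjacency.get(frozenset((u, v)), 0.0)

    def direction_frequency(self, u: str, v: str) -> float:
        return self.direction.get((u, v), 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pair in sorted(self.adjacency, key=sorted):
            u, v = sorted(pair)
            rows.append({"from": u, "to": v,
                         "adjacency_frequency": self.adjacency[pair],
                         "direction_frequency": self.direction.get((u, v), 0.0)})
            rows.append({"from": v, "to": u,
                         "adjacency_frequency": self.adjacency[pair],
                         "direction_frequency": self.direction.get((v, u), 0.0)})
        return pd.DataFrame(rows,
                            columns=["from", "to", "adjacency_frequency",
                                     "direction_frequency"])


class TooManyFailuresError(RuntimeError):
    pass


def bootstrap_strengths(data: DiscreteData | pd.DataFrame,
                        algorithms=("hc", "tabu", "pc_stable", "gs", "mmpc"),
                        B: int = 1000, m_fraction: float = 1.0,
                        constraints: ExpertConstraints | None = None,
                        seed: int | None = None,
                        algorithm_kwargs: dict | None = None,
                        max_failure_fraction: float = 0.05
                        ) -> ArcStrengthTable:
    """Arc strengths from ``B`` bootstrap replicates × the algorithm ensemble.

    The published configuration uses B = 1,000.  Failed learner runs are
    logged and skipped; more than ``max_failure_fraction`` of failures aborts.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < m_fraction <= 1:
        raise ValueError("m_fraction must lie in (0, 1]")
    if not algorithms:
        raise ValueError("need at least one algorithm")
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise ValueError(f"unknown algorithms {unknown}; choose from "
                         f"{sorted(ALGORITHMS)}")
    if isinstance(data, pd.DataFrame):
        data = DiscreteData.from_dataframe(data)
    kw_common: dict = dict(algorithm_kwargs or {})
    if constraints is not None:
        kw_common.setdefault("whitelist", set(constraints.whitelist))
        kw_common.setdefault("blacklist", set(constraints.blacklist))

    rng = np.random.default_rng(seed)
    m = max(1, int(round(m_fraction * data.n)))
    nodes = tuple(data.columns)
    adj_n: dict[frozenset, float] = {}
    dir_n: dict[tuple[str, str], float] = {}
    per_algo: dict[str, dict[frozenset, float]] = {a: {} for a in algorithms}
    n_graphs = 0
    failures = 0
    total_runs = B * len(algorithms)

    for _ in range(B):
        rep = data.bootstrap(rng, m)
        for algo in algorithms:
            try:
                g = ALGORITHMS[algo](rep, kw_common)
                if g.is_dag():                # DAG -> equivalence pattern
                    g = cpdag_of_dag(g)
            except Exception:
                failures += 1
                if failures > max_failure_fraction * total_runs:
                    raise TooManyFailuresError(
                        f"{failures}/{total_runs} learner runs failed")
                continue
            n_graphs += 1
            for u, v in g.arcs:
                pair = frozenset((u, v))
                adj_n[pair] = adj_n.get(pair, 0.0) + 1.0
                dir_n[(u, v)] = dir_n.get((u, v), 0.0) + 1.0
                per_algo[algo][pair] = per_algo[algo].get(pair, 0.0) + 1.0
            for e in g.undirected:
                u, v = sorted(e)
                adj_n[e] = adj_n.get(e, 0.0) + 1.0
                dir_n[(u, v)] = dir_n.get((u, v), 0.0) + 0.5
                dir_n[(v, u)] = dir_n.get((v, u), 0.0) + 0.5
                per_algo[algo][e] = per_algo[algo].get(e, 0.0) + 1.0

    adjacency = {p: c / n_graphs for p, c in adj_n.items()}
    direction = {}
    for pair, c in adj_n.items():
        u, v = sorted(pair)
        direction[(u, v)] = dir_n.get((u, v), 0.0) / c
        direction[(v, u)] = dir_n.get((v, u), 0.0) / c
    per_algorithm = {
        a: {p: c / (n_graphs / len(algorithms)) for p, c in tab.items()}
        for a, tab in per_algo.items()}
    return ArcStrengthTable(nodes, n_graphs, adjacency, direction,
                            per_algorithm, failures)


def averaged_network(strengths: ArcStrengthTable, threshold: float = 0.75,
                     direction_margin: float = 0.0) -> NetworkStructure:
    """Threshold the strength table into a consensus PDAG.

    Pairs with adjacency frequency ≥ ``threshold`` are kept; an edge is
    oriented u→v when its direction frequency exceeds ``0.5 +
    direction_margin``, else left undirected.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    g = NetworkStructure(strengths.nodes)
    for pair, f in strengths.adjacency.items():
        if f < threshold:
            continue
        u, v = sorted(pair)
        duv = strengths.direction.get((u, v), 0.5)
        if duv > 0.5 + direction_margin:
            g.add_arc(u, v)
        elif (1.0 - duv) > 0.5 + direction_margin:
            g.add_arc(v, u)
        else:
            g.add_undirected(u, v)
    return g


def apply_expert_constraints(network: NetworkStructure,
                             constraints: ExpertConstraints
                             ) -> NetworkStructure:
    """Remove blacklisted arcs, add/orient whitelisted ones, re-check acyclicity.

    A blacklisted direction on an undirected edge orients it the other way;
    blacklisting both directions removes the pair.
    """
    g = network.copy()
    for u, v in constraints.blacklist:
        if (u, v) in g.arcs:
            g.remove_edge(u, v)
        elif frozenset((u, v)) in g.undirected:
            g.remove_edge(u, v)
            if (v, u) not in constraints.blacklist:
                g.add_arc(v, u)
    for u, v in constraints.whitelist:
        g.add_arc(u, v)
    try:
        g.assert_acyclic()
    except CycleError as err:
        raise CycleError(
            f"expert constraints created a cycle: {err}") from err
    return g
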