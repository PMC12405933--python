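"""Structure-learning algorithms for discrete Bayesian networks.

Score-based: greedy hill climbing with add/delete/reverse moves (plain or
tabu search, optional random restarts).  Constraint-based: the
order-independent PC-stable algorithm.  Local-discovery: grow-shrink Markov
blankets, max-min parents-and-children (MMPC) and semi-interleaved HITON-PC,
all with AND-rule symmetry correction.  ``rsmax2`` is the generic two-phase
restrict-maximise hybrid (local discovery builds a candidate skeleton, hill
climbing maximises the score inside it).

Whitelists force arcs (with direction); blacklists forbid directed arcs.  For
the skeleton-based learners a pair is excluded only when both directions are
blacklisted.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .citest import g2_test
from .data import DiscreteData
from .graphs import CycleError, NetworkStructure
from .scores import Scorer

__all__ = ["hill_climb", "tabu_search", "pc_stable", "markov_blanket_local",
           "rsmax2"]


def _norm_constraints(whitelist, blacklist):
    wl = {tuple(a) for a in (whitelist or ())}
    bl = {tuple(a) for a in (blacklist or ())}
    if wl & bl:
        raise ValueError("whitelist and blacklist overlap")
    return wl, bl


# ---------------------------------------------------------------------------
# hill climbing / tabu search
# ---------------------------------------------------------------------------

def hill_climb(data: DiscreteData, score: str = "bic", restarts: int = 0,
               tabu_length: int = 0, whitelist=None, blacklist=None,
               seed: int | None = None, max_iter: int = 10_000,
               ess: float = 1.0, tie_order=None) -> NetworkStructure:
    """Greedy score maximisation over DAGs.

    With ``tabu_length > 0`` the best non-tabu neighbour is accepted even when
    it does not improve, recently undone moves are excluded, and the
    best-scoring DAG visited is returned.  Deterministic tie-break: among
    equal-score moves the smallest ``(operation, from, to)`` in ``tie_order``
    precedence wins (lexicographic node order by default).  Passing a
    permuted ``tie_order`` per bootstrap replicate removes the systematic
    orientation bias that a fixed tie-break imprints on score-equivalent
    moves (the standard precaution in bootstrapped structure learning).
    """
    wl, bl = _norm_constraints(whitelist, blacklist)
    scorer = Scorer(data, score, ess)
    rng = np.random.default_rng(seed)
    order = list(tie_order) if tie_order is not None else sorted(data.columns)
    if set(order) != set(data.columns):
        raise ValueError("tie_order must be a permutation of the columns")

    start = NetworkStructure(tuple(data.columns))
    for u, v in sorted(wl):
        if start.would_cycle(u, v):
            raise CycleError(f"whitelist forces a cycle at {u}->{v}")
        start.add_arc(u, v)

    best_g, best_s = _hc_once(start.copy(), scorer, wl, bl, tabu_length,
                              max_iter, order)
    for _ in range(restarts):
        g0 = _random_restart(start, rng, bl)
        g, s = _hc_once(g0, scorer, wl, bl, tabu_length, max_iter, order)
        if s > best_s + 1e-12:
            best_g, best_s = g, s
    best_g.assert_acyclic()
    return best_g


def tabu_search(data: DiscreteData, score: str = "bic", tabu_length: int = 10,
                **kw) -> NetworkStructure:
    return hill_climb(data, score=score, tabu_length=tabu_length, **kw)


def _random_restart(base: NetworkStructure, rng: np.random.Generator,
                    bl) -> NetworkStructure:
    g = base.copy()
    nodes = list(g.nodes)
    perm = list(rng.permutation(nodes))
    order = {n: i for i, n in enumerate(perm)}
    for u, v in combinations(nodes, 2):
        if rng.random() < 2.0 / max(len(nodes) - 1, 1):
            a, b = (u, v) if order[u] < order[v] else (v, u)
            if (a, b) not in bl and not g.adjacent(a, b) and not g.would_cycle(a, b):
                g.add_arc(a, b)
    return g


def _hc_once(g: NetworkStructure, scorer: Scorer, wl, bl,
             tabu_length: int, max_iter: int, order):
    fam = {v: scorer(v, g.parents(v)) for v in g.nodes}
    current = sum(fam.values())
    best_snapshot = (g.copy(), current)
    tabu: list[tuple] = []
    stall = 0
    rank = {n: i for i, n in enumerate(order)}
    for _ in range(max_iter):
        move = _best_move(g, scorer, fam, wl, bl, tabu, order, rank)
        if move is None:
            break
        delta, op, u, v = move
        if tabu_length == 0 and delta <= 1e-10:
            break
        _apply_move(g, fam, scorer, op, u, v)
        current += delta
        if tabu_length > 0:
            tabu.append(_inverse_move(op, u, v))
            if len(tabu) > tabu_length:
                tabu.pop(0)
            if current > best_snapshot[1] + 1e-10:
                best_snapshot = (g.copy(), current)
                stall = 0
            else:
                stall += 1
                if stall > max(2 * tabu_length, 10):
                    break
    if tabu_length > 0:
        return best_snapshot
    return g, current


def _descendants(g):
    """node -> set of strict descendants through directed arcs."""
    ch = {n: set() for n in g.nodes}
    for a, b in g.arcs:
        ch[a].add(b)
    desc = {}

    def visit(x):
        if x in desc:
            return desc[x]
        acc = set()
        for y in ch[x]:
            acc.add(y)
            acc |= visit(y)
        desc[x] = acc
        return acc

    for n in g.nodes:
        visit(n)
    return desc


def _best_move(g, scorer, fam, wl, bl, tabu, order, rank):
    best = None
    desc = _descendants(g)
    parents = {n: g.parents(n) for n in g.nodes}
    for u, v in combinations(order, 2):
        for a, b in ((u, v), (v, u)):
            if (a, b) in g.arcs:
                # delete
                if (a, b) not in wl:
                    d = scorer(b, parents[b] - {a}) - fam[b]
                    best = _pick(best, d, ("delete", a, b), tabu)
                # reverse: new arc b->a cycles iff a still reaches b via
                # another path (no a=>b path can use (a, b) except directly)
                if (a, b) not in wl and (b, a) not in bl:
                    cyc = any(b in desc[c] or b == c
                              for c in g.children(a) if c != b)
                    if not cyc:
                        d = (scorer(b, parents[b] - {a}) - fam[b]
                             + scorer(a, parents[a] | {b}) - fam[a])
                        best = _pick(best, d, ("reverse", a, b), tabu)
            elif not g.adjacent(a, b):
                if (a, b) in bl or a in desc[b]:
                    continue
                d = scorer(b, parents[b] | {a}) - fam[b]
                best = _pick(best, d, ("add", a, b), tabu)
    return best


def _pick(best, delta, move, tabu):
    # ties keep the first candidate in scan order, so the tie-break
    # precedence is exactly the (possibly permuted) node order
    if move in tabu:
        return best
    if best is None or delta > best[0] + 1e-10:
        return (delta, *move)
    return best


def _apply_move(g, fam, scorer, op, u, v):
    if op == "add":
        g.add_arc(u, v)
        fam[v] = scorer(v, g.parents(v))
    elif op == "delete":
        g.remove_edge(u, v)
        fam[v] = scorer(v, g.parents(v))
    elif op == "reverse":
        g.remove_edge(u, v)
        g.add_arc(v, u)
        fam[u] = scorer(u, g.parents(u))
        fam[v] = scorer(v, g.parents(v))


def _inverse_move(op, u, v):
    if op == "add":
        return ("delete", u, v)
    if op == "delete":
        return ("add", u, v)
    return ("reverse", v, u)


# ---------------------------------------------------------------------------
# PC-stable
# ---------------------------------------------------------------------------

def pc_stable(data: DiscreteData, alpha: float = 0.05, whitelist=None,
              blacklist=None, max_cond: int | None = None) -> NetworkStructure:
    """Order-independent PC: stable skeleton, v-structures, Meek closure."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    wl, bl = _norm_constraints(whitelist, blacklist)
    nodes = sorted(data.columns)
    adj = {n: set(nodes) - {n} for n in nodes}
    for u, v in combinations(nodes, 2):
        if (u, v) in bl and (v, u) in bl:
            adj[u].discard(v)
            adj[v].discard(u)
    protected = {frozenset(a) for a in wl}
    sepset: dict[frozenset, tuple] = {}

    depth = 0
    while True:
        if max_cond is not None and depth > max_cond:
            break
        frozen = {n: frozenset(adj[n]) for n in nodes}   # stable phase
        any_testable = False
        for u in nodes:
            for v in sorted(frozen[u]):
                if v not in adj[u] or frozenset((u, v)) in protected:
                    continue
                cands = sorted(frozen[u] - {v})
                if len(cands) < depth:
                    continue
                any_testable = True
                for S in combinations(cands, depth):
                    res = g2_test(u, v, S, data)
                    if res.p_value > alpha:
                        adj[u].discard(v)
                        adj[v].discard(u)
                        sepset[frozenset((u, v))] = tuple(S)
                        break
        if not any_testable:
            break
        depth += 1

    g = NetworkStructure(tuple(data.columns))
    for u, v in combinations(nodes, 2):
        if v in adj[u]:
            g.add_undirected(u, v)
    # v-structures: u - w - v with u, v non-adjacent and w not in sepset(u, v)
    for w in nodes:
        nb = sorted(g.neighbours(w))
        for u, v in combinations(nb, 2):
            if g.adjacent(u, v):
                continue
            if w not in sepset.get(frozenset((u, v)), ()):
                if frozenset((u, w)) in g.undirected or (u, w) in g.arcs:
                    if frozenset((v, w)) in g.undirected or (v, w) in g.arcs:
                        if (w, u) not in g.arcs and (w, v) not in g.arcs:
                            g.add_arc(u, w)
                            g.add_arc(v, w)
    for u, v in wl:
        g.add_arc(u, v)
    g.apply_meek_rules()
    return g


# ---------------------------------------------------------------------------
# local discovery: GS / MMPC / SI-HITON-PC
# ---------------------------------------------------------------------------

def _assoc(x, y, cond, data, alpha):
    """(p_value, statistic) of the G² test; lower p = stronger association."""
    r = g2_test(x, y, tuple(cond), data)
    return r.p_value, r.statistic


def _grow_shrink_blanket(data, target, alpha, candidates):
    mb: list[str] = []
    changed = True
    while changed:       # grow
        changed = False
        for x in candidates:
            if x in mb or x == target:
                continue
            p, _ = _assoc(target, x, mb, data, alpha)
            if p <= alpha:
                mb.append(x)
                changed = True
    changed = True
    while changed:       # shrink
        changed = False
        for x in list(mb):
            rest = [y for y in mb if y != x]
            p, _ = _assoc(target, x, rest, data, alpha)
            if p > alpha:
                mb.remove(x)
                changed = True
    return set(mb)


def _min_assoc(data, target, x, cpc, alpha, max_sx=None):
    """Max p-value (weakest association) over subsets of cpc."""
    worst_p, worst_stat = -1.0, np.inf
    kmax = len(cpc) if max_sx is None else min(max_sx, len(cpc))
    for k in range(kmax + 1):
        for S in combinations(sorted(cpc), k):
            p, stat = _assoc(target, x, S, data, alpha)
            if p > worst_p:
                worst_p, worst_stat = p, stat
            if worst_p > alpha:
                return worst_p, worst_stat   # already independent somewhere
    return worst_p, worst_stat


def _mmpc_one(data, target, alpha, candidates, max_sx=None):
    cpc: list[str] = []
    # incremental max-min: per candidate, track the weakest association seen;
    # when CPC grows, only subsets containing the new member need testing
    worst: dict[str, tuple[float, float]] = {}
    alive = [x for x in candidates if x != target]
    for x in alive:
        worst[x] = _assoc(target, x, (), data, alpha)
    while True:
        best = None
        for x in alive:
            if x in cpc:
                continue
            p, stat = worst[x]
            if p <= alpha:
                cand = (p, -stat, x)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        new = best[2]
        cpc.append(new)
        for x in alive:
            if x in cpc or worst[x][0] > alpha:
                continue
            others = [y for y in cpc if y != new]
            kmax = len(others) if max_sx is None else min(max_sx - 1,
                                                          len(others))
            for k in range(kmax + 1):
                for S in combinations(sorted(others), k):
                    p, stat = _assoc(target, x, (*S, new), data, alpha)
                    if p > worst[x][0]:
                        worst[x] = (p, stat)
                    if worst[x][0] > alpha:
                        break
                if worst[x][0] > alpha:
                    break
    # backward pruning
    for x in list(cpc):
        rest = [y for y in cpc if y != x]
        p, _ = _min_assoc(data, target, x, rest, alpha, max_sx)
        if p > alpha:
            cpc.remove(x)
    return set(cpc)


def _hiton_one(data, target, alpha, candidates, max_sx=None):
    ranked = []
    for x in candidates:
        if x == target:
            continue
        p, stat = _assoc(target, x, (), data, alpha)
        if p <= alpha:
            ranked.append((p, -stat, x))
    ranked.sort()
    pc: list[str] = []
    for _, _, x in ranked:         # semi-interleaved: eliminate after each add
        pc.append(x)
        for y in list(pc):
            rest = [z for z in pc if z != y]
            p, _ = _min_assoc(data, target, y, rest, alpha, max_sx)
            if p > alpha:
                pc.remove(y)
    return set(pc)


_STRATEGIES = {"grow_shrink", "mmpc", "si_hiton_pc"}


def markov_blanket_local(data: DiscreteData, target: str,
                         strategy: str = "mmpc", alpha: float = 0.05,
                         symmetry: bool = True,
                         max_sx: int | None = None) -> set[str]:
    """Local neighbourhood of ``target``.

    ``grow_shrink`` returns the Markov blanket; ``mmpc`` and ``si_hiton_pc``
    return the parents-and-children set.  With ``symmetry=True`` (default) the
    AND-rule correction is applied: X stays in the set only when the target is
    recovered from X's side as well.
    """
    if target not in data.columns:
        raise KeyError(f"target {target!r} not in data")
    if strategy not in _STRATEGIES:
        raise ValueError(f"strategy must be one of {sorted(_STRATEGIES)}")
    cands = sorted(c for c in data.columns if c != target)
    own = _one_neighbourhood(data, target, strategy, alpha, cands, max_sx)
    if not symmetry:
        return own
    out = set()
    for x in own:
        other = _one_neighbourhood(
            data, x, strategy, alpha,
            sorted(c for c in data.columns if c != x), max_sx)
        if target in other:
            out.add(x)
    return out


def _one_neighbourhood(data, target, strategy, alpha, cands, max_sx):
    if strategy == "grow_shrink":
        return _grow_shrink_blanket(data, target, alpha, cands)
    if strategy == "mmpc":
        return _mmpc_one(data, target, alpha, cands, max_sx)
    return _hiton_one(data, target, alpha, cands, max_sx)


# ---------------------------------------------------------------------------
# restricted maximisation
# ---------------------------------------------------------------------------

def rsmax2(data: DiscreteData, restrict_strategy: str = "mmpc",
           maximize_score: str = "bic", alpha: float = 0.05,
           whitelist=None, blacklist=None, max_sx: int | None = None,
           **hc_kw) -> NetworkStructure:
    """Two-phase hybrid: local discovery restricts, hill climbing maximises."""
    wl, bl = _norm_constraints(whitelist, blacklist)
    nbr: dict[str, set[str]] = {}
    for t in data.columns:
        nbr[t] = _one_neighbourhood(
            data, t, restrict_strategy, alpha,
            sorted(c for c in data.columns if c != t), max_sx)
    allowed = set()
    for t, s in nbr.items():
        for x in s:
            if t in nbr[x]:                      # AND-rule symmetry
                allowed.add(frozenset((t, x)))
    for u, v in wl:
        allowed.add(frozenset((u, v)))
    full_bl = set(bl)
    for u, v in combinations(sorted(data.columns), 2):
        if frozenset((u, v)) not in allowed:
            full_bl.add((u, v))
            full_bl.add((v, u))
    full_bl -= wl
    return hill_climb(data, score=maximize_score, whitelist=wl,
                      blacklist=full_bl, **hc_kw)
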