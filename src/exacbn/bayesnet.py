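"""Discrete Bayesian networks: CPT fitting, exact inference, interventions.

``DiscreteBayesNet`` couples a DAG with per-node conditional probability
tables over discrete levels.  Queries are answered exactly by variable
elimination over the CPT factors (min-degree elimination order,
name-deterministic tie-break).  Counterfactual what-ifs follow intervention
semantics: ``intervene_do`` mutilates the graph by cutting the arcs into the
intervened node and pinning its distribution, so effects propagate to
descendants only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import NetworkStructure

__all__ = [
    "DiscreteBayesNet", "RiskPrediction", "fit_cpts", "variable_elimination",
    "intervene_do", "predict_exacerbation_risk", "counterfactual_compare",
    "InconsistentEvidenceError", "joint_probability", "bayesnet_from_spec",
]

OUTCOME = "future_exac"


class InconsistentEvidenceError(ValueError):
    """Evidence has zero probability under the network."""


@dataclass
class RiskPrediction:
    """Posterior over the 3-level outcome {0, 1, ≥2} for one patient."""
    probabilities: np.ndarray            # aligned with outcome levels
    levels: tuple[str, ...]

    @property
    def p_ge1(self) -> float:
        return float(self.probabilities[1:].sum())

    @property
    def p_ge2(self) -> float:
        return float(self.probabilities[2:].sum())


@dataclass
class DiscreteBayesNet:
    dag: NetworkStructure
    levels: dict[str, list[str]]
    cpts: dict[str, np.ndarray]          # shape (*parent cards, own card)
    fitted_n: int = 0
    smoothing: float = 0.0
    parent_order: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for n in self.dag.nodes:
            self.parent_order.setdefault(n, tuple(sorted(self.dag.parents(n))))
        self.validate()

    def validate(self) -> None:
        if not self.dag.is_dag():
            raise ValueError("structure must be a DAG")
        for n in self.dag.nodes:
            cpt = self.cpts[n]
            want = tuple(len(self.levels[p]) for p in self.parent_order[n]) \
                + (len(self.levels[n]),)
            if cpt.shape != want:
                raise ValueError(
                    f"CPT of {n}: shape {cpt.shape}, expected {want}")
            rows = cpt.reshape(-1, cpt.shape[-1])
            if np.any(rows < 0):
                raise ValueError(f"negative probability in CPT of {n}")
            if np.max(np.abs(rows.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError(f"CPT rows of {n} do not sum to 1")

    def level_index(self, node: str, level) -> int:
        try:
            return self.levels[node].index(str(level))
        except ValueError:
            raise KeyError(
                f"unknown level {level!r} for node {node!r}; "
                f"known: {self.levels[node]}") from None

    def copy(self) -> "DiscreteBayesNet":
        return DiscreteBayesNet(
            self.dag.copy(), {k: list(v) for k, v in self.levels.items()},
            {k: v.copy() for k, v in self.cpts.items()},
            self.fitted_n, self.smoothing,
            {k: tuple(v) for k, v in self.parent_order.items()})

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "nodes": list(self.dag.nodes),
            "arcs": sorted(self.dag.arcs),
            "levels": self.levels,
            "parent_order": {k: list(v) for k, v in self.parent_order.items()},
            "cpts": {k: v.tolist() for k, v in self.cpts.items()},
            "fitted_n": self.fitted_n,
            "smoothing": self.smoothing,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscreteBayesNet":
        d = json.loads(text)
        dag = NetworkStructure(tuple(d["nodes"]),
                               {tuple(a) for a in d["arcs"]})
        return cls(dag, {k: list(v) for k, v in d["levels"].items()},
                   {k: np.asarray(v, dtype=float) for k, v in d["cpts"].items()},
                   d.get("fitted_n", 0), d.get("smoothing", 0.0),
                   {k: tuple(v) for k, v in d["parent_order"].items()})


def fit_cpts(dag: NetworkStructure, data: pd.DataFrame,
             smoothing_alpha: float = 1.0) -> DiscreteBayesNet:
    """Maximum-likelihood / Dirichlet-smoothed CPTs on discrete data.

    Cell = (count + α) / (row total + α·levels).  With α = 0, unobserved
    parent configurations fall back to uniform rows (with a warning).
    """
    if not dag.is_dag():
        raise ValueError("fit_cpts needs a DAG (orient the PDAG first)")
    missing_cols = [n for n in dag.nodes if n not in data.columns]
    if missing_cols:
        raise KeyError(f"data lacks columns {missing_cols}")
    levels: dict[str, list[str]] = {}
    codes: dict[str, np.ndarray] = {}
    for n in dag.nodes:
        cat = pd.Categorical(data[n].astype(str)) \
            if not isinstance(data[n].dtype, pd.CategoricalDtype) \
            else pd.Categorical(data[n])
        if (cat.codes < 0).any():
            raise ValueError(f"column {n!r} has missing values")
        levels[n] = [str(c) for c in cat.categories]
        codes[n] = cat.codes.astype(np.int64)

    cpts: dict[str, np.ndarray] = {}
    parent_order = {n: tuple(sorted(dag.parents(n))) for n in dag.nodes}
    for n in dag.nodes:
        ps = parent_order[n]
        r = len(levels[n])
        cards = [len(levels[p]) for p in ps]
        idx = np.zeros(len(data), dtype=np.int64)
        for p, c in zip(ps, cards):
            idx = idx * c + codes[p]
        q = int(np.prod(cards)) if cards else 1
        tab = np.bincount(idx * r + codes[n], minlength=q * r) \
            .reshape(q, r).astype(float)
        row_n = tab.sum(axis=1, keepdims=True)
        if smoothing_alpha > 0:
            tab = (tab + smoothing_alpha) / (row_n + smoothing_alpha * r)
        else:
            empty = row_n[:, 0] == 0
            if empty.any():
                import warnings
                warnings.warn(
                    f"{int(empty.sum())} unobserved parent configurations for "
                    f"{n!r}; using uniform rows")
                tab[empty] = 1.0
                row_n[empty] = r
            tab = tab / tab.sum(axis=1, keepdims=True)
        cpts[n] = tab.reshape(*cards, r)
    return DiscreteBayesNet(dag.copy(), levels, cpts, len(data),
                            smoothing_alpha, parent_order)


def bayesnet_from_spec(spec) -> DiscreteBayesNet:
    """Exact band-level network of a ground-truth cohort spec."""
    dag = spec.dag()
    parent_order = {n: tuple(spec.parents.get(n, ())) for n in spec.nodes}
    return DiscreteBayesNet(
        dag, {n: [str(l) for l in spec.levels[n]] for n in spec.nodes},
        {n: spec.cpts[n].copy() for n in spec.nodes}, 0, 0.0, parent_order)


# ---------------------------------------------------------------------------
# exact inference
# ---------------------------------------------------------------------------

def _factors(net: DiscreteBayesNet):
    out = []
    for n in net.dag.nodes:
        vars_ = net.parent_order[n] + (n,)
        out.append((vars_, net.cpts[n]))
    return out


def _reduce_factor(vars_, table, evidence_idx):
    keep, slicer = [], []
    for v in vars_:
        if v in evidence_idx:
            slicer.append(evidence_idx[v])
        else:
            slicer.append(slice(None))
            keep.append(v)
    return tuple(keep), table[tuple(slicer)]


def _multiply(f1, f2):
    v1, t1 = f1
    v2, t2 = f2
    allv = list(v1) + [v for v in v2 if v not in v1]
    sh1 = t1.reshape(t1.shape + (1,) * (len(allv) - len(v1)))
    perm = [v2.index(v) if v in v2 else None for v in allv]
    sh2_shape = [t2.shape[v2.index(v)] if v in v2 else 1 for v in allv]
    t2b = np.transpose(t2, [v2.index(v) for v in allv if v in v2]) \
        .reshape(sh2_shape)
    return tuple(allv), sh1 * t2b


def variable_elimination(net: DiscreteBayesNet, query_node: str,
                         evidence: dict | None = None) -> np.ndarray:
    """Exact posterior P(query | evidence), normalized.

    Evidence maps nodes to level labels (or indices).  Evidence on the query
    itself is rejected; zero-probability evidence raises
    :class:`InconsistentEvidenceError`.
    """
    evidence = evidence or {}
    if query_node not in net.dag.nodes:
        raise KeyError(f"unknown query node {query_node!r}")
    if query_node in evidence:
        raise ValueError("evidence must not include the query node")
    ev_idx = {v: net.level_index(v, l) if not isinstance(l, (int, np.integer))
              or isinstance(l, bool) else int(l)
              for v, l in evidence.items()}
    for v in ev_idx:
        if v not in net.dag.nodes:
            raise KeyError(f"unknown evidence node {v!r}")

    factors = []
    for vars_, tab in _factors(net):
        kv, kt = _reduce_factor(vars_, tab, ev_idx)
        factors.append((kv, kt))

    hidden = [n for n in net.dag.nodes if n != query_node and n not in ev_idx]
    # min-degree elimination order, deterministic by name
    while hidden:
        degree = {}
        for h in hidden:
            nbrs = set()
            for kv, _ in factors:
                if h in kv:
                    nbrs |= set(kv)
            degree[h] = len(nbrs - {h})
        h = min(hidden, key=lambda x: (degree[x], x))
        hidden.remove(h)
        related = [f for f in factors if h in f[0]]
        factors = [f for f in factors if h not in f[0]]
        if not related:
            continue
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        kv, kt = prod
        axis = kv.index(h)
        factors.append((tuple(v for v in kv if v != h), kt.sum(axis=axis)))

    prod = (tuple(), np.array(1.0))
    for f in factors:
        prod = _multiply(prod, f)
    kv, kt = prod
    if kv != (query_node,):
        if query_node in kv:
            others = tuple(i for i, v in enumerate(kv) if v != query_node)
            kt = np.transpose(kt, [kv.index(query_node), *others]) \
                if others else kt
            kt = kt.reshape(kt.shape[0], -1).sum(axis=1)
        else:
            raise RuntimeError("query variable vanished during elimination")
    total = float(np.sum(kt))
    if total <= 0:
        raise InconsistentEvidenceError(
            f"evidence {evidence!r} has zero probability")
    return np.asarray(kt, dtype=float) / total


def joint_probability(net: DiscreteBayesNet, assignment: dict) -> float:
    """Chain-rule probability of one full assignment (all nodes)."""
    if set(assignment) != set(net.dag.nodes):
        raise ValueError("assignment must cover every node")
    idx = {v: net.level_index(v, l) if not isinstance(l, (int, np.integer))
           else int(l) for v, l in assignment.items()}
    p = 1.0
    for n in net.dag.nodes:
        sel = tuple(idx[pp] for pp in net.parent_order[n]) + (idx[n],)
        p *= float(net.cpts[n][sel])
    return p


def intervene_do(net: DiscreteBayesNet, node: str, level) -> DiscreteBayesNet:
    """Graph mutilation do(node = level): cut incoming arcs, pin the node."""
    if node not in net.dag.nodes:
        raise KeyError(f"unknown node {node!r}")
    li = net.level_index(node, level)
    out = net.copy()
    for p in list(out.dag.parents(node)):
        out.dag.remove_edge(p, node)
    point = np.zeros(len(out.levels[node]))
    point[li] = 1.0
    out.cpts[node] = point
    out.parent_order[node] = ()
    return out


def predict_exacerbation_risk(net: DiscreteBayesNet, patient_evidence: dict,
                              outcome: str = OUTCOME) -> RiskPrediction:
    """Outcome posterior for one patient; absent predictors are marginalized."""
    evidence = {k: v for k, v in patient_evidence.items()
                if v is not None and not (isinstance(v, float) and np.isnan(v))}
    post = variable_elimination(net, outcome, evidence)
    return RiskPrediction(post, tuple(net.levels[outcome]))


def counterfactual_compare(net: DiscreteBayesNet, node: str, levels,
                           target: str = OUTCOME) -> pd.DataFrame:
    """Target distribution under do(node = level) for each level.

    Returns one row per level with the target distribution, P(target ≥ 1),
    and deltas against the first level.
    """
    levels = list(levels)
    if len(levels) < 1:
        raise ValueError("need at least one level")
    rows = []
    base = None
    for lv in levels:
        mut = intervene_do(net, node, lv)
        post = variable_elimination(mut, target)
        p_ge1 = float(post[1:].sum())
        if base is None:
            base = (post.copy(), p_ge1)
        rows.append({
            "level": str(lv),
            **{f"p_{l}": float(p) for l, p in zip(net.levels[target], post)},
            "p_ge1": p_ge1,
            "delta_p_ge1": p_ge1 - base[1],
        })
    return pd.DataFrame(rows)
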