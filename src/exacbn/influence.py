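"""Influence diagrams: a discrete Bayesian network plus decisions and utilities.

Decision nodes carry finite action sets and may observe their (chance-node)
parents; utility nodes are sinks with real-valued tables over their parents'
configurations (sign convention: utility minus cost).  Evaluation is by exact
enumeration of the chance joint — the diagrams in scope are small (one or two
decisions), so brute force is both simple and an oracle-free ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .bayesnet import DiscreteBayesNet, joint_probability

__all__ = ["DecisionNode", "UtilityNode", "InfluenceDiagram",
           "evaluate_influence_diagram"]


@dataclass
class DecisionNode:
    name: str
    actions: tuple[str, ...]
    observes: tuple[str, ...] = ()       # chance parents visible at decision time


@dataclass
class UtilityNode:
    name: str
    parents: tuple[str, ...]             # chance or decision nodes
    table: np.ndarray                    # shape (*parent cards in order)


@dataclass
class InfluenceDiagram:
    net: DiscreteBayesNet                # chance nodes; CPTs may depend on
    decisions: list[DecisionNode]        # decision nodes via parent_order
    utilities: list[UtilityNode]
    decision_cpt_children: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        names = set(self.net.dag.nodes)
        dnames = {d.name for d in self.decisions}
        if names & dnames:
            raise ValueError("decision names collide with chance nodes")
        for u in self.utilities:
            for p in u.parents:
                if p not in names and p not in dnames:
                    raise ValueError(f"utility {u.name} references unknown {p}")
        for d in self.decisions:
            for o in d.observes:
                if o not in names:
                    raise ValueError(
                        f"decision {d.name} observes unknown chance node {o}")

    def card(self, name: str) -> int:
        for d in self.decisions:
            if d.name == name:
                return len(d.actions)
        return len(self.net.levels[name])


def _policies(diagram: InfluenceDiagram):
    """All deterministic policies: per decision, an action per info state."""
    per_decision = []
    for d in diagram.decisions:
        info_cards = [len(diagram.net.levels[o]) for o in d.observes]
        n_states = int(np.prod(info_cards)) if info_cards else 1
        per_decision.append([dict(zip(range(n_states), acts))
                             for acts in product(range(len(d.actions)),
                                                 repeat=n_states)])
    for combo in product(*per_decision):
        yield {d.name: rule for d, rule in zip(diagram.decisions, combo)}


def _info_state(diagram, d: DecisionNode, assignment: dict) -> int:
    idx = 0
    for o in d.observes:
        idx = idx * len(diagram.net.levels[o]) + assignment[o]
    return idx


def _policy_value(diagram: InfluenceDiagram, policy: dict) -> float:
    net = diagram.net
    nodes = list(net.dag.nodes)
    cards = [len(net.levels[n]) for n in nodes]
    total = 0.0
    for combo in product(*(range(c) for c in cards)):
        assignment = dict(zip(nodes, combo))
        p = joint_probability(net, assignment)
        if p == 0.0:
            continue
        full = dict(assignment)
        for d in diagram.decisions:
            rule = policy[d.name]
            state = _info_state(diagram, d, assignment)
            if state not in rule:
                raise KeyError(
                    f"policy for {d.name} lacks an action for reachable "
                    f"information state {state}")
            full[d.name] = rule[state]
        u = 0.0
        for un in diagram.utilities:
            sel = tuple(full[p_] for p_ in un.parents)
            u += float(un.table[sel])
        total += p * u
    return total


def evaluate_influence_diagram(diagram: InfluenceDiagram,
                               policy: dict | str = "optimal"
                               ) -> tuple[float, dict]:
    """Expected utility of a policy, or the optimal policy by enumeration.

    A policy maps each decision name to {information-state index: action
    index}; decisions without observations have the single state 0.  Returns
    ``(expected_utility, policy)``.
    """
    for un in diagram.utilities:
        if not np.all(np.isfinite(un.table)):
            raise ValueError(f"utility {un.name} has non-finite entries")
    if policy == "optimal":
        best = None
        for pol in _policies(diagram):
            val = _policy_value(diagram, pol)
            if best is None or val > best[0] + 1e-12:
                best = (val, pol)
        if best is None:                 # no decisions: single empty policy
            best = (_policy_value(diagram, {}), {})
        return best
    if isinstance(policy, dict):
        norm = {}
        for d in diagram.decisions:
            rule = policy.get(d.name)
            if rule is None:
                raise KeyError(f"policy missing decision {d.name!r}")
            if isinstance(rule, (int, np.integer, str)):
                act = d.actions.index(rule) if isinstance(rule, str) else int(rule)
                info_cards = [len(diagram.net.levels[o]) for o in d.observes]
                n_states = int(np.prod(info_cards)) if info_cards else 1
                rule = {s: act for s in range(n_states)}
            norm[d.name] = rule
        return _policy_value(diagram, norm), norm
    raise TypeError("policy must be a dict or 'optimal'")
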