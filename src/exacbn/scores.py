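"""Decomposable network scores for discrete Bayesian networks.

``family_score`` scores one node given a candidate parent set; the score of a
DAG is the sum of its family scores.  BIC uses the multinomial log-likelihood
minus ``(ln n / 2)`` per free parameter, with the parameter count taken over
all parent configurations (observed or not).  BDeu is the Dirichlet-multinomial
marginal likelihood with a uniform structure prior and equivalent sample size
``ess``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, xlogy

from .data import DiscreteData
from .graphs import NetworkStructure

__all__ = ["family_score", "network_score", "Scorer"]


def family_score(node: str, parents: tuple[str, ...] | list[str],
                 data: DiscreteData, score: str = "bic",
                 ess: float = 1.0) -> float:
    parents = tuple(parents)
    tab = data.counts((node,) + parents).astype(np.float64)
    r = tab.shape[0]
    counts = tab.reshape(r, -1)                 # (levels, parent configs)
    q = counts.shape[1]
    nj = counts.sum(axis=0)
    if score == "bic":
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(np.sum(xlogy(counts, counts)) - np.sum(xlogy(nj, nj)))
        k = (r - 1) * q
        return ll - 0.5 * np.log(data.n) * k
    if score == "bdeu":
        a_j = ess / q
        a_ij = ess / (q * r)
        live = nj > 0
        val = float(
            np.sum(gammaln(a_j) - gammaln(nj[live] + a_j))
            + np.sum(gammaln(counts[:, live] + a_ij) - gammaln(a_ij))
        )
        return val
    raise ValueError(f"unknown score {score!r}")


class Scorer:
    """Family-score cache for one dataset (decomposability makes this exact)."""

    def __init__(self, data: DiscreteData, score: str = "bic", ess: float = 1.0):
        self.data = data
        self.score = score
        self.ess = ess
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def __call__(self, node: str, parents) -> float:
        key = (node, tuple(sorted(parents)))
        v = self._cache.get(key)
        if v is None:
            v = family_score(node, key[1], self.data, self.score, self.ess)
            self._cache[key] = v
        return v


def network_score(dag: NetworkStructure, data: DiscreteData,
                  score: str = "bic", ess: float = 1.0) -> float:
    sc = Scorer(data, score, ess)
    return sum(sc(v, dag.parents(v)) for v in dag.nodes)
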