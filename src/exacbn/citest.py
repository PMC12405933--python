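"""Likelihood-ratio (G²) test of conditional independence for discrete data.

The G² statistic for X ⫫ Y | Z is ``2 Σ O log(O/E)`` accumulated within each
stratum of Z, with the expected counts formed from the within-stratum margins.
Degrees of freedom follow the usual discrete-BN convention
``(|X|−1)(|Y|−1)·Π|Z|``, with empty strata skipped and their contribution
removed; strata margins that are entirely zero likewise shrink the effective
dimension.  A Pearson χ² variant is available through ``test="x2"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import chdtrc, xlogy

from .data import DiscreteData

__all__ = ["CITestResult", "g2_test"]


@dataclass(frozen=True)
class CITestResult:
    statistic: float
    dof: int
    p_value: float
    test_name: str
    reliable: bool = True

    def independent(self, alpha: float) -> bool:
        return self.p_value > alpha


def g2_test(x: str, y: str, z: tuple[str, ...] | list[str],
            data: DiscreteData, test: str = "g2") -> CITestResult:
    """Test X ⫫ Y | Z on discrete data.

    Returns the statistic, the (stratum-adjusted) degrees of freedom and the
    chi-square upper-tail p value.  The result is flagged unreliable (but
    still returned) when the average cell count falls below 5 or when the
    degrees of freedom collapse to zero.
    """
    z = tuple(z)
    memo = getattr(data, "_ci_memo", None)
    if memo is None:
        memo = data._ci_memo = {}
    key = (test, *sorted((x, y)), *sorted(z))
    hit = memo.get(key)
    if hit is not None:
        return hit

    tab = data.counts((x, y) + z).astype(np.float64)
    rx, ry = tab.shape[0], tab.shape[1]
    strat = tab.reshape(rx, ry, -1)           # (x, y, stratum)
    tot = strat.sum(axis=(0, 1))              # per-stratum totals
    mx = strat.sum(axis=1)                    # (x, stratum)
    my = strat.sum(axis=0)                    # (y, stratum)

    # O > 0 implies both margins > 0 and hence E > 0: xlogy never sees log 0
    expected = mx[:, None, :] * my[None, :, :] / np.where(tot > 0, tot, 1.0)
    if test == "g2":
        statistic = 2.0 * float(np.sum(xlogy(strat, strat) - xlogy(strat, expected)))
    elif test == "x2":
        safe = np.where(expected > 0, expected, 1.0)
        statistic = float(np.sum((strat - expected) ** 2 / safe))
    else:
        raise ValueError(f"unknown test {test!r}")
    statistic = max(statistic, 0.0)

    nz_x = (mx > 0).sum(axis=0)               # non-zero x margins per stratum
    nz_y = (my > 0).sum(axis=0)
    live = tot > 0
    dof = int(np.sum(np.maximum(nz_x[live] - 1, 0) * np.maximum(nz_y[live] - 1, 0)))
    if dof < 1:
        res = CITestResult(statistic, 1, 1.0, test, reliable=False)
        memo[key] = res
        return res
    n_cells = rx * ry * strat.shape[2]
    reliable = data.n / n_cells >= 5
    p = float(chdtrc(dof, statistic))
    res = CITestResult(statistic, dof, p, test, reliable)
    memo[key] = res
    return res
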