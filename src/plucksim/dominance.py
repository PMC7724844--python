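"""Empirical CDFs and first-/second-order stochastic dominance verdicts.

For profit samples A and B with empirical CDFs ``F_A`` and ``F_B``
(``F(x) = P(X <= x)``), A first-order dominates B if ``F_A(x) <= F_B(x)``
everywhere with strict inequality somewhere — A's CDF lies to the right,
so A gives at least B's probability of exceeding any profit level.
Second-order dominance compares the running integrals of the CDFs
(computed exactly; the empirical CDF is a step function, so the integral
is piecewise linear): a risk-averse decision maker prefers A if
``int F_A <= int F_B`` everywhere with strict inequality somewhere.
First-order dominance implies second-order dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EmpiricalCDF",
    "ecdf",
    "fosd",
    "sosd",
    "exceedance_report",
]

LE_TOL = 1e-12     # tolerance for the "<=" comparisons
STRICT_TOL = 1e-9  # threshold for counting an inequality as strict


@dataclass(frozen=True)
class EmpiricalCDF:
    """Right-continuous empirical CDF of a sample."""

    values: np.ndarray  # sorted sample

    @property
    def n(self) -> int:
        return len(self.values)

    def evaluate(self, x) -> np.ndarray:
        """F(x) = fraction of the sample <= x (broadcasts over arrays)."""
        return np.searchsorted(self.values, np.asarray(x, dtype=float),
                               side="right") / self.n

    def integral(self, grid: np.ndarray) -> np.ndarray:
        """Exact running integral of the step CDF at each grid point,
        starting from the first grid value."""
        f = self.evaluate(grid)
        out = np.zeros_like(grid, dtype=float)
        out[1:] = np.cumsum(f[:-1] * np.diff(grid))
        return out


def ecdf(values) -> EmpiricalCDF:
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    return EmpiricalCDF(values=np.sort(values))


def _merged_grid(a: EmpiricalCDF, b: EmpiricalCDF) -> np.ndarray:
    return np.unique(np.concatenate([a.values, b.values]))


def _verdict(diff: np.ndarray) -> str:
    """Dominance verdict from pointwise differences (A-statistic - B-statistic).

    A dominates iff diff <= 0 everywhere with at least one strictly
    negative point; lower CDF (or CDF integral) is better.
    """
    a_ok = np.all(diff <= LE_TOL)
    b_ok = np.all(-diff <= LE_TOL)
    a_strict = np.any(diff < -STRICT_TOL)
    b_strict = np.any(-diff < -STRICT_TOL)
    if a_ok and a_strict and not (b_ok and b_strict):
        return "A_dominates"
    if b_ok and b_strict and not (a_ok and a_strict):
        return "B_dominates"
    return "none"


def fosd(a: EmpiricalCDF, b: EmpiricalCDF) -> str:
    """First-order stochastic dominance verdict on the merged support grid.

    Returns "A_dominates", "B_dominates" or "none".
    """
    grid = _merged_grid(a, b)
    return _verdict(a.evaluate(grid) - b.evaluate(grid))


def sosd(a: EmpiricalCDF, b: EmpiricalCDF) -> str:
    """Second-order stochastic dominance verdict (running CDF integrals)."""
    grid = _merged_grid(a, b)
    return _verdict(a.integral(grid) - b.integral(grid))


def exceedance_report(samples: dict, thresholds) -> pd.DataFrame:
    """P(outcome >= threshold) per scenario at the given profit levels."""
    rows = {}
    for name, values in samples.items():
        cdf = ecdf(values)
        rows[name] = {t: float(1.0 - cdf.evaluate(t) + np.mean(cdf.values == t))
                      for t in thresholds}
    out = pd.DataFrame(rows)
    out.index.name = "threshold_eur"
    return out


def cdf_export(samples: dict) -> pd.DataFrame:
    """Merged-grid CDF curves of several samples, one column per scenario
    (suitable for plotting the cumulative-probability comparison)."""
    cdfs = {name: ecdf(v) for name, v in samples.items()}
    grid = np.unique(np.concatenate([c.values for c in cdfs.values()]))
    data = {"x": grid}
    for name, c in cdfs.items():
        data[f"F_{name}"] = c.evaluate(grid)
    return pd.DataFrame(data)
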