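"""Bounded input distributions: modified PERT and mean-matched truncated normals.

The farm-level inputs of the simulation are only ever published as
(minimum, mean, maximum) triples or as mean +/- SD with hard bounds, so the
two families here are parameterised directly from those summaries:

* modified PERT — a scaled Beta on [min, max], unimodal, with the mode
  chosen so the distribution mean hits a target exactly;
* truncated normal with the *underlying* location solved so that the
  post-truncation mean equals a target (naive truncation would bias the
  mean away from the published value).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy import stats

__all__ = [
    "Dirac",
    "pert",
    "pert_from_mean",
    "truncnorm_matching_mean",
]


class Dirac:
    """Point mass used for degenerate (min == max) input triples.

    Implements the small subset of the frozen-distribution API the risk
    engine touches.
    """

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size=None, random_state=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def mean(self) -> float:
        return self.value

    def std(self) -> float:
        return 0.0

    def ppf(self, q):
        return np.full_like(np.asarray(q, dtype=float), self.value)

    def support(self):
        return (self.value, self.value)


def pert(minimum: float, mode: float, maximum: float, shape: float = 4.0):
    """Frozen modified-PERT distribution (scaled Beta) on [minimum, maximum].

    ``shape`` is the PERT lambda; 4 gives the classical PERT. The Beta
    parameters are ``alpha = 1 + shape*(mode-min)/(max-min)`` and
    ``beta = 1 + shape*(max-mode)/(max-min)``.
    """
    if not (minimum <= mode <= maximum):
        raise ValueError(f"mode {mode} outside [{minimum}, {maximum}]")
    if maximum <= minimum:
        raise ValueError("maximum must exceed minimum")
    span = maximum - minimum
    a = 1.0 + shape * (mode - minimum) / span
    b = 1.0 + shape * (maximum - mode) / span
    return stats.beta(a, b, loc=minimum, scale=span)


def pert_from_mean(minimum: float, mean: float, maximum: float,
                   shape: float = 4.0):
    """Modified PERT whose *mean* (not mode) equals ``mean``.

    The PERT mean is linear in the mode, ``(min + shape*mode + max) /
    (shape + 2)``, so the mode is solved in closed form.  If the implied
    mode falls outside the support (an extremely skewed triple) the mode is
    pinned to the nearer bound and the shape parameter is solved instead.
    Degenerate triples collapse to a point mass.
    """
    if not (minimum <= mean <= maximum):
        raise ValueError(f"mean {mean} outside [{minimum}, {maximum}]")
    if maximum - minimum < 1e-12:
        return Dirac(mean)
    mode = (mean * (shape + 2.0) - minimum - maximum) / shape
    if minimum <= mode <= maximum:
        return pert(minimum, mode, maximum, shape)
    # pin the mode at the boundary and loosen the shape so the mean is kept
    pinned = minimum if mode < minimum else maximum
    # mean = (min + lam*pinned + max) / (lam + 2)  =>  solve lam > 0
    lam = (minimum + maximum - 2.0 * mean) / (mean - pinned)
    if lam <= 0:
        raise ValueError(
            f"triple ({minimum}, {mean}, {maximum}) not representable by a PERT"
        )
    return pert(minimum, pinned, maximum, lam)


def _truncnorm(loc: float, scale: float, low: float, high: float):
    a = (low - loc) / scale
    b = (high - loc) / scale
    return stats.truncnorm(a, b, loc=loc, scale=scale)


def truncnorm_matching_mean(target_mean: float, sd: float, low: float,
                            high: float):
    """Truncated normal on [low, high] whose mean equals ``target_mean``.

    ``sd`` is the scale of the underlying (pre-truncation) normal; the
    location is solved so the truncated mean matches, since truncating a
    normal centred on the published mean would shift the sample mean off
    it.
    """
    if not (low < high):
        raise ValueError("low must be < high")
    if not (low <= target_mean <= high):
        raise ValueError(f"target mean {target_mean} outside [{low}, {high}]")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd < 1e-12:
        return Dirac(target_mean)

    def gap(loc):
        return _truncnorm(loc, sd, low, high).mean() - target_mean

    lo, hi = low - 10.0 * sd, high + 10.0 * sd
    # truncated mean is strictly increasing in loc
    loc = optimize.brentq(gap, lo, hi, xtol=1e-10)
    return _truncnorm(loc, sd, low, high)
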