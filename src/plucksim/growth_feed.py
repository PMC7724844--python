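"""Gompertz growth curve, calibration to a target ADG, and feed demand.

Pigs grow along a Gompertz curve ``BW(t) = W0 * exp[mu0 * (1 - exp(-D*t)) / D]``
with ``W0`` the weight at age zero, ``mu0`` the log relative growth rate at
age zero and ``D`` its decay slope.  The curve has asymptote
``A = W0 * exp(mu0 / D)`` (mature weight).  Each scenario pins the curve to
two anchors — weaning (7 kg at 28 d) and sale (110.8 kg at the age implied
by the scenario's wean-to-finish average daily gain) — with the mature
weight fixed, which determines all three parameters in closed form.

Feed demand per growth stage is a two-coefficient model,
``feed = a * (kg live-weight gained) + b * (pig-days in stage)``,
i.e. a growth term plus a maintenance/time term; slower pigs spend longer
in each weight band and therefore eat more for the same gain.  Sow,
creep and link feeds are flat per-sow-year / per-weaned-pig allowances.
The default coefficients are calibrated against the reference annual
tonnages of the 728-sow benchmark scenarios (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GompertzParams",
    "FeedDemandParams",
    "DEFAULT_FEED_PARAMS",
    "gompertz_bw",
    "gompertz_age_at_weight",
    "calibrate_gompertz",
    "wean_to_finish_days",
    "stage_durations",
    "slaughter_age_weeks",
    "annual_feed_usage",
]


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz growth-curve parameters (kg, 1/day)."""

    w0: float
    mu0: float
    d: float

    def __post_init__(self):
        if not (self.w0 > 0 and self.mu0 > 0 and self.d > 0):
            raise ValueError("Gompertz parameters must all be positive")

    @property
    def mature_weight(self) -> float:
        """Asymptotic body weight ``W0 * exp(mu0 / D)``, kg."""
        return self.w0 * math.exp(self.mu0 / self.d)


def gompertz_bw(t, p: GompertzParams):
    """Body weight (kg) at age ``t`` days; broadcasts over arrays."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    bw = p.w0 * np.exp(p.mu0 * (1.0 - np.exp(-p.d * t)) / p.d)
    return bw if bw.ndim else float(bw)


def gompertz_age_at_weight(w, p: GompertzParams):
    """Invert the growth curve: age (days) at which weight ``w`` is reached.

    ``t(W) = -ln( ln(A/W) / k ) / D`` with ``k = mu0/D`` and asymptote A.
    """
    w = np.asarray(w, dtype=float)
    a = p.mature_weight
    if np.any(w <= 0) or np.any(w >= a):
        raise ValueError(f"weight must lie in (0, {a:.1f}) kg")
    k = p.mu0 / p.d
    t = -np.log(np.log(a / w) / k) / p.d
    return t if t.ndim else float(t)


def wean_to_finish_days(adg: float, w_wean: float = 7.0,
                        w_sale: float = 110.8):
    """Days from weaning to sale at a given mean ADG (g/day)."""
    adg = np.asarray(adg, dtype=float)
    if np.any(adg <= 0):
        raise ValueError("adg must be positive")
    days = (w_sale - w_wean) * 1000.0 / adg
    return days if days.ndim else float(days)


def calibrate_gompertz(w_wean: float = 7.0, age_wean: float = 28.0,
                       w_sale: float = 110.8, adg: float = 760.0,
                       mature_weight: float = 230.0) -> GompertzParams:
    """Gompertz curve through (age_wean, w_wean) and (age_sale, w_sale).

    ``age_sale = age_wean + (w_sale - w_wean)*1000/adg`` so the mean ADG
    over the wean-to-finish span equals the scenario ADG by construction.
    With the asymptote fixed the system is exactly determined:

        D  = ln[ ln(A/w_wean) / ln(A/w_sale) ] / (age_sale - age_wean)
        k  = ln(A/w_wean) * exp(D * age_wean),   mu0 = k * D,
        W0 = A * exp(-k)
    """
    if not (0 < w_wean < w_sale < mature_weight):
        raise ValueError("need 0 < w_wean < w_sale < mature_weight")
    span = wean_to_finish_days(adg, w_wean, w_sale)
    if span <= 0:
        raise ValueError("adg implies sale age at or before weaning")
    lw = math.log(mature_weight / w_wean)
    ls = math.log(mature_weight / w_sale)
    d = math.log(lw / ls) / span
    k = lw * math.exp(d * age_wean)
    return GompertzParams(w0=mature_weight * math.exp(-k), mu0=k * d, d=d)


def stage_durations(p: GompertzParams, transfer_weights=(19.0, 38.0),
                    w_sale: float = 110.8, age_wean: float = 28.0):
    """Day spans of each growth stage between weaning and sale.

    With the default transfer weights this is (wean->19 kg, 19->38 kg,
    38 kg->sale).  An empty transfer list yields the single wean-to-sale
    span.  The spans partition the wean-to-finish period exactly.
    """
    weights = list(transfer_weights) + [w_sale]
    ages = [age_wean] + [gompertz_age_at_weight(w, p) for w in weights]
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ValueError("transfer weights must be increasing and below sale weight")
    return [b - a for a, b in zip(ages, ages[1:])]


def slaughter_age_weeks(adg: float, weaning_age_days: float = 28.0,
                        weaning_weight_kg: float = 7.0,
                        sale_weight_kg: float = 110.8,
                        rounding: str = "ceil"):
    """Age at slaughter in whole weeks for pigs sold in weekly batches.

    ``rounding`` is "ceil" (default: a pig is sold the first week it is at
    or above target weight), "nearest", or "exact" (fractional weeks).
    """
    days = weaning_age_days + wean_to_finish_days(adg, weaning_weight_kg,
                                                  sale_weight_kg)
    weeks = np.asarray(days, dtype=float) / 7.0
    if rounding == "exact":
        out = weeks
    elif rounding == "ceil":
        out = np.ceil(weeks)
    elif rounding == "nearest":
        out = np.round(weeks)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FeedDemandParams:
    """Per-diet feed-demand coefficients.

    ``weaner_per_kg_gain``/``finisher_per_kg_gain`` are kg feed per kg
    live-weight gain; the ``*_per_day`` terms are kg feed per pig-day in
    the stage (maintenance).  Creep and link are kg per weaned pig;
    gestation and lactation are kg per sow per year.
    """

    weaner_per_kg_gain: float
    weaner_per_day: float
    finisher_per_kg_gain: float
    finisher_per_day: float
    creep_per_weaned_kg: float
    link_per_weaned_kg: float
    gestation_per_sow_kg: float
    lactation_per_sow_kg: float

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


# Calibrated so the two benchmark scenarios (760 and 671 g/day) reproduce
# the reference annual tonnages for every diet; see docs/methods.md.
DEFAULT_FEED_PARAMS = FeedDemandParams(
    weaner_per_kg_gain=0.057286,
    weaner_per_day=0.939467,
    finisher_per_kg_gain=0.450375,
    finisher_per_day=1.604699,
    creep_per_weaned_kg=3.77353,
    link_per_weaned_kg=6.94662,
    gestation_per_sow_kg=742.445,
    lactation_per_sow_kg=505.220,
)


def annual_feed_usage(*, sows, weaned_pigs, weaner_in, weaner_out,
                      finisher_in, finisher_out, weaner_gain_kg,
                      finisher_gain_kg, weaner_days, finisher_days,
                      fd: FeedDemandParams = DEFAULT_FEED_PARAMS):
    """Annual feed usage per diet, tonnes/year.  Broadcasts over arrays.

    Pigs dying in a stage are credited half the stage's gain and days
    (deaths occur uniformly through the stage), so the effective number of
    pigs through a stage is ``(in + out) / 2``.
    """
    w_eff = (np.asarray(weaner_in, dtype=float) + weaner_out) / 2.0
    f_eff = (np.asarray(finisher_in, dtype=float) + finisher_out) / 2.0
    usage = {
        "gestation": sows * fd.gestation_per_sow_kg,
        "lactation": sows * fd.lactation_per_sow_kg,
        "creep": weaned_pigs * fd.creep_per_weaned_kg,
        "link": weaned_pigs * fd.link_per_weaned_kg,
        "weaner": w_eff * (fd.weaner_per_kg_gain * weaner_gain_kg
                           + fd.weaner_per_day * weaner_days),
        "finisher": f_eff * (fd.finisher_per_kg_gain * finisher_gain_kg
                             + fd.finisher_per_day * finisher_days),
    }
    return {k: v / 1000.0 for k, v in usage.items()}


def calibrate_feed_coefficients(ref_a: dict, ref_b: dict) -> dict:
    """Solve the (gain, day) coefficient pair per stage from two reference
    scenarios.

    Each reference dict needs ``gain_kg_total`` (pig-kg gained/year),
    ``pig_days_total`` and ``feed_kg`` for one stage.  Returns
    ``{"per_kg_gain": a, "per_day": b}``.  Used to derive the frozen
    defaults; kept public so the calibration is reproducible.
    """
    m = np.array([[ref_a["gain_kg_total"], ref_a["pig_days_total"]],
                  [ref_b["gain_kg_total"], ref_b["pig_days_total"]]])
    rhs = np.array([ref_a["feed_kg"], ref_b["feed_kg"]])
    a, b = np.linalg.solve(m, rhs)
    return {"per_kg_gain": float(a), "per_day": float(b)}
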