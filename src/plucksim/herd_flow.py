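"""Weekly steady-state herd dynamics of a farrow-to-finish pig farm.

The farm runs weekly farrowing batches at steady state: every week the
same number of sows is served, farrows and weans, and one batch moves
between stages, so week 1 looks like week 52 and annual totals are 52
identical weekly flows.  The sow herd is fixed at ``herd_size``; culled
and dead sows are replaced by home-reared maiden gilts withdrawn from the
finisher pool.

Farrowing flow
--------------
By default the farrowing flow is derived from the sow reproductive cycle:

    cycle = gestation + lactation + wean-to-service
            + (1/farrowing_rate - 1) * re-service interval
            + nonproductive days
    litters/sow/year = 365.25 / cycle

so a lower farrowing rate directly lengthens the cycle and reduces the
number of litters.  Setting ``litters_per_sow_year`` explicitly on the
scenario bypasses the cycle and uses the given value (farrowings/week =
herd_size * lsy / 52).

Stage mortalities are applied as one survival factor per stage
(deaths spread uniformly over the stage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import growth_feed as gf

__all__ = [
    "ReproductionCycle",
    "DEFAULT_REPRO_CYCLE",
    "ScenarioSpec",
    "AnnualPhysicalOutputs",
    "effective_litters_per_sow_year",
    "annual_flows",
    "simulate_year",
]

WEEKS_PER_YEAR = 52
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ReproductionCycle:
    """Sow reproductive-cycle components, days.

    ``nonproductive_days`` lumps weaning-to-culling gaps, late returns and
    other empty days; the default is calibrated so that a farrowing rate
    of 89.3% yields 2.30 litters/sow/year (the benchmark herd's printed
    mean).
    """

    gestation_days: float = 115.0
    lactation_days: float = 28.0
    wean_to_service_days: float = 5.0
    reservice_interval_days: float = 21.0
    nonproductive_days: float = 8.2881


DEFAULT_REPRO_CYCLE = ReproductionCycle()


def effective_litters_per_sow_year(farrowing_rate_pct,
                                   cycle: ReproductionCycle = DEFAULT_REPRO_CYCLE):
    """Litters per sow per year implied by the reproductive cycle."""
    fr = np.asarray(farrowing_rate_pct, dtype=float) / 100.0
    if np.any(fr <= 0) or np.any(fr > 1):
        raise ValueError("farrowing rate must be in (0, 100]")
    days = (cycle.gestation_days + cycle.lactation_days
            + cycle.wean_to_service_days + cycle.nonproductive_days
            + (1.0 / fr - 1.0) * cycle.reservice_interval_days)
    lsy = DAYS_PER_YEAR / days
    return lsy if lsy.ndim else float(lsy)


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterisation of one simulated farm.

    Percentages are in [0, 100].  ``litters_per_sow_year=None`` means the
    value is derived from the reproductive cycle and farrowing rate.
    ``prices`` / ``fixed_costs`` are an economics.PriceSchedule and
    economics.FixedCostSchedule (left open here to keep this module free
    of the budgeting layer; `plucksim.scenarios` wires the defaults).
    """

    name: str
    adg: float                       # wean-to-finish average daily gain, g/day
    farrowing_rate: float            # %
    born_alive_per_litter: float
    sow_culling_rate: float          # %/year
    sow_mortality: float             # %/year
    piglet_mortality: float          # % of born alive
    weaner_mortality: float          # % over both weaner stages
    finisher_mortality: float        # %
    dressing_pct: float              # %
    herd_size: float = 728.0         # sows
    litters_per_sow_year: Optional[float] = None
    condemnation_rate: float = 1.5   # % of carcass output
    weaning_age_days: float = 28.0
    weaning_weight_kg: float = 7.0
    transfer_weights_kg: tuple = (19.0, 38.0)
    sale_weight_kg: float = 110.8
    mature_weight_kg: float = 230.0
    slaughter_rounding: str = "ceil"
    repro_cycle: ReproductionCycle = DEFAULT_REPRO_CYCLE
    feed_params: gf.FeedDemandParams = gf.DEFAULT_FEED_PARAMS
    prices: object = None
    fixed_costs: object = None

    def __post_init__(self):
        pct = {
            "farrowing_rate": self.farrowing_rate,
            "sow_culling_rate": self.sow_culling_rate,
            "sow_mortality": self.sow_mortality,
            "piglet_mortality": self.piglet_mortality,
            "weaner_mortality": self.weaner_mortality,
            "finisher_mortality": self.finisher_mortality,
            "dressing_pct": self.dressing_pct,
            "condemnation_rate": self.condemnation_rate,
        }
        for name, v in pct.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.adg <= 0:
            raise ValueError("adg must be positive")
        if self.herd_size <= 0:
            raise ValueError("herd_size must be positive")
        if self.litters_per_sow_year is not None and not (
                0 < self.litters_per_sow_year <= 3):
            raise ValueError("litters_per_sow_year must be in (0, 3]")
        w = (self.weaning_weight_kg, *self.transfer_weights_kg,
             self.sale_weight_kg)
        if any(b <= a for a, b in zip(w, w[1:])):
            raise ValueError("transfer weights must increase strictly up to sale weight")

    def growth_curve(self) -> gf.GompertzParams:
        return gf.calibrate_gompertz(
            w_wean=self.weaning_weight_kg, age_wean=self.weaning_age_days,
            w_sale=self.sale_weight_kg, adg=self.adg,
            mature_weight=self.mature_weight_kg)


@dataclass
class AnnualPhysicalOutputs:
    """Annual physical aggregates of one simulated year."""

    sows: float
    services: float
    farrowings: float
    litters_per_sow_year: float
    born_alive: float
    weaned_pigs: float
    replacement_gilts: float
    pigs_sold: float
    meat_sold_kg: float
    cull_sows_sold: float
    feed_usage_t: dict          # diet -> tonnes/year
    deaths: dict                # stage -> head/year (piglet/weaner/finisher/sow)
    stage_durations_days: tuple  # (wean->19, 19->38, 38->sale)
    slaughter_age_weeks: float

    def validate(self):
        scalars = [self.pigs_sold, self.meat_sold_kg, self.cull_sows_sold,
                   self.replacement_gilts, *self.feed_usage_t.values(),
                   *self.deaths.values()]
        if any(np.any(np.asarray(v) < 0) for v in scalars):
            raise ValueError("annual outputs must be non-negative")
        return self


def annual_flows(*, herd_size, farrowing_rate, born_alive_per_litter,
                 piglet_mortality, weaner_mortality, finisher_mortality,
                 sow_culling_rate, sow_mortality,
                 litters_per_sow_year=None,
                 repro_cycle: ReproductionCycle = DEFAULT_REPRO_CYCLE,
                 check: bool = True):
    """Annual head-count flows.  All rates in %, broadcasts over arrays.

    Returns a dict of arrays/floats: lsy, services, farrowings, born,
    weaned, finisher_in, finisher_out, gilts, sold, culled_sows,
    sow_deaths and per-stage deaths.  ``check=False`` skips the
    negative-saleable-output error (the risk engine counts such
    iterations as infeasible instead of aborting the run).
    """
    if litters_per_sow_year is None:
        lsy = effective_litters_per_sow_year(farrowing_rate, repro_cycle)
    else:
        lsy = np.asarray(litters_per_sow_year, dtype=float)
        lsy = lsy if lsy.ndim else float(lsy)
    farrowings = herd_size * lsy
    services = farrowings / (np.asarray(farrowing_rate, dtype=float) / 100.0)
    born = farrowings * born_alive_per_litter
    weaned = born * (1.0 - np.asarray(piglet_mortality, dtype=float) / 100.0)
    finisher_in = weaned * (1.0 - np.asarray(weaner_mortality, dtype=float) / 100.0)
    finisher_out = finisher_in * (1.0 - np.asarray(finisher_mortality, dtype=float) / 100.0)
    gilts = herd_size * (np.asarray(sow_culling_rate, dtype=float)
                         + sow_mortality) / 100.0
    sold = finisher_out - gilts
    if check and np.any(np.asarray(sold) < 0):
        raise ValueError("replacement-gilt demand exceeds finisher output")
    return {
        "lsy": lsy,
        "services": services,
        "farrowings": farrowings,
        "born": born,
        "weaned": weaned,
        "finisher_in": finisher_in,
        "finisher_out": finisher_out,
        "gilts": gilts,
        "sold": sold,
        "culled_sows": herd_size * np.asarray(sow_culling_rate, dtype=float) / 100.0,
        "sow_deaths": herd_size * np.asarray(sow_mortality, dtype=float) / 100.0,
        "piglet_deaths": born - weaned,
        "weaner_deaths": weaned - finisher_in,
        "finisher_deaths": finisher_in - finisher_out,
    }


def meat_sold_kg(pigs_sold, sale_weight_kg, dressing_pct, condemnation_rate):
    """Saleable carcass output: head x live weight x dressing x (1 - condemnation)."""
    return (np.asarray(pigs_sold, dtype=float) * sale_weight_kg
            * np.asarray(dressing_pct, dtype=float) / 100.0
            * (1.0 - np.asarray(condemnation_rate, dtype=float) / 100.0))


def _annual_outputs(spec: ScenarioSpec, flows: dict) -> AnnualPhysicalOutputs:
    curve = spec.growth_curve()
    d1, d2, d3 = gf.stage_durations(curve, spec.transfer_weights_kg,
                                    spec.sale_weight_kg, spec.weaning_age_days)
    w19, w38 = spec.transfer_weights_kg
    feed = gf.annual_feed_usage(
        sows=spec.herd_size,
        weaned_pigs=flows["weaned"],
        weaner_in=flows["weaned"], weaner_out=flows["finisher_in"],
        finisher_in=flows["finisher_in"], finisher_out=flows["finisher_out"],
        weaner_gain_kg=w38 - spec.weaning_weight_kg,
        finisher_gain_kg=spec.sale_weight_kg - w38,
        weaner_days=d1 + d2, finisher_days=d3,
        fd=spec.feed_params)
    meat = meat_sold_kg(flows["sold"], spec.sale_weight_kg,
                        spec.dressing_pct, spec.condemnation_rate)
    out = AnnualPhysicalOutputs(
        sows=spec.herd_size,
        services=flows["services"],
        farrowings=flows["farrowings"],
        litters_per_sow_year=flows["lsy"],
        born_alive=flows["born"],
        weaned_pigs=flows["weaned"],
        replacement_gilts=flows["gilts"],
        pigs_sold=flows["sold"],
        meat_sold_kg=meat,
        cull_sows_sold=flows["culled_sows"],
        feed_usage_t=feed,
        deaths={"piglet": flows["piglet_deaths"],
                "weaner": flows["weaner_deaths"],
                "finisher": flows["finisher_deaths"],
                "sow": flows["sow_deaths"]},
        stage_durations_days=(d1, d2, d3),
        slaughter_age_weeks=gf.slaughter_age_weeks(
            spec.adg, spec.weaning_age_days, spec.weaning_weight_kg,
            spec.sale_weight_kg, spec.slaughter_rounding),
    )
    return out.validate()


def simulate_year(spec: ScenarioSpec):
    """Simulate one steady-state year.

    Returns ``(weekly, annual)`` where ``weekly`` is a 52-row DataFrame of
    per-week stocks and flows and ``annual`` the AnnualPhysicalOutputs.
    Weekly stocks are constant (steady state) and satisfy
    stock(t+1) = stock(t) + inflow - outflow - deaths exactly.
    """
    flows = annual_flows(
        herd_size=spec.herd_size, farrowing_rate=spec.farrowing_rate,
        born_alive_per_litter=spec.born_alive_per_litter,
        piglet_mortality=spec.piglet_mortality,
        weaner_mortality=spec.weaner_mortality,
        finisher_mortality=spec.finisher_mortality,
        sow_culling_rate=spec.sow_culling_rate,
        sow_mortality=spec.sow_mortality,
        litters_per_sow_year=spec.litters_per_sow_year,
        repro_cycle=spec.repro_cycle)
    annual = _annual_outputs(spec, flows)

    d1, d2, d3 = annual.stage_durations_days
    weeks = {"piglets": math.ceil(spec.weaning_age_days / 7),
             "weaner1": math.ceil(d1 / 7),
             "weaner2": math.ceil(d2 / 7),
             "finishers": math.ceil(d3 / 7)}
    if sum(weeks.values()) > WEEKS_PER_YEAR:
        raise ValueError("stage durations exceed 52 weeks")

    wk = {k: v / WEEKS_PER_YEAR for k, v in flows.items()}
    # split the single weaner mortality over the two housing stages in
    # proportion to time spent in each
    w_loss = wk["weaned"] - wk["finisher_in"]
    loss1 = w_loss * d1 / (d1 + d2)
    w1_out = wk["weaned"] - loss1
    lactating = wk["farrowings"] * weeks["piglets"]
    gestating = spec.herd_size - lactating
    if gestating < 0:
        raise ValueError("lactating sows exceed herd size")

    def stock(inflow, outflow, n_weeks):
        # average of entry and exit batch sizes, held for n_weeks
        return (inflow + outflow) / 2.0 * n_weeks

    rows = []
    for week in range(1, WEEKS_PER_YEAR + 1):
        rows.append({
            "week": week,
            # stocks
            "maiden_gilts": wk["gilts"] * 8.0,   # retained 24-32 wk of age
            "gestating": gestating,
            "lactating": lactating,
            "piglets": stock(wk["born"], wk["weaned"], weeks["piglets"]),
            "weaner1": stock(wk["weaned"], w1_out, weeks["weaner1"]),
            "weaner2": stock(w1_out, wk["finisher_in"], weeks["weaner2"]),
            "finishers": stock(wk["finisher_in"], wk["finisher_out"],
                               weeks["finishers"]),
            # flows
            "services": wk["services"],
            "farrowings": wk["farrowings"],
            "births": wk["born"],
            "weanings": wk["weaned"],
            "transfers_w1_w2": w1_out,
            "transfers_w2_fin": wk["finisher_in"],
            "finishers_sold": wk["sold"],
            "gilts_retained": wk["gilts"],
            "sows_culled": wk["culled_sows"],
            "sow_deaths": wk["sow_deaths"],
            "piglet_deaths": wk["piglet_deaths"],
            "weaner1_deaths": loss1,
            "weaner2_deaths": w_loss - loss1,
            "finisher_deaths": wk["finisher_deaths"],
        })
    weekly = pd.DataFrame(rows)
    return weekly, annual
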