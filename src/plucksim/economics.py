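"""Enterprise budget: itemised profit & loss account for one simulated year.

Income is the sale of finisher pigs (priced per kg cold carcass) and
culled sows.  Variable costs cover the six diets, replacement-gilt
production, dead-animal disposal, healthcare, reproduction, manure
handling and transport; fixed costs are a flat annual schedule shared
across scenarios.  Gross margin = sales - variable costs; net profit =
gross margin - fixed costs.  Currency totals are accumulated in exact
decimal cents so the account identities hold to the cent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .herd_flow import AnnualPhysicalOutputs

__all__ = [
    "PriceSchedule",
    "FixedCostSchedule",
    "ProfitLossAccount",
    "DEFAULT_PRICES",
    "DEFAULT_FIXED_COSTS",
    "build_pnl",
    "compare_scenarios",
]

_CENT = Decimal("0.01")

DIETS = ("gestation", "lactation", "creep", "link", "weaner", "finisher")

VARIABLE_LINES = tuple(f"{d}_feed" for d in DIETS) + (
    "replacement_gilts", "dead_disposal", "healthcare", "reproduction",
    "manure", "transport")
SALES_LINES = ("finisher_pigs", "culled_sows")
FIXED_LINES = ("admin", "energy", "insurance", "repairs",
               "epa_subscription", "labour", "loan_interest", "depreciation")


@dataclass(frozen=True)
class PriceSchedule:
    """Unit prices and cost rates (EUR).

    Defaults are calibrated from the 2017 benchmark ratios of the 728-sow
    reference farm (e.g. pork = finisher sales / kg meat sold); they are
    plain config values and freely overridable.
    """

    pork_price_per_kg: float = 1.6191        # EUR/kg cold carcass
    cull_sow_price: float = 120.0            # EUR/head
    feed_prices_per_t: dict = field(default_factory=lambda: {
        "gestation": 233.97, "lactation": 257.61, "creep": 921.54,
        "link": 594.10, "weaner": 260.37, "finisher": 237.96})
    replacement_gilt_cost: float = 161.91    # EUR/head reared
    disposal_price_per_kg: float = 0.17670   # EUR/kg carcass disposed
    disposal_weights_kg: dict = field(default_factory=lambda: {
        "piglet": 4.0, "weaner": 22.5, "finisher": 74.4, "sow": 230.0})
    healthcare_per_weaned: float = 1.9898    # vaccines etc., EUR/weaned pig
    vet_visits_per_year: float = 1200.0      # 4 visits x EUR 300
    reproduction_per_sow: float = 51.249     # EUR/sow/year
    manure_per_pig_sold: float = 0.83204
    transport_per_pig_sold: float = 0.94010

    def validate(self):
        vals = [self.pork_price_per_kg, self.cull_sow_price,
                self.replacement_gilt_cost, self.disposal_price_per_kg,
                self.healthcare_per_weaned, self.vet_visits_per_year,
                self.reproduction_per_sow, self.manure_per_pig_sold,
                self.transport_per_pig_sold,
                *self.feed_prices_per_t.values(),
                *self.disposal_weights_kg.values()]
        if any(v < 0 for v in vals):
            raise ValueError("prices must be non-negative")
        return self


@dataclass(frozen=True)
class FixedCostSchedule:
    """Annual fixed costs, EUR/year; identical across scenarios."""

    admin: float = 2500.0
    energy: float = 81614.0
    insurance: float = 20533.0
    repairs: float = 20533.0
    epa_subscription: float = 10000.0
    labour: float = 279136.0
    loan_interest: float = 75780.0
    depreciation: float = 175021.0

    def lines(self) -> dict:
        return {name: getattr(self, name) for name in FIXED_LINES}

    def total(self) -> float:
        return float(sum(self.lines().values()))


DEFAULT_PRICES = PriceSchedule()
DEFAULT_FIXED_COSTS = FixedCostSchedule()


def _to_cents(x) -> Decimal:
    return Decimal(repr(float(x))).quantize(_CENT, rounding=ROUND_HALF_UP)


@dataclass
class ProfitLossAccount:
    """Itemised annual profit & loss account.

    Line values are stored as exact Decimals (cents); totals are sums of
    the lines so the account identities are exact by construction.
    """

    name: str
    sales: dict
    variable: dict
    fixed: dict
    pigs_sold: float
    meat_sold_kg: float

    @classmethod
    def from_lines(cls, name, sales, variable, fixed, pigs_sold,
                   meat_sold_kg) -> "ProfitLossAccount":
        """Build an account from itemised annual lines (EUR/year)."""
        acct = cls(name=name,
                   sales={k: _to_cents(v) for k, v in sales.items()},
                   variable={k: _to_cents(v) for k, v in variable.items()},
                   fixed={k: _to_cents(v) for k, v in fixed.items()},
                   pigs_sold=float(pigs_sold),
                   meat_sold_kg=float(meat_sold_kg))
        return acct.validate()

    def validate(self):
        if any(v < 0 for d in (self.sales, self.variable, self.fixed)
               for v in d.values()):
            raise ValueError("account lines must be non-negative")
        return self

    # ---- totals (exact by construction) ----
    @property
    def total_sales(self) -> Decimal:
        return sum(self.sales.values(), Decimal(0))

    @property
    def total_variable(self) -> Decimal:
        return sum(self.variable.values(), Decimal(0))

    @property
    def total_fixed(self) -> Decimal:
        return sum(self.fixed.values(), Decimal(0))

    @property
    def gross_margin(self) -> Decimal:
        return self.total_sales - self.total_variable

    @property
    def total_costs(self) -> Decimal:
        return self.total_variable + self.total_fixed

    @property
    def net_profit(self) -> Decimal:
        return self.gross_margin - self.total_fixed

    # ---- views ----
    def all_lines(self) -> dict:
        lines = {}
        lines.update({k: v for k, v in self.sales.items()})
        lines["total_sales"] = self.total_sales
        lines.update({k: v for k, v in self.variable.items()})
        lines["total_variable"] = self.total_variable
        lines["gross_margin"] = self.gross_margin
        lines.update({k: v for k, v in self.fixed.items()})
        lines["total_fixed"] = self.total_fixed
        lines["total_costs"] = self.total_costs
        lines["net_profit"] = self.net_profit
        return lines

    def per_pig(self, line: str) -> float:
        if self.pigs_sold == 0:
            raise ZeroDivisionError("no pigs sold")
        return float(self.all_lines()[line]) / self.pigs_sold

    def per_kg(self, line: str) -> float:
        if self.meat_sold_kg == 0:
            raise ZeroDivisionError("no meat sold")
        return float(self.all_lines()[line]) / self.meat_sold_kg

    def to_frame(self) -> pd.DataFrame:
        """Annual / per-pig / per-kg columns for every line."""
        lines = self.all_lines()
        return pd.DataFrame({
            "eur_per_year": {k: float(v) for k, v in lines.items()},
            "eur_per_pig": {k: self.per_pig(k) for k in lines},
            "eur_per_kg": {k: self.per_kg(k) for k in lines},
        })

    def report(self) -> str:
        df = self.to_frame()
        return df.to_string(float_format=lambda x: f"{x:,.2f}")


def variable_cost_lines(phys, prices: PriceSchedule) -> dict:
    """Variable-cost lines (EUR/year) from physical outputs.

    Works elementwise on array-valued physical outputs (used by the Monte
    Carlo engine), returning float arrays instead of Decimals.
    """
    lines = {}
    for diet in DIETS:
        lines[f"{diet}_feed"] = (np.asarray(phys.feed_usage_t[diet], dtype=float)
                                 * prices.feed_prices_per_t[diet])
    lines["replacement_gilts"] = phys.replacement_gilts * prices.replacement_gilt_cost
    lines["dead_disposal"] = sum(
        np.asarray(phys.deaths[stage], dtype=float)
        * prices.disposal_weights_kg[stage] * prices.disposal_price_per_kg
        for stage in ("piglet", "weaner", "finisher", "sow"))
    lines["healthcare"] = (prices.vet_visits_per_year
                           + np.asarray(phys.weaned_pigs, dtype=float)
                           * prices.healthcare_per_weaned)
    lines["reproduction"] = phys.sows * prices.reproduction_per_sow
    lines["manure"] = np.asarray(phys.pigs_sold, dtype=float) * prices.manure_per_pig_sold
    lines["transport"] = np.asarray(phys.pigs_sold, dtype=float) * prices.transport_per_pig_sold
    return lines


def sales_lines(phys, prices: PriceSchedule) -> dict:
    return {
        "finisher_pigs": np.asarray(phys.meat_sold_kg, dtype=float) * prices.pork_price_per_kg,
        "culled_sows": np.asarray(phys.cull_sows_sold, dtype=float) * prices.cull_sow_price,
    }


def build_pnl(phys: AnnualPhysicalOutputs, prices: PriceSchedule = DEFAULT_PRICES,
              fixed: FixedCostSchedule = DEFAULT_FIXED_COSTS,
              name: str = "scenario") -> ProfitLossAccount:
    """Assemble the annual profit & loss account for one scenario."""
    prices.validate()
    return ProfitLossAccount.from_lines(
        name=name,
        sales=sales_lines(phys, prices),
        variable=variable_cost_lines(phys, prices),
        fixed=fixed.lines(),
        pigs_sold=phys.pigs_sold,
        meat_sold_kg=phys.meat_sold_kg)


def compare_scenarios(accounts: dict) -> pd.DataFrame:
    """Pairwise line deltas of named accounts against the first (reference).

    Returns a DataFrame indexed by account line with one absolute-value
    column per account plus ``<name>_vs_<ref>_pct`` percentage-change
    columns (base = reference scenario, 1 decimal).
    """
    if len(accounts) < 2:
        raise ValueError("need at least two accounts to compare")
    names = list(accounts)
    line_sets = [tuple(a.all_lines()) for a in accounts.values()]
    if len(set(line_sets)) != 1:
        raise ValueError("accounts have mismatched line sets")
    ref_name = names[0]
    data = {n: {k: float(v) for k, v in a.all_lines().items()}
            for n, a in accounts.items()}
    df = pd.DataFrame(data)
    ref = df[ref_name]
    for n in names[1:]:
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = (df[n] - ref) / ref * 100.0
        df[f"{n}_vs_{ref_name}_pct"] = pct.round(1)
    return df
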