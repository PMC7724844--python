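"""Monte Carlo risk analysis of annual gross margin and net profit.

Each stochastic input (the scenario's biological parameters and the pork
and feed prices) is given a modified-PERT distribution fitted to its
(min, mean, max) triple.  Rank correlation between the biological inputs
is induced with the Iman–Conover method, which reorders independently
drawn samples to match a target Spearman matrix while preserving every
marginal exactly.  Each iteration overrides the scenario fields with the
sampled values, runs the full deterministic pipeline (herd flows ->
growth/feed -> budget) and records gross margin and net profit; the whole
computation is vectorised over iterations.

Price draws are shared across scenarios inside a comparison run (common
market conditions), so cross-scenario profit differences reflect the
biology, not independent price noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import economics, herd_flow, scenarios
from . import growth_feed as gf
from .distributions import pert_from_mean
from .synthetic_cohort import generate_cohort

__all__ = [
    "StochasticInputSpec",
    "RiskResult",
    "BIO_INPUTS",
    "PRICE_INPUTS",
    "fit_distribution",
    "default_input_specs",
    "default_price_triples",
    "default_correlation",
    "correlate_samples",
    "nearest_psd_correlation",
    "run_monte_carlo",
    "run_scenario_comparison",
    "sample_price_draws",
]

# biological scenario fields sampled per iteration (litters/sow/year is
# derived from the sampled farrowing rate through the reproductive cycle)
BIO_INPUTS = (
    "farrowing_rate", "born_alive_per_litter", "sow_culling_rate",
    "sow_mortality", "piglet_mortality", "weaner_mortality",
    "finisher_mortality", "dressing_pct",
)

PRICE_INPUTS = ("pork_price",) + tuple(
    f"{diet}_feed_price" for diet in economics.DIETS)


@dataclass(frozen=True)
class StochasticInputSpec:
    """One stochastic model input: its triple, bounds and fitted distribution."""

    name: str
    triple: tuple          # (min, mean, max)
    dist: object           # frozen distribution with .rvs / .mean
    bounds: tuple          # hard truncation (defaults to (min, max))


def fit_distribution(name: str, triple) -> StochasticInputSpec:
    """Fit a modified PERT to a (min, mean, max) triple.

    The mode is solved so the distribution mean equals the triple's mean;
    a degenerate triple (min == max) yields a point mass.
    """
    lo, mid, hi = (float(v) for v in triple)
    if lo > hi:
        raise ValueError("min must be <= max")
    return StochasticInputSpec(name=name, triple=(lo, mid, hi),
                               dist=pert_from_mean(lo, mid, hi),
                               bounds=(lo, hi))


def default_price_triples(prices: economics.PriceSchedule = economics.DEFAULT_PRICES,
                          variation: float = scenarios.PRICE_VARIATION) -> dict:
    """Symmetric (min, mean, max) triples around the calibrated price levels."""
    triples = {"pork_price": (prices.pork_price_per_kg * (1 - variation),
                              prices.pork_price_per_kg,
                              prices.pork_price_per_kg * (1 + variation))}
    for diet in economics.DIETS:
        p = prices.feed_prices_per_t[diet]
        triples[f"{diet}_feed_price"] = (p * (1 - variation), p,
                                         p * (1 + variation))
    return triples


def default_input_specs(scenario_name: str) -> list:
    """Stochastic input specs for one scenario: 8 biological + 7 prices."""
    bio = scenarios.PARAMETER_TRIPLES[scenario_name]
    specs = [fit_distribution(name, bio[name]) for name in BIO_INPUTS]
    specs += [fit_distribution(name, triple)
              for name, triple in default_price_triples().items()]
    return specs


def nearest_psd_correlation(matrix: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix into a positive semi-definite correlation
    matrix by eigenvalue clipping and diagonal rescaling."""
    m = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(m)
    m = (vecs * np.clip(vals, eps, None)) @ vecs.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m


def default_correlation(seed: int = 0) -> pd.DataFrame:
    """Spearman correlation of the biological inputs, estimated from a
    default synthetic cohort (so the pipeline is self-contained)."""
    cohort = generate_cohort(scenarios.DEFAULT_CLUSTERS, seed=seed)
    corr = cohort[list(BIO_INPUTS)].corr(method="spearman")
    repaired = nearest_psd_correlation(corr.to_numpy())
    return pd.DataFrame(repaired, index=corr.index, columns=corr.columns)


def correlate_samples(draws: np.ndarray, target: np.ndarray,
                      rng=None) -> np.ndarray:
    """Iman–Conover rank reordering toward a target Spearman matrix.

    Each column of the output is a permutation of the corresponding input
    column (marginals preserved exactly); the empirical Spearman
    correlation approaches ``target`` as the sample size grows.
    """
    draws = np.asarray(draws, dtype=float)
    target = np.asarray(target, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be an (n_iter, n_vars) matrix")
    n, k = draws.shape
    if target.shape != (k, k):
        raise ValueError(f"target must be {k}x{k}")
    if not np.allclose(target, target.T, atol=1e-10):
        raise ValueError("target must be symmetric")
    if not np.allclose(np.diag(target), 1.0, atol=1e-10):
        raise ValueError("target must have a unit diagonal")
    rng = np.random.default_rng(rng)

    # Spearman -> Pearson of the normal scores, then ensure PSD
    pearson = nearest_psd_correlation(2.0 * np.sin(np.pi * target / 6.0))
    c = np.linalg.cholesky(pearson + 1e-12 * np.eye(k))

    scores = stats.norm.ppf(np.arange(1, n + 1) / (n + 1.0))
    m = np.column_stack([scores[rng.permutation(n)] for _ in range(k)])
    # strip the sampling noise correlation of the score matrix itself
    e = nearest_psd_correlation(np.corrcoef(m, rowvar=False))
    q = np.linalg.cholesky(e + 1e-12 * np.eye(k))
    m_target = m @ np.linalg.inv(q).T @ c.T

    out = np.empty_like(draws)
    for j in range(k):
        ranks = stats.rankdata(m_target[:, j], method="ordinal") - 1
        out[:, j] = np.sort(draws[:, j])[ranks.astype(int)]
    return out


@dataclass
class RiskResult:
    """Per-iteration profit outcomes of one scenario and their summaries."""

    scenario: str
    n_iter: int
    seed: int
    gross_margin: np.ndarray     # EUR/year, one entry per iteration
    net_profit: np.ndarray
    pigs_sold: np.ndarray
    meat_sold_kg: np.ndarray
    n_infeasible: int = 0

    def _views(self, values):
        return {"eur_per_year": values,
                "eur_per_pig": values / self.pigs_sold,
                "eur_per_kg": values / self.meat_sold_kg}

    def summary(self) -> pd.DataFrame:
        """Mean, SD, 5th/95th percentiles, min and max of gross margin and
        net profit on the annual, per-pig and per-kg scales."""
        rows = {}
        for metric, values in (("gross_margin", self.gross_margin),
                               ("net_profit", self.net_profit)):
            for unit, v in self._views(values).items():
                rows[(metric, unit)] = {
                    "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                    "p5": float(np.percentile(v, 5)),
                    "p95": float(np.percentile(v, 95)),
                    "min": float(np.min(v)), "max": float(np.max(v)),
                }
        out = pd.DataFrame(rows).T
        out.index.names = ["metric", "unit"]
        return out

    def iterations_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gross_margin_eur": self.gross_margin,
            "net_profit_eur": self.net_profit,
            "pigs_sold": self.pigs_sold,
            "meat_sold_kg": self.meat_sold_kg,
        })


def _evaluate(spec: herd_flow.ScenarioSpec, sampled: dict):
    """Vectorised deterministic pipeline under sampled input arrays."""
    flows = herd_flow.annual_flows(
        herd_size=spec.herd_size,
        farrowing_rate=sampled["farrowing_rate"],
        born_alive_per_litter=sampled["born_alive_per_litter"],
        piglet_mortality=sampled["piglet_mortality"],
        weaner_mortality=sampled["weaner_mortality"],
        finisher_mortality=sampled["finisher_mortality"],
        sow_culling_rate=sampled["sow_culling_rate"],
        sow_mortality=sampled["sow_mortality"],
        litters_per_sow_year=spec.litters_per_sow_year,
        repro_cycle=spec.repro_cycle,
        check=False)
    n_infeasible = int(np.sum(np.asarray(flows["sold"]) < 0))

    curve = spec.growth_curve()
    d1, d2, d3 = gf.stage_durations(curve, spec.transfer_weights_kg,
                                    spec.sale_weight_kg, spec.weaning_age_days)
    w19, w38 = spec.transfer_weights_kg
    feed = gf.annual_feed_usage(
        sows=spec.herd_size, weaned_pigs=flows["weaned"],
        weaner_in=flows["weaned"], weaner_out=flows["finisher_in"],
        finisher_in=flows["finisher_in"], finisher_out=flows["finisher_out"],
        weaner_gain_kg=w38 - spec.weaning_weight_kg,
        finisher_gain_kg=spec.sale_weight_kg - w38,
        weaner_days=d1 + d2, finisher_days=d3, fd=spec.feed_params)
    meat = herd_flow.meat_sold_kg(flows["sold"], spec.sale_weight_kg,
                                  sampled["dressing_pct"],
                                  spec.condemnation_rate)

    base_prices = spec.prices if spec.prices is not None else economics.DEFAULT_PRICES
    prices = replace(
        base_prices,
        pork_price_per_kg=sampled.get("pork_price", base_prices.pork_price_per_kg),
        feed_prices_per_t={
            diet: sampled.get(f"{diet}_feed_price",
                              base_prices.feed_prices_per_t[diet])
            for diet in economics.DIETS})

    phys = herd_flow.AnnualPhysicalOutputs(
        sows=spec.herd_size, services=flows["services"],
        farrowings=flows["farrowings"], litters_per_sow_year=flows["lsy"],
        born_alive=flows["born"], weaned_pigs=flows["weaned"],
        replacement_gilts=flows["gilts"], pigs_sold=flows["sold"],
        meat_sold_kg=meat, cull_sows_sold=flows["culled_sows"],
        feed_usage_t=feed,
        deaths={"piglet": flows["piglet_deaths"],
                "weaner": flows["weaner_deaths"],
                "finisher": flows["finisher_deaths"],
                "sow": flows["sow_deaths"]},
        stage_durations_days=(d1, d2, d3),
        slaughter_age_weeks=gf.slaughter_age_weeks(
            spec.adg, spec.weaning_age_days, spec.weaning_weight_kg,
            spec.sale_weight_kg, spec.slaughter_rounding))

    sales = economics.sales_lines(phys, prices)
    variable = economics.variable_cost_lines(phys, prices)
    fixed_total = (spec.fixed_costs or economics.DEFAULT_FIXED_COSTS).total()
    gross_margin = sum(sales.values()) - sum(variable.values())
    net_profit = gross_margin - fixed_total
    return {"gross_margin": np.asarray(gross_margin, dtype=float),
            "net_profit": np.asarray(net_profit, dtype=float),
            "pigs_sold": np.asarray(flows["sold"], dtype=float),
            "meat_sold_kg": np.asarray(meat, dtype=float),
            "n_infeasible": n_infeasible}


def sample_price_draws(n_iter: int, seed,
                       prices: economics.PriceSchedule = economics.DEFAULT_PRICES,
                       variation: float = scenarios.PRICE_VARIATION) -> dict:
    """Independent PERT price draws, one array per price input."""
    rng = np.random.default_rng(seed)
    triples = default_price_triples(prices, variation)
    return {name: fit_distribution(name, t).dist.rvs(size=n_iter,
                                                     random_state=rng)
            for name, t in triples.items()}


def run_monte_carlo(spec: herd_flow.ScenarioSpec, inputs=None,
                    corr: Optional[pd.DataFrame] = None,
                    n_iter: int = 10_000, seed: int = 0,
                    shared_draws: Optional[dict] = None) -> RiskResult:
    """Run the correlated Monte Carlo simulation for one scenario.

    ``inputs`` defaults to the scenario's 8 biological triples plus the 7
    price triples.  ``corr`` is a Spearman target (DataFrame labelled by
    input names) applied to the named subset via Iman–Conover; by default
    the biological-input matrix estimated from the synthetic cohort.
    ``shared_draws`` overrides the raw draws of named inputs (used to share
    price draws across scenarios).  Deterministic given (spec, seed).
    """
    if inputs is None:
        inputs = default_input_specs(spec.name)
    if corr is None:
        corr = default_correlation()
    shared_draws = shared_draws or {}

    master = np.random.SeedSequence(seed)
    draw_ss, ic_ss = master.spawn(2)
    rng = np.random.default_rng(draw_ss)
    sampled = {}
    for inp in inputs:
        if inp.name in shared_draws:
            values = np.asarray(shared_draws[inp.name], dtype=float)
            if values.shape != (n_iter,):
                raise ValueError(f"shared draws for {inp.name} have wrong length")
        else:
            values = inp.dist.rvs(size=n_iter, random_state=rng)
        sampled[inp.name] = values

    corr_names = [n for n in corr.columns if n in sampled]
    if corr_names:
        block = np.column_stack([sampled[n] for n in corr_names])
        reordered = correlate_samples(
            block, corr.loc[corr_names, corr_names].to_numpy(),
            rng=np.random.default_rng(ic_ss))
        for j, n in enumerate(corr_names):
            sampled[n] = reordered[:, j]

    out = _evaluate(spec, sampled)
    return RiskResult(scenario=spec.name, n_iter=n_iter, seed=seed,
                      gross_margin=out["gross_margin"],
                      net_profit=out["net_profit"],
                      pigs_sold=out["pigs_sold"],
                      meat_sold_kg=out["meat_sold_kg"],
                      n_infeasible=out["n_infeasible"])


def run_scenario_comparison(specs: Optional[dict] = None,
                            n_iter: int = 10_000, seed: int = 0,
                            corr: Optional[pd.DataFrame] = None) -> dict:
    """Monte Carlo runs for several scenarios with shared price draws.

    Returns ``{scenario name: RiskResult}``.  Within an iteration all
    scenarios see the same pork and feed prices; biological draws are
    scenario-specific.
    """
    if specs is None:
        specs = scenarios.default_scenarios()
    if corr is None:
        corr = default_correlation()
    master = np.random.SeedSequence(seed)
    price_ss, *scen_ss = master.spawn(1 + len(specs))
    prices = sample_price_draws(n_iter, price_ss)
    results = {}
    for (name, spec), ss in zip(specs.items(), scen_ss):
        sub_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        results[name] = run_monte_carlo(spec, corr=corr, n_iter=n_iter,
                                        seed=sub_seed, shared_draws=prices)
    return results
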