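"""Synthetic 56-farm cohort with the structure of the study population.

The emulated cohort is three clusters of farrow-to-finish farms that
differ in slaughter-check lung lesions and wean-to-finish growth:

* 17 farms with low pleurisy (< 25%) and low lung scars (< 8%), ADG ~760 g/d;
* 29 farms with low pleurisy but scars >= 8%, ADG ~725 g/d;
* 10 farms with pleurisy >= 25%, ADG ~671 g/d.

Lesion prevalences are drawn from truncated normals clipped to [0, 100]
and to the cluster's side of the relevant cut-off, with the underlying
location solved so the post-truncation mean equals the cluster mean.
Performance indicators are drawn from modified-PERT distributions
parameterised by each cluster's (min, mean, max) triple.  Within-farm
indicators are sampled independently; lesions not tied to a cluster
(pneumonia-like lesions, abscesses, pericarditis, milk spots) share one
cohort-wide distribution so they carry no signal about ADG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distributions import pert_from_mean, truncnorm_matching_mean

__all__ = [
    "ClusterSpec",
    "FARM_COLUMNS",
    "LESION_COLUMNS",
    "INDICATOR_COLUMNS",
    "generate_cohort",
    "validate_cohort",
    "write_cohort",
    "read_cohort",
]

LESION_COLUMNS = [
    "prev_pleurisy", "prev_ep_like", "prev_scars", "prev_abscess",
    "prev_pericarditis", "prev_milk_spots",
]

INDICATOR_COLUMNS = [
    "farrowing_rate", "litters_per_sow_year", "born_alive_per_litter",
    "sow_culling_rate", "sow_mortality", "piglet_mortality",
    "weaner_mortality", "finisher_mortality", "dressing_pct",
]

FARM_COLUMNS = ["farm_id"] + LESION_COLUMNS + ["adg"] + INDICATOR_COLUMNS

# cohort-wide (cluster-independent) lesion distributions: (mean, sd) in %,
# truncated to [0, 100].  Stand-ins chosen to look like a typical abattoir
# lesion-prevalence survey; they carry no association with ADG by design.
BACKGROUND_LESIONS = {
    "prev_ep_like": (12.0, 10.0),
    "prev_abscess": (2.0, 2.5),
    "prev_pericarditis": (4.0, 3.5),
    "prev_milk_spots": (8.0, 8.0),
}

_PCT_BOUNDED = set(LESION_COLUMNS) | {
    "farrowing_rate", "sow_culling_rate", "sow_mortality",
    "piglet_mortality", "weaner_mortality", "finisher_mortality",
    "dressing_pct",
}


@dataclass(frozen=True)
class ClusterSpec:
    """One farm cluster: lesion distributions, ADG level, indicator triples.

    ``pleurisy_bounds``/``scars_bounds`` clip the truncated normals to the
    cluster's side of the tree cut-offs so the partition structure is
    recoverable.  ``indicator_ranges`` maps indicator name ->
    (min, mean, max).
    """

    name: str
    n_farms: int
    pleurisy_mean: float
    pleurisy_sd: float
    pleurisy_bounds: tuple
    scars_mean: float
    scars_sd: float
    scars_bounds: tuple
    adg_mean: float
    indicator_ranges: dict
    adg_sd: float = 20.0

    def __post_init__(self):
        if self.n_farms < 1:
            raise ValueError("n_farms must be >= 1")
        if self.pleurisy_sd < 0 or self.scars_sd < 0 or self.adg_sd < 0:
            raise ValueError("sd must be >= 0")
        for lo, hi in (self.pleurisy_bounds, self.scars_bounds):
            if not (0 <= lo < hi <= 100):
                raise ValueError("lesion bounds must satisfy 0 <= lo < hi <= 100")
        for name, (lo, mid, hi) in self.indicator_ranges.items():
            if not (lo <= mid <= hi):
                raise ValueError(f"indicator {name}: need min <= mean <= max")


def _draw_lesion(rng, n, mean, sd, bounds):
    lo, hi = bounds
    if not (lo <= mean <= hi):
        raise ValueError(f"lesion mean {mean} outside truncation bounds {bounds}")
    dist = truncnorm_matching_mean(mean, sd, lo, hi)
    return np.clip(dist.rvs(size=n, random_state=rng), 0.0, 100.0)


def generate_cohort(clusters, seed: int) -> pd.DataFrame:
    """Generate one cohort table, one row per farm.

    Per-cluster random streams are spawned deterministically from the
    master seed, so identical (clusters, seed) give identical tables.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("cluster list is empty")
    streams = np.random.SeedSequence(seed).spawn(len(clusters))
    frames = []
    farm_no = 0
    for spec, ss in zip(clusters, streams):
        rng = np.random.default_rng(ss)
        n = spec.n_farms
        row = {
            "farm_id": [f"{spec.name}_{farm_no + i + 1:03d}" for i in range(n)],
            "prev_pleurisy": _draw_lesion(rng, n, spec.pleurisy_mean,
                                          spec.pleurisy_sd, spec.pleurisy_bounds),
            "prev_scars": _draw_lesion(rng, n, spec.scars_mean,
                                       spec.scars_sd, spec.scars_bounds),
        }
        for col, (mean, sd) in BACKGROUND_LESIONS.items():
            row[col] = _draw_lesion(rng, n, mean, sd, (0.0, 100.0))
        row["adg"] = np.maximum(rng.normal(spec.adg_mean, spec.adg_sd, size=n), 1.0)
        for col in INDICATOR_COLUMNS:
            lo, mid, hi = spec.indicator_ranges[col]
            row[col] = pert_from_mean(lo, mid, hi).rvs(size=n, random_state=rng)
        frames.append(pd.DataFrame(row))
        farm_no += n
    cohort = pd.concat(frames, ignore_index=True)[FARM_COLUMNS]
    return validate_cohort(cohort)


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the farm-record invariants; returns the cohort unchanged."""
    missing = [c for c in FARM_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    for col in _PCT_BOUNDED:
        v = cohort[col]
        if (v < 0).any() or (v > 100).any():
            raise ValueError(f"{col} outside [0, 100]")
    if (cohort["adg"] <= 0).any():
        raise ValueError("adg must be positive")
    lsy = cohort["litters_per_sow_year"]
    if (lsy <= 0).any() or (lsy > 3).any():
        raise ValueError("litters_per_sow_year outside (0, 3]")
    return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))
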