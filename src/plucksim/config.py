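"""YAML configuration for cluster specs and scenario specs.

One structured-text dialect for every config the pipeline consumes:
cluster lists for the cohort generator and scenario files for the
simulation.  Omitted scenario fields fall back to the dataclass defaults
(prices, fixed costs, feed coefficients, reproductive cycle included), so
a minimal scenario file only needs the biological parameters.
"""

from __future__ import annotations

import dataclasses

import yaml

from .economics import FixedCostSchedule, PriceSchedule
from .growth_feed import FeedDemandParams
from .herd_flow import ReproductionCycle, ScenarioSpec
from .synthetic_cohort import ClusterSpec

__all__ = [
    "load_clusters", "dump_clusters",
    "load_scenario", "dump_scenario",
]

_NESTED = {
    "repro_cycle": ReproductionCycle,
    "feed_params": FeedDemandParams,
    "prices": PriceSchedule,
    "fixed_costs": FixedCostSchedule,
}


def _plain(value):
    if dataclasses.is_dataclass(value):
        return {f.name: _plain(getattr(value, f.name))
                for f in dataclasses.fields(value)}
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    return value


def dump_clusters(clusters, path) -> None:
    doc = {"clusters": [_plain(c) for c in clusters]}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_clusters(path):
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    out = []
    for entry in doc["clusters"]:
        entry = dict(entry)
        for key in ("pleurisy_bounds", "scars_bounds"):
            entry[key] = tuple(entry[key])
        entry["indicator_ranges"] = {k: tuple(v) for k, v
                                     in entry["indicator_ranges"].items()}
        out.append(ClusterSpec(**entry))
    return tuple(out)


def dump_scenario(spec: ScenarioSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"scenario": _plain(spec)}, fh, sort_keys=False)


def load_scenario(path) -> ScenarioSpec:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entry = dict(doc["scenario"])
    for key, cls in _NESTED.items():
        if entry.get(key) is not None:
            entry[key] = cls(**entry[key])
    if "transfer_weights_kg" in entry:
        entry["transfer_weights_kg"] = tuple(entry["transfer_weights_kg"])
    return ScenarioSpec(**entry)
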