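"""YAML-backed pipeline configuration; defaults reproduce the study design."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from . import defaults
from .types import Habit, PanelConfig, PolytunnelDesign, PouchDesign

DEFAULT_CONFIG: dict = {
    "panel": {
        **{h.value: c for h, c in defaults.HABIT_COUNTS.items()},
        "n_reference": defaults.N_REFERENCE,
        "n_filler": defaults.N_FILLER,
    },
    "pouch": {
        "n_runs": defaults.ROOT_RUNS,
        "frames_per_run": 4,
        "trays_per_frame": 9,
        "pouches_per_frame": 96,
        "plants_per_pouch": 2,
    },
    "polytunnel": {
        "n_replicates": 5,
        "tunnel_a_replicates": 3,
        "subblocks_per_replicate": 12,
        "units_per_subblock": 36,
    },
    "icpms": {
        "leaf_runs": defaults.LEAF_ICPMS_RUNS,
        "leaf_samples": defaults.LEAF_SAMPLE_TARGET,
        "seed_runs": defaults.SEED_ICPMS_RUNS,
        "seed_samples": defaults.SEED_SAMPLE_TARGET,
        "drift_amplitude": 0.05,
    },
    "exclusion": {
        "leaf": list(defaults.LEAF_EXCLUDED),
        "seed": list(defaults.SEED_EXCLUDED),
    },
    "attrition_rate": defaults.ATTRITION_RATE,
    "min_radicle_cm": defaults.MIN_RADICLE_CM,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_merge(DEFAULT_CONFIG, user)


def panel_config(cfg: dict) -> PanelConfig:
    p = cfg["panel"]
    return PanelConfig(
        habit_counts={h: int(p.get(h.value, 0)) for h in Habit},
        n_reference=int(p["n_reference"]),
        n_filler=int(p["n_filler"]),
    )


def pouch_design(cfg: dict, n_runs: int | None = None) -> PouchDesign:
    p = cfg["pouch"]
    return PouchDesign(
        n_runs=int(n_runs if n_runs is not None else p["n_runs"]),
        frames_per_run=int(p["frames_per_run"]),
        trays_per_frame=int(p["trays_per_frame"]),
        pouches_per_frame=int(p["pouches_per_frame"]),
        plants_per_pouch=int(p["plants_per_pouch"]),
    )


def polytunnel_design(cfg: dict) -> PolytunnelDesign:
    p = cfg["polytunnel"]
    n_rep = int(p["n_replicates"])
    n_a = int(p["tunnel_a_replicates"])
    return PolytunnelDesign(
        n_replicates=n_rep,
        replicate_to_tunnel={r: ("A" if r <= n_a else "B")
                             for r in range(1, n_rep + 1)},
        subblocks_per_replicate=int(p["subblocks_per_replicate"]),
        units_per_subblock=int(p["units_per_subblock"]),
    )


def run_size_for(n_samples: int, n_runs: int) -> int:
    """Smallest interleaved run size whose sample capacity covers
    n_samples/n_runs."""
    import math

    capacity_needed = math.ceil(n_samples / n_runs)
    run_size = capacity_needed
    while run_size - run_size // 10 < capacity_needed:
        run_size += 1
    return max(run_size, 10)
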