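"""Running scenarios end-to-end, single runs and seed ensembles.

With random initial sizes the winner count can vary from seed to seed
whenever several ovulation numbers are stable, so figure-level outcomes
are reported as the modal count over a seed ensemble.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import replace
from typing import Dict, Iterable, Tuple

from .presets import ScenarioPreset
from .simulate import (
    CONTINUAL_ENTRY,
    OvulationOutcome,
    Trajectory,
    classify_ovulating,
    integrate_cohort,
    sample_initial_sizes,
    simulate_continual_entry,
    twin_scenario,
)

__all__ = ["run_scenario", "ensemble_counts", "modal_count"]


def run_scenario(
    preset: ScenarioPreset, seed: int | None = None
) -> Tuple[Trajectory, OvulationOutcome]:
    """Execute one preset once and classify the outcome."""
    cfg = preset.config if seed is None else replace(preset.config, seed=seed)
    if preset.twin_delta is not None:
        outcome, traj = twin_scenario(
            preset.twin_delta, preset.params, cfg, return_trajectory=True
        )
        return traj, outcome
    if cfg.mode == CONTINUAL_ENTRY:
        traj = simulate_continual_entry(preset.params, cfg)
    else:
        initial = sample_initial_sizes(cfg)
        traj = integrate_cohort(initial, preset.params, cfg)
    return traj, classify_ovulating(traj, preset.params)


def ensemble_counts(preset: ScenarioPreset, seeds: Iterable[int]) -> Dict[int, int]:
    """Histogram {ovulation count: frequency} over an ensemble of seeds."""
    counts = Counter(run_scenario(preset, seed=s)[1].count for s in seeds)
    return dict(sorted(counts.items()))


def modal_count(histogram: Dict[int, int]) -> int:
    """Most frequent count; ties broken toward the smaller count."""
    best = max(histogram.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]
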