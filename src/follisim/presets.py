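"""Scenario presets: named parameter regimes with documented outcomes.

Each preset bundles model parameters and a simulation protocol for one
qualitative regime of the model: single or multiple ovulation races,
a twin ovulation near an unstable two-follicle solution, and the two
continual-entry regimes (anovulatory high-androgen turnover vs a single
dominant follicle).  ``expected_count`` records the documented modal
ovulation count for the regime, where one exists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

from .core import BiphasicParams
from .simulate import CONTINUAL_ENTRY, FIXED_COHORT, SimulationConfig

__all__ = ["ScenarioPreset", "PRESET_NAMES", "load_preset"]


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    alias: str
    params: BiphasicParams
    config: SimulationConfig
    expected_count: Optional[int]
    provenance: str
    twin_delta: Optional[float] = None  # set for the twin scenario

    def with_seed(self, seed: int) -> "ScenarioPreset":
        return replace(self, config=replace(self.config, seed=seed))


def _fixed(n: int, t_max: float) -> SimulationConfig:
    return SimulationConfig(n_follicles=n, mode=FIXED_COHORT, t_max=t_max)


_PRESETS: Dict[str, ScenarioPreset] = {}


def _register(p: ScenarioPreset) -> None:
    _PRESETS[p.name] = p
    _PRESETS[p.alias] = p


_register(
    ScenarioPreset(
        name="fig2c",
        alias="single-ovulation",
        params=BiphasicParams(m1=0.9, m2=3.5),
        config=_fixed(5, 400.0),
        expected_count=1,
        provenance=(
            "five-follicle race with thresholds admitting only one stable "
            "ovulation number; a single dominant follicle ovulates"
        ),
    )
)
_register(
    ScenarioPreset(
        name="fig2d",
        alias="triple-ovulation",
        params=BiphasicParams(m1=2.9, m2=7.5),
        config=_fixed(5, 2000.0),
        expected_count=3,
        provenance=(
            "five-follicle race with thresholds making three (modal) "
            "co-dominant follicles the stable outcome"
        ),
    )
)
_register(
    ScenarioPreset(
        name="fig2e",
        alias="single-of-fifteen",
        params=BiphasicParams(m1=0.9, m2=10.0),
        config=_fixed(15, 400.0),
        expected_count=1,
        provenance="fifteen-follicle race; one follicle ovulates",
    )
)
_register(
    ScenarioPreset(
        name="fig2f",
        alias="six-of-fifteen",
        params=BiphasicParams(m1=5.9, m2=13.0),
        config=_fixed(15, 5000.0),
        expected_count=6,
        provenance="fifteen-follicle race; six follicles ovulate (modal)",
    )
)
_register(
    ScenarioPreset(
        name="fig3d",
        alias="twin-ovulation",
        params=BiphasicParams(m1=0.5, m2=4.0),
        config=_fixed(5, 400.0),
        expected_count=2,
        twin_delta=0.001,
        provenance=(
            "two near-identical leaders reach the surge together and both "
            "ovulate, although a lone dominant follicle is the only stable state"
        ),
    )
)
_register(
    ScenarioPreset(
        name="fig4b",
        alias="pcos-anovulatory",
        params=BiphasicParams(m1=0.9, m2=10.0, alpha=0.005, a_ex=5.0),
        config=SimulationConfig(
            mode=CONTINUAL_ENTRY,
            n_entries=25,
            entry_window=40.0,
            t_max=60.0,
            surge_multiplier=None,
        ),
        expected_count=0,
        provenance=(
            "continual follicle entry under chronic external androgen that "
            "closes the growth window; follicles rise to the critical size "
            "and then shrink, none ovulate"
        ),
    )
)
_register(
    ScenarioPreset(
        name="fig4d",
        alias="ovulatory-turnover",
        params=BiphasicParams(m1=0.9, m2=10.0, alpha=1.0, a_ex=0.0),
        config=SimulationConfig(
            mode=CONTINUAL_ENTRY,
            n_entries=7,
            entry_window=40.0,
            t_max=60.0,
            surge_multiplier=None,
        ),
        expected_count=1,
        provenance=(
            "continual entry without excess androgen: a single dominant "
            "follicle grows at constant velocity while later entrants peak "
            "at the critical size and shrink"
        ),
    )
)

PRESET_NAMES = tuple(sorted({p.name for p in _PRESETS.values()}))


def load_preset(name: str) -> ScenarioPreset:
    """Look up a preset by canonical name or descriptive alias."""
    try:
        return _PRESETS[name]
    except KeyError:
        valid = ", ".join(
            sorted({p.name for p in _PRESETS.values()} | {p.alias for p in _PRESETS.values()})
        )
        raise KeyError(f"unknown preset {name!r}; valid presets: {valid}") from None
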