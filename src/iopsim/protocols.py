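"""Constant-rate micro-volumetric infusion protocols.

Three named protocols deliver the same 15 uL total intraocular volume at
rates spanning three decades: fast (15 uL/s for 1 s), intermediate
(1 uL/s for 15 s) and slow (0.1 uL/s for 150 s), on top of a 15 mmHg
baseline IOP.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["InfusionProtocol", "FAST", "INTERMEDIATE", "SLOW", "PROTOCOLS", "default_timestep"]


@dataclass(frozen=True)
class InfusionProtocol:
    """Constant-rate infusion: rate (uL/s), duration (s), baseline IOP (mmHg)."""

    rate: float
    duration: float
    baseline_iop: float = 15.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be positive")
        if self.baseline_iop < 0:
            raise ValueError("baseline IOP must be non-negative")

    @property
    def total_volume(self) -> float:
        """Total infused volume in uL (rate x duration)."""
        return self.rate * self.duration

    def volume_at(self, t):
        """Injected volume (uL) at time t during the infusion."""
        import numpy as np

        return self.rate * np.minimum(np.asarray(t, dtype=float), self.duration)


FAST = InfusionProtocol(rate=15.0, duration=1.0, name="fast")
INTERMEDIATE = InfusionProtocol(rate=1.0, duration=15.0, name="intermediate")
SLOW = InfusionProtocol(rate=0.1, duration=150.0, name="slow")

PROTOCOLS = {"fast": FAST, "intermediate": INTERMEDIATE, "slow": SLOW}

_NAMED_STEPS = {"fast": 0.01, "intermediate": 0.1, "slow": 1.0}


def default_timestep(protocol: InfusionProtocol) -> float:
    """Default solver step: 0.01 / 0.1 / 1 s for the named protocols
    (>= 100 steps each), otherwise duration/120."""
    if protocol.name in _NAMED_STEPS:
        return _NAMED_STEPS[protocol.name]
    return protocol.duration / 120.0
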