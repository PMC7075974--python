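"""Transition-state-theory conversion between free-energy barriers and rates.

The Eyring equation k = κ (k_B T / h) exp(-ΔG‡ / RT) links the
umbrella-sampling barrier heights to first-order rate constants. κ is a
transmission (reflection) coefficient, taken as 1 unless stated; at 310 K
the prefactor k_B T / h is ≈ 6.46e12 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DEFAULT_TEMPERATURE, K_B, PLANCK_H, rt
from .errors import InvalidInputError

__all__ = [
    "RateQuery",
    "rate_from_barrier",
    "barrier_from_rate",
    "timescale_label",
    "TIMESCALE_BOUNDARIES",
]

#: upper bounds (s) of the 1/k timescale classes, in order
TIMESCALE_BOUNDARIES = (
    (60.0, "seconds"),
    (3600.0, "minutes"),
    (86400.0, "hours"),
)

#: barriers more negative than this would overflow the exponential
_MIN_BARRIER = -500.0


@dataclass(frozen=True)
class RateQuery:
    """A barrier (kcal mol^-1) with its temperature and transmission factor."""

    delta_g_barrier: float
    temperature: float = DEFAULT_TEMPERATURE
    kappa: float = 1.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise InvalidInputError(
                f"temperature must be > 0 K, got {self.temperature}"
            )
        if not (0 < self.kappa <= 1):
            raise InvalidInputError(f"kappa must be in (0, 1], got {self.kappa}")
        if not math.isfinite(self.delta_g_barrier):
            raise InvalidInputError("barrier must be finite")
        if self.delta_g_barrier < _MIN_BARRIER:
            raise InvalidInputError(
                f"barrier {self.delta_g_barrier} kcal/mol would overflow the "
                "Eyring exponential"
            )


def attempt_frequency(temperature: float) -> float:
    """The Eyring prefactor k_B T / h (s^-1)."""
    return K_B * temperature / PLANCK_H


def rate_from_barrier(query: RateQuery) -> float:
    """Rate constant k = κ (k_B T / h) exp(-ΔG‡/RT), in s^-1."""
    q = query
    return q.kappa * attempt_frequency(q.temperature) * math.exp(
        -q.delta_g_barrier / rt(q.temperature)
    )


def barrier_from_rate(
    k: float, temperature: float = DEFAULT_TEMPERATURE, kappa: float = 1.0
) -> float:
    """Invert the Eyring equation: ΔG‡ = RT ln(κ k_B T / (h k)), kcal mol^-1."""
    if k <= 0:
        raise InvalidInputError(f"rate constant must be > 0, got {k}")
    if not (0 < kappa <= 1):
        raise InvalidInputError(f"kappa must be in (0, 1], got {kappa}")
    return rt(temperature) * math.log(kappa * attempt_frequency(temperature) / k)


def timescale_label(k: float) -> str:
    """Human-readable timescale of a first-order process with rate ``k`` (s^-1).

    Classified by the lifetime 1/k against clock boundaries: under a minute
    is "seconds", under an hour "minutes", under a day "hours", else "days".
    """
    if k <= 0:
        raise InvalidInputError(f"rate constant must be > 0, got {k}")
    lifetime = 1.0 / k
    for bound, label in TIMESCALE_BOUNDARIES:
        if lifetime < bound:
            return label
    return "days"
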