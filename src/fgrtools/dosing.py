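"""Drinking-water dose arithmetic.

Dose rate (mg/kg/day) delivered by medicated drinking water is
concentration (mg/ml) × intake (ml/day) / body mass (kg).  A 25 g mouse
drinking 3–4 ml/day of 0.2 mg/ml solution receives 24–32 mg/kg/day; hitting
a 50 mg/kg/day target at those intakes requires roughly doubling the
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DoseSpec:
    concentration: float  # mg/ml
    intake: float  # ml/day
    body_mass: float  # g

    def __post_init__(self) -> None:
        if self.concentration < 0 or self.intake < 0 or self.body_mass < 0:
            raise ValueError("dose spec fields must be >= 0")


def dose_mg_per_kg_day(spec: DoseSpec) -> float:
    """Delivered dose = concentration × intake / (mass in kg)."""
    if spec.body_mass <= 0:
        raise ValueError("body mass must be > 0")
    return spec.concentration * spec.intake / (spec.body_mass / 1000.0)


def required_concentration(
    target: float, intake: float, body_mass: float
) -> float:
    """Drinking-water concentration (mg/ml) needed to deliver ``target``
    mg/kg/day; exact inverse of :func:`dose_mg_per_kg_day`."""
    if intake <= 0:
        raise ValueError("intake must be > 0")
    if body_mass <= 0:
        raise ValueError("body mass must be > 0")
    if target < 0:
        raise ValueError("target dose must be >= 0")
    return target * (body_mass / 1000.0) / intake
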