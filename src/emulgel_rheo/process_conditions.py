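"""Rotor-stator mixing calculus: specific power and specific energy.

The specific power delivered per gram of batch by the Ultra Turrax
rotor-stator follows the calorimetric correlation

    P_s = a * Omega**b        (W/g, Omega in rpm)

with a = 1.59e-10 and b = 2.3.  The specific energy of mixing is then
E_s = P_s * t for a mixing time t in seconds.  Both constants come from a
calorimetric calibration of the device and are overridable.

Printed process tables divide a target energy by the power *rounded to three
decimals* before rounding the time to whole seconds; ``table_convention=True``
reproduces that convention, while the default keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError

#: Prefactor of the calorimetric power correlation, W/g per rpm**POWER_EXPONENT.
POWER_PREFACTOR = 1.59e-10
#: Exponent of the calorimetric power correlation (dimensionless).
POWER_EXPONENT = 2.3

__all__ = [
    "POWER_PREFACTOR",
    "POWER_EXPONENT",
    "MixingSpec",
    "parse_speed",
    "specific_power",
    "specific_energy",
    "mixing_time",
]


def parse_speed(speed: float | int | str) -> float:
    """Parse a rotational speed in rpm; accepts '10,000'-style strings."""
    if isinstance(speed, str):
        try:
            speed = float(speed.replace(",", "").strip())
        except ValueError as exc:
            raise ValidationError(f"cannot parse speed {speed!r}") from exc
    return float(speed)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention of the printed tables."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)


def specific_power(
    speed_rpm: float | str,
    *,
    prefactor: float = POWER_PREFACTOR,
    exponent: float = POWER_EXPONENT,
) -> float:
    """Specific power of mixing, W/g, from the rotational speed in rpm."""
    speed = parse_speed(speed_rpm)
    if speed <= 0:
        raise ValidationError(f"speed must be positive, got {speed}")
    return prefactor * speed**exponent


def specific_energy(power: float, time: float) -> float:
    """Specific energy of mixing E_s = P_s * t, J/g.

    Parameters
    ----------
    power : specific power of mixing, W/g (> 0).
    time : mixing duration, s (>= 0).
    """
    if power <= 0:
        raise ValidationError(f"power must be positive, got {power}")
    if time < 0:
        raise ValidationError(f"time must be non-negative, got {time}")
    return power * time


def mixing_time(
    energy: float,
    power: float,
    *,
    table_convention: bool = False,
    rounded: bool = True,
) -> float:
    """Mixing time t = E_s / P_s needed to reach a target specific energy.

    Parameters
    ----------
    energy : target specific energy, J/g (> 0).
    power : specific power of mixing, W/g (> 0).
    table_convention : round the power to 3 decimals before dividing, the
        convention some printed process tables follow.
    rounded : report the time rounded to the nearest whole second
        (half away from zero); set False for the exact ratio.
    """
    if energy <= 0:
        raise ValidationError(f"energy must be positive, got {energy}")
    if power <= 0:
        raise ValidationError(f"power must be positive, got {power}")
    p = round_half_up(power, 3) if table_convention else power
    if p <= 0:
        raise ValidationError(f"power rounds to zero at 3 decimals: {power}")
    t = energy / p
    return round_half_up(t) if rounded else t


@dataclass(frozen=True)
class MixingSpec:
    """A rotor-stator mixing condition.

    Attributes
    ----------
    speed : rotational speed, rpm.
    time : mixing duration, s.
    specific_power : power per gram of batch, W/g.
    specific_energy : energy per gram of batch, J/g.
    """

    speed: float
    time: float
    specific_power: float
    specific_energy: float

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValidationError(f"speed must be positive, got {self.speed}")
        if self.time < 0:
            raise ValidationError(f"time must be non-negative, got {self.time}")
        if self.specific_power <= 0:
            raise ValidationError("specific_power must be positive")
        if self.time > 0:
            expected = self.specific_power * self.time
            if abs(self.specific_energy - expected) > 0.005 * expected:
                raise ValidationError(
                    "specific_energy inconsistent with specific_power * time: "
                    f"{self.specific_energy} vs {expected}"
                )

    @classmethod
    def from_speed_time(
        cls,
        speed_rpm: float | str,
        time_s: float,
        *,
        prefactor: float = POWER_PREFACTOR,
        exponent: float = POWER_EXPONENT,
    ) -> "MixingSpec":
        """Build the full spec from speed and time via the power correlation."""
        speed = parse_speed(speed_rpm)
        power = specific_power(speed, prefactor=prefactor, exponent=exponent)
        return cls(
            speed=speed,
            time=time_s,
            specific_power=power,
            specific_energy=specific_energy(power, time_s),
        )
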