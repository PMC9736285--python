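"""Log-normal droplet-size statistics for emulgel dispersed phases.

Droplet diameters d (equivalent circular-area diameters, um) of rotor-stator
emulsions follow a log-normal law with density

    f(d) = exp(-(ln d - d_ln)^2 / (2 sigma_ln^2)) / (d sigma_ln sqrt(2 pi)),

where d_ln is the mean and sigma_ln the standard deviation of ln d
(diameters normalized to 1 um, so both parameters are dimensionless in
log space).  The arithmetic moments of the distribution are

    d_s     = exp(d_ln + sigma_ln^2 / 2)                       (mean, um)
    sigma_s = sqrt(exp(2 d_ln + sigma_ln^2) (exp(sigma_ln^2) - 1))

and the map inverts exactly: sigma_ln^2 = ln(1 + sigma_s^2 / d_s^2),
d_ln = ln d_s - sigma_ln^2 / 2.  Fitting uses log-space moments (mean and
sample sd of ln d), which coincides with maximum likelihood for the
log-normal and is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "LogNormalPSD",
    "DropletPopulation",
    "lognormal_pdf",
    "moments_from_params",
    "params_from_moments",
    "fit_psd",
    "mean_droplet_radius",
]

MIN_FIT_DIAMETERS = 10


@dataclass(frozen=True)
class LogNormalPSD:
    """Log-normal particle-size distribution parameters.

    ``d_ln`` is the mean of ln(d / 1 um); ``sigma_ln`` (>= 0) the standard
    deviation of ln d.  The arithmetic mean ``d_s`` and standard deviation
    ``sigma_s`` (both um) are derived properties.
    """

    d_ln: float
    sigma_ln: float

    def __post_init__(self) -> None:
        if self.sigma_ln < 0:
            raise ValidationError(f"sigma_ln must be >= 0, got {self.sigma_ln}")

    @property
    def d_s(self) -> float:
        return moments_from_params(self.d_ln, self.sigma_ln)[0]

    @property
    def sigma_s(self) -> float:
        return moments_from_params(self.d_ln, self.sigma_ln)[1]

    @property
    def mode(self) -> float:
        """Most probable diameter, exp(d_ln - sigma_ln^2), um."""
        return math.exp(self.d_ln - self.sigma_ln**2)

    @classmethod
    def from_moments(cls, d_s: float, sigma_s: float) -> "LogNormalPSD":
        return cls(*params_from_moments(d_s, sigma_s))


@dataclass(frozen=True)
class DropletPopulation:
    """Measured droplet diameters (equivalent circular-area, um)."""

    diameters: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        object.__setattr__(self, "diameters", d)
        if d.ndim != 1 or d.size < 1:
            raise ValidationError("diameters must be a non-empty 1-D array")
        if not np.all(d > 0):
            raise ValidationError("all diameters must be positive")

    def __len__(self) -> int:
        return int(self.diameters.size)


def lognormal_pdf(d, params: LogNormalPSD):
    """Log-normal probability density at diameter(s) d (um), per um."""
    if params.sigma_ln <= 0:
        raise ValidationError("sigma_ln must be positive for a density")
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("diameters must be positive")
    out = stats.lognorm.pdf(d, s=params.sigma_ln, scale=math.exp(params.d_ln))
    return float(out) if out.ndim == 0 else out


def moments_from_params(d_ln: float, sigma_ln: float) -> tuple[float, float]:
    """Arithmetic mean d_s and standard deviation sigma_s (um) of the PSD."""
    if sigma_ln < 0:
        raise ValidationError(f"sigma_ln must be >= 0, got {sigma_ln}")
    s2 = sigma_ln**2
    d_s = math.exp(d_ln + s2 / 2.0)
    sigma_s = math.sqrt(math.exp(2.0 * d_ln + s2) * math.expm1(s2))
    return d_s, sigma_s


def params_from_moments(d_s: float, sigma_s: float) -> tuple[float, float]:
    """Exact inversion of :func:`moments_from_params`."""
    if d_s <= 0:
        raise ValidationError(f"d_s must be positive, got {d_s}")
    if sigma_s < 0:
        raise ValidationError(f"sigma_s must be >= 0, got {sigma_s}")
    s2 = math.log1p((sigma_s / d_s) ** 2)
    return math.log(d_s) - s2 / 2.0, math.sqrt(s2)


def fit_psd(pop: DropletPopulation) -> LogNormalPSD:
    """Fit the log-normal PSD by log-space moments.

    d_ln is the mean of ln(diameters) and sigma_ln their sample standard
    deviation (ddof=1); requires at least 10 diameters.
    """
    if len(pop) < MIN_FIT_DIAMETERS:
        raise ValidationError(
            f"need >= {MIN_FIT_DIAMETERS} diameters to fit, got {len(pop)}"
        )
    logs = np.log(pop.diameters)
    return LogNormalPSD(d_ln=float(np.mean(logs)), sigma_ln=float(np.std(logs, ddof=1)))


def mean_droplet_radius(mean_diameters) -> float:
    """Mean droplet radius, um: half the arithmetic mean of mean diameters.

    Used to set the droplet radius R of the Palierne model from the
    per-sample mean diameters measured by optical microscopy.
    """
    d = np.asarray(mean_diameters, dtype=float)
    if d.size == 0:
        raise ValidationError("need at least one mean diameter")
    return float(np.mean(d)) / 2.0
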