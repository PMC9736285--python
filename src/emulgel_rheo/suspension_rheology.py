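"""Weak-gel and fractal analysis of fiber-suspension rheology.

Citrus-fiber suspensions behave as particle gels in the weak-link regime:
the storage modulus is a shallow power law of frequency,

    G'(omega) = k * omega**n,

and the slope n maps onto the fractal dimension D of the particle network
through the Muthukumar relation in d = 3 spatial dimensions,

    n = d * (d + 2 - 2 D) / (2 * (d + 2 - D))  =  3 (5 - 2 D) / (2 (5 - D)),

which inverts in closed form to D = (15 - 10 n) / (6 - 2 n).  At fixed
frequency the modulus scales with the fiber mass fraction x_f as

    G' = lambda' * x_f ** (1 / (3 - D)),

the weak-link fractal scaling, with lambda' (Pa) a measure of inter-particle
interaction strength.  Fits are ordinary least squares: log-log for the
frequency power law, linear in lambda' (no intercept) for the concentration
scaling.

Frequency unit convention: sweeps are stored in Hz as measured; the fit can
be performed on omega in rad/s via ``omega_units="rad_per_s"``.  The slope n
(and hence D) is invariant to that choice; the prefactor k is not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ModelDomainError, NonPhysicalResultWarning, ValidationError

SPATIAL_DIMENSION = 3

__all__ = [
    "FrequencySweep",
    "WeakGelFit",
    "SuspensionSeries",
    "FractalFit",
    "fit_power_law",
    "fractal_dimension_from_slope",
    "slope_from_fractal_dimension",
    "fit_fractal_dimension",
    "fit_fractal_scaling",
    "modulus_at",
    "average_fractal_dimension",
]


@dataclass(frozen=True)
class FrequencySweep:
    """A small-amplitude oscillatory frequency sweep.

    Attributes
    ----------
    frequency : oscillation frequencies, Hz, strictly increasing (>= 2 points).
    storage_modulus : G' per point, Pa (> 0).
    loss_modulus : G'' per point, Pa (>= 0); optional.
    temperature : test temperature, deg C (metadata).
    """

    frequency: np.ndarray
    storage_modulus: np.ndarray
    loss_modulus: np.ndarray | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequency, dtype=float)
        gp = np.asarray(self.storage_modulus, dtype=float)
        object.__setattr__(self, "frequency", freq)
        object.__setattr__(self, "storage_modulus", gp)
        if freq.ndim != 1 or freq.size < 2:
            raise ValidationError("sweep needs at least 2 frequency points")
        if gp.shape != freq.shape:
            raise ValidationError("storage_modulus shape mismatch")
        if not np.all(freq > 0):
            raise ValidationError("frequencies must be positive")
        if not np.all(np.diff(freq) > 0):
            raise ValidationError("frequencies must be strictly increasing")
        if not np.all(gp > 0):
            raise ValidationError("storage moduli must be positive")
        if self.loss_modulus is not None:
            gpp = np.asarray(self.loss_modulus, dtype=float)
            object.__setattr__(self, "loss_modulus", gpp)
            if gpp.shape != freq.shape:
                raise ValidationError("loss_modulus shape mismatch")
            if not np.all(gpp >= 0):
                raise ValidationError("loss moduli must be non-negative")

    def __len__(self) -> int:
        return int(self.frequency.size)


@dataclass(frozen=True)
class WeakGelFit:
    """Result of a weak-gel power-law fit.

    ``k`` is in Pa.Hz^-n (or Pa.(rad/s)^-n when the fit used rad/s),
    ``n`` is the dimensionless log-log slope, ``fractal_dimension`` the
    Muthukumar D when derived, and ``r_squared`` the log-log goodness of fit.
    """

    k: float
    n: float
    fractal_dimension: float | None = None
    r_squared: float = float("nan")

    def predict(self, frequency: np.ndarray | float) -> np.ndarray | float:
        """G' = k * f**n at the given frequency (same units as the fit)."""
        return self.k * np.asarray(frequency, dtype=float) ** self.n


@dataclass(frozen=True)
class SuspensionSeries:
    """Modulus and phase angle at the reference frequency vs fiber fraction.

    ``modulus`` holds the printed modulus per point (complex modulus G* by
    convention; set ``use_storage_from_complex=False`` in the fit when it is
    already a storage modulus).
    """

    fiber_fraction: np.ndarray
    modulus: np.ndarray
    phase_angle: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.fiber_fraction, dtype=float)
        g = np.asarray(self.modulus, dtype=float)
        object.__setattr__(self, "fiber_fraction", x)
        object.__setattr__(self, "modulus", g)
        if x.shape != g.shape or x.ndim != 1:
            raise ValidationError("fiber_fraction and modulus must be 1-D, same length")
        if not np.all((x > 0) & (x < 1)):
            raise ValidationError("fiber fractions must lie in (0, 1)")
        if not np.all(g > 0):
            raise ValidationError("moduli must be positive")
        if self.phase_angle is not None:
            d = np.asarray(self.phase_angle, dtype=float)
            object.__setattr__(self, "phase_angle", d)
            if d.shape != x.shape:
                raise ValidationError("phase_angle shape mismatch")
            if not np.all((d > 0) & (d < 90)):
                raise ValidationError("phase angles must lie in (0, 90) degrees")

    def storage_modulus(self, use_storage_from_complex: bool = True) -> np.ndarray:
        """G' per point: G* cos(delta) when the series stores G*, else as-is."""
        if use_storage_from_complex:
            if self.phase_angle is None:
                raise ValidationError(
                    "phase angles required to convert G* to G'"
                )
            return self.modulus * np.cos(np.radians(self.phase_angle))
        return self.modulus


@dataclass(frozen=True)
class FractalFit:
    """Weak-link fractal concentration scaling G' = lambda' x_f^(1/(3-D))."""

    lambda_prime: float
    fractal_dimension: float
    r_squared: float = float("nan")

    @property
    def exponent(self) -> float:
        return 1.0 / (3.0 - self.fractal_dimension)

    def predict(self, fiber_fraction: np.ndarray | float) -> np.ndarray | float:
        """Storage modulus, Pa, at the given fiber mass fraction."""
        return self.lambda_prime * np.asarray(fiber_fraction, dtype=float) ** self.exponent


def fit_power_law(sweep: FrequencySweep, *, omega_units: str = "hz") -> WeakGelFit:
    """Fit G'(omega) = k omega^n by ordinary least squares in log-log space.

    Two points determine the law exactly (r^2 = 1).  ``omega_units`` selects
    whether the abscissa is the stored frequency in Hz (default) or the
    angular frequency 2*pi*f in rad/s; only k depends on the choice.
    """
    if omega_units not in ("hz", "rad_per_s"):
        raise ValidationError(f"unknown omega_units {omega_units!r}")
    f = sweep.frequency
    if omega_units == "rad_per_s":
        f = 2.0 * np.pi * f
    logw = np.log10(f)
    logg = np.log10(sweep.storage_modulus)
    slope, intercept = np.polyfit(logw, logg, 1)
    pred = slope * logw + intercept
    ss_res = float(np.sum((logg - pred) ** 2))
    ss_tot = float(np.sum((logg - logg.mean()) ** 2))
    # constant G' (flat weak gel) fits exactly; avoid 0/0 in r^2
    if ss_tot <= 1e-12 * max(1.0, float(np.sum(logg**2))):
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return WeakGelFit(k=float(10.0**intercept), n=float(slope), r_squared=r2)


def fractal_dimension_from_slope(n: float) -> float:
    """Invert the Muthukumar relation: D = (15 - 10 n) / (6 - 2 n), d = 3.

    Values outside the physical range (0, 3) are returned with a
    :class:`NonPhysicalResultWarning` rather than raised.
    """
    if n >= 1.5:
        raise ModelDomainError(f"slope n must be < 1.5, got {n}")
    D = (15.0 - 10.0 * n) / (6.0 - 2.0 * n)
    if not 0.0 < D < 3.0:
        warnings.warn(
            f"fractal dimension {D:.3f} outside the physical range (0, 3)",
            NonPhysicalResultWarning,
            stacklevel=2,
        )
    return D


def slope_from_fractal_dimension(D: float) -> float:
    """Muthukumar relation forward: n = 3 (5 - 2 D) / (2 (5 - D)), d = 3."""
    if D >= 5.0:
        raise ModelDomainError(f"fractal dimension must be < 5, got {D}")
    return 3.0 * (5.0 - 2.0 * D) / (2.0 * (5.0 - D))


def fit_fractal_dimension(
    sweep: FrequencySweep, *, omega_units: str = "hz"
) -> WeakGelFit:
    """Extract the fractal dimension from a frequency sweep.

    Composition of the weak-gel power-law fit and the closed-form
    Muthukumar inversion; equivalent to a direct nonlinear fit of
    G'(omega) = k omega^(3(5-2D)/(2(5-D))).
    """
    base = fit_power_law(sweep, omega_units=omega_units)
    D = fractal_dimension_from_slope(base.n)
    return WeakGelFit(k=base.k, n=base.n, fractal_dimension=D, r_squared=base.r_squared)


def fit_fractal_scaling(
    series: SuspensionSeries,
    D: float,
    *,
    use_storage_from_complex: bool = True,
) -> FractalFit:
    """Fit lambda' in G' = lambda' x_f^(1/(3-D)) with D held fixed.

    The model is linear in lambda' with no intercept, so the least-squares
    solution is the closed form sum(G' x^e) / sum(x^(2e)), e = 1/(3-D).
    ``use_storage_from_complex`` converts the stored complex modulus to
    G' = G* cos(delta) before fitting.
    """
    if D >= 3.0:
        raise ModelDomainError(f"fractal dimension must be < 3, got {D}")
    gp = series.storage_modulus(use_storage_from_complex)
    x = series.fiber_fraction
    basis = x ** (1.0 / (3.0 - D))
    lam = float(np.sum(gp * basis) / np.sum(basis * basis))
    pred = lam * basis
    ss_res = float(np.sum((gp - pred) ** 2))
    ss_tot = float(np.sum((gp - gp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FractalFit(lambda_prime=lam, fractal_dimension=D, r_squared=r2)


def modulus_at(sweep: FrequencySweep, frequency: float) -> tuple[float, float]:
    """Complex modulus G* (Pa) and phase angle delta (deg) at a frequency.

    G' and G'' are interpolated log-log between the bracketing sweep points;
    no extrapolation outside the measured range.
    """
    f = sweep.frequency
    if not (f[0] <= frequency <= f[-1]):
        raise ValidationError(
            f"frequency {frequency} Hz outside sweep range [{f[0]}, {f[-1]}]"
        )
    if sweep.loss_modulus is None:
        raise ValidationError("loss modulus required to compute G* and delta")
    logf = math.log10(frequency)
    gp = 10.0 ** float(np.interp(logf, np.log10(f), np.log10(sweep.storage_modulus)))
    # G'' may contain zeros; interpolate linearly in that case
    gpp_arr = sweep.loss_modulus
    if np.all(gpp_arr > 0):
        gpp = 10.0 ** float(np.interp(logf, np.log10(f), np.log10(gpp_arr)))
    else:
        gpp = float(np.interp(frequency, f, gpp_arr))
    g_star = math.hypot(gp, gpp)
    delta = math.degrees(math.atan2(gpp, gp))
    return g_star, delta


def average_fractal_dimension(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation of fractal dimensions."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("need at least one fractal dimension")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), sd
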