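"""The Palierne emulsion-model family for emulgel complex moduli.

An O/W emulgel is a dispersion of liquid oil droplets (modulus G_d) in a
gelled continuous phase (modulus G_c).  The relative modulus G_r = G / G_c
at oil volume fraction phi is, in the dilute limit,

    G_r = 1 + 5 H phi,

and for moderately concentrated systems (Palierne)

    G_r = (1 + 3 H phi) / (1 - 2 H phi),

where the kernel H combines the modulus ratio M = G_d / G_c with the
dimensionless interfacial number Gamma = gamma / (R G_c):

    H = [(M - 1)(19 M + 16) + 4 Gamma (5 M + 2)]
        / [(2 M + 3)(19 M + 16) + 40 Gamma (M + 1)].

With gamma negligible this reduces to H = (M - 1)/(2 M + 3), and for a soft
filler (M -> 0) to H = -1/3.  Real fiber emulgels deviate from the Palierne
assumptions (monodisperse, non-interacting, spherical droplets), so an
empirical crowding factor psi multiplies the effective volume fraction in
the denominator (Kerner-Lewis/Nielsen form)

    G_r = (1 + 3 H phi) / (1 - 2 H psi phi),

optionally also in the numerator (extended Kerner form).  psi is fitted by
unweighted least squares on (phi, G_r) data.

Unit conventions: the core works in SI (gamma in N/m, R in m, moduli in Pa);
:meth:`PhasePair.from_io_units` accepts the tabulated units (mN/m, um).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import ModelDomainError, NonPhysicalResultWarning, ValidationError
from .suspension_rheology import FractalFit

#: Default oil/aqueous-phase density ratio for w/w -> v/v conversion.
DEFAULT_DENSITY_RATIO = 0.92

__all__ = [
    "DEFAULT_DENSITY_RATIO",
    "PhasePair",
    "PalierneFit",
    "EmulgelPrediction",
    "oil_volume_fraction",
    "modulus_ratio",
    "h_parameter",
    "h_bulk",
    "gr_dilute",
    "gr_palierne",
    "gr_modified",
    "gr_extended_kerner",
    "relative_modulus",
    "fit_psi",
    "predict_emulgel_modulus",
]


@dataclass(frozen=True)
class PhasePair:
    """Everything the Palierne kernel H needs, in SI units.

    Attributes
    ----------
    g_c : continuous-phase complex modulus at the reference frequency, Pa.
    g_d : dispersed-phase complex modulus at the reference frequency, Pa.
    gamma : interfacial tension, N/m (>= 0).
    radius : droplet radius, m.
    """

    g_c: float
    g_d: float
    gamma: float
    radius: float

    def __post_init__(self) -> None:
        if self.g_c <= 0 or self.g_d <= 0:
            raise ValidationError("phase moduli must be positive")
        if self.gamma < 0:
            raise ValidationError("interfacial tension must be >= 0")
        if self.radius <= 0:
            raise ValidationError("droplet radius must be positive")

    @property
    def modulus_ratio(self) -> float:
        """M = G_d / G_c."""
        return self.g_d / self.g_c

    @property
    def interfacial_number(self) -> float:
        """gamma / (R G_c), the dimensionless interfacial term of H."""
        return self.gamma / (self.radius * self.g_c)

    @classmethod
    def from_io_units(
        cls, g_c: float, g_d: float, gamma_mn_per_m: float, radius_um: float
    ) -> "PhasePair":
        """Build from the tabulated units: gamma in mN/m, radius in um."""
        return cls(
            g_c=g_c, g_d=g_d, gamma=gamma_mn_per_m * 1e-3, radius=radius_um * 1e-6
        )


@dataclass(frozen=True)
class PalierneFit:
    """Fitted crowding factor with diagnostics."""

    psi: float
    h: float
    residuals: np.ndarray  # model - data per point
    sse: float
    psi_stderr: float = float("nan")


@dataclass(frozen=True)
class EmulgelPrediction:
    """Forward-predicted emulgel modulus and its intermediate quantities."""

    g_star: float
    g_r: float
    g_c: float
    h: float
    phi: float


def oil_volume_fraction(
    oil_weight_fraction: float, density_ratio: float = DEFAULT_DENSITY_RATIO
) -> float:
    """Convert an oil weight fraction (w/w) to a volume fraction (v/v).

    ``density_ratio`` is rho_oil / rho_aqueous; the default 0.92 is typical
    of vegetable oil in water.
    """
    w = oil_weight_fraction
    if not 0 <= w < 1:
        raise ValidationError(f"weight fraction must be in [0, 1), got {w}")
    if density_ratio <= 0:
        raise ValidationError("density ratio must be positive")
    v = w / density_ratio
    return v / (v + (1.0 - w))


def modulus_ratio(g_d: float, g_c: float) -> float:
    """M = G_d / G_c, dispersed over continuous phase modulus."""
    if g_c == 0:
        raise ModelDomainError("continuous-phase modulus must be nonzero")
    if g_d <= 0 or g_c < 0:
        raise ValidationError("moduli must be positive")
    return g_d / g_c


def _h_kernel(M: float, interfacial_number: float) -> float:
    g = interfacial_number
    num = (M - 1.0) * (19.0 * M + 16.0) + 4.0 * g * (5.0 * M + 2.0)
    den = (2.0 * M + 3.0) * (19.0 * M + 16.0) + 40.0 * g * (M + 1.0)
    return num / den


def h_parameter(pair: PhasePair) -> float:
    """Palierne kernel H with bulk and interfacial contributions.

    H = [(M-1)(19M+16) + (4 gamma/(R G_c))(5M+2)]
        / [(2M+3)(19M+16) + (40 gamma/(R G_c))(M+1)]

    The denominator is strictly positive for physical inputs.  With
    gamma = 0 this equals :func:`h_bulk`.
    """
    return _h_kernel(pair.modulus_ratio, pair.interfacial_number)


def h_bulk(M: float) -> float:
    """Bulk-only Palierne kernel H = (M - 1) / (2 M + 3); -1/3 for M -> 0."""
    if M < 0:
        raise ValidationError(f"modulus ratio must be >= 0, got {M}")
    return (M - 1.0) / (2.0 * M + 3.0)


def _check_phi(phi) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if np.any((phi < 0) | (phi >= 1)):
        raise ValidationError("volume fractions must lie in [0, 1)")
    return phi


def gr_dilute(H: float, phi):
    """Dilute-emulsion relative modulus G_r = 1 + 5 H phi."""
    phi = _check_phi(phi)
    out = 1.0 + 5.0 * H * phi
    return float(out) if out.ndim == 0 else out


def gr_palierne(H: float, phi):
    """Palierne relative modulus G_r = (1 + 3 H phi) / (1 - 2 H phi)."""
    return gr_modified(H, phi, 1.0)


def gr_modified(H: float, phi, psi: float):
    """Kerner-Lewis/Nielsen relative modulus with crowding factor psi:

    G_r = (1 + 3 H phi) / (1 - 2 H psi phi).

    Negative values (possible when 1 + 3 H phi < 0) are returned as-is with
    a :class:`NonPhysicalResultWarning`; a vanishing or negative denominator
    raises :class:`ModelDomainError`.
    """
    phi = _check_phi(phi)
    den = 1.0 - 2.0 * H * psi * phi
    if np.any(den <= 0):
        raise ModelDomainError(
            f"denominator 1 - 2 H psi phi vanishes (H={H}, psi={psi})"
        )
    out = (1.0 + 3.0 * H * phi) / den
    if np.any(out < 0):
        warnings.warn(
            "negative relative modulus: model outside its physical range",
            NonPhysicalResultWarning,
            stacklevel=2,
        )
    return float(out) if out.ndim == 0 else out


def gr_extended_kerner(H: float, phi, psi: float):
    """Extended Kerner form G_r = (1 + 3 H psi phi) / (1 - 2 H psi phi)."""
    phi = _check_phi(phi)
    den = 1.0 - 2.0 * H * psi * phi
    if np.any(den <= 0):
        raise ModelDomainError(
            f"denominator 1 - 2 H psi phi vanishes (H={H}, psi={psi})"
        )
    out = (1.0 + 3.0 * H * psi * phi) / den
    if np.any(out < 0):
        warnings.warn(
            "negative relative modulus: model outside its physical range",
            NonPhysicalResultWarning,
            stacklevel=2,
        )
    return float(out) if out.ndim == 0 else out


def relative_modulus(g_star: float, g_c_star: float) -> float:
    """Experimental relative modulus G_r* = G*(1 Hz) / G_c*(1 Hz)."""
    if g_c_star == 0:
        raise ModelDomainError("continuous-phase modulus must be nonzero")
    if g_star <= 0 or g_c_star < 0:
        raise ValidationError("moduli must be positive")
    return g_star / g_c_star


def fit_psi(
    phi,
    g_r,
    H: float,
    *,
    bounds: tuple[float, float] = (1e-6, 1000.0),
) -> PalierneFit:
    """Fit the crowding factor psi of the modified Palierne model.

    Minimizes the unweighted sum of squared residuals of
    ``gr_modified(H, phi, psi) - g_r`` over psi in ``bounds`` (bounded
    scalar minimization).  The reported standard error comes from the
    curvature of the SSE at the optimum (Gauss-Newton approximation).
    """
    phi = _check_phi(phi)
    g_r = np.asarray(g_r, dtype=float)
    if phi.shape != g_r.shape or phi.size < 2:
        raise ValidationError("need >= 2 (phi, G_r) points of equal length")
    if np.all(phi == 0):
        raise ValidationError("all volume fractions are zero: psi not identifiable")

    def sse(psi: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonPhysicalResultWarning)
            model = gr_modified(H, phi, psi)
        return float(np.sum((model - g_r) ** 2))

    res = minimize_scalar(sse, bounds=bounds, method="bounded", options={"xatol": 1e-8})
    psi = float(res.x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonPhysicalResultWarning)
        residuals = np.asarray(gr_modified(H, phi, psi)) - g_r
    s = float(np.sum(residuals**2))
    # curvature-based standard error: var(psi) ~ 2 sigma^2 / d2SSE/dpsi2
    h = max(1e-5, 1e-4 * psi)
    d2 = (sse(psi + h) - 2.0 * s + sse(psi - h)) / h**2
    dof = max(phi.size - 1, 1)
    stderr = float(np.sqrt(2.0 * (s / dof) / d2)) if d2 > 0 else float("nan")
    return PalierneFit(psi=psi, h=H, residuals=residuals, sse=s, psi_stderr=stderr)


def predict_emulgel_modulus(
    fiber_fraction: float,
    oil_weight_fraction: float,
    fractal: FractalFit,
    *,
    g_d: float,
    gamma: float,
    radius: float,
    psi: float,
    density_ratio: float = DEFAULT_DENSITY_RATIO,
) -> EmulgelPrediction:
    """Forward-predict the emulgel complex modulus from the formulation.

    Chains the fractal scaling (continuous-phase modulus G_c at the fiber
    mass fraction), the Palierne kernel H (with ``gamma`` in N/m and
    ``radius`` in m), and the modified Palierne relative modulus at the oil
    volume fraction converted from w/w:

        G* = G_r(H, phi, psi) * G_c.
    """
    g_c = float(fractal.predict(fiber_fraction))
    phi = oil_volume_fraction(oil_weight_fraction, density_ratio)
    pair = PhasePair(g_c=g_c, g_d=g_d, gamma=gamma, radius=radius)
    H = h_parameter(pair)
    g_r = gr_modified(H, phi, psi)
    return EmulgelPrediction(g_star=g_r * g_c, g_r=g_r, g_c=g_c, h=H, phi=phi)
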