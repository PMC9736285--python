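"""Synthetic data generators with the statistical structure the models assume.

Each generator is a pure function of its arguments, including the seed, so
every pipeline stage is testable by parameter recovery without external
data.  Noise on moduli is multiplicative log-normal (rheometer errors scale
with the signal); the default level of 3% matches the relative standard
deviations typical of triplicate frequency-sweep measurements on these
systems.  The phase angle is generated independently of the modulus level
(it is insensitive to composition in fiber emulgels; default 5.6 deg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emulgel_model import PhasePair, gr_modified, h_parameter
from .droplet_psd import DropletPopulation
from .exceptions import ValidationError
from .suspension_rheology import FrequencySweep, SuspensionSeries

DEFAULT_DELTA_DEG = 5.6
DEFAULT_NOISE_SD = 0.03

__all__ = [
    "NoiseSpec",
    "gen_sweep",
    "gen_suspension_series",
    "gen_emulgel_series",
    "gen_droplets",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative log-normal noise: values are scaled by exp(N(0, sd))."""

    multiplicative_sd: float = DEFAULT_NOISE_SD
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.multiplicative_sd < 0:
            raise ValidationError("noise sd must be >= 0")

    def factors(self, size: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        if self.multiplicative_sd == 0:
            return np.ones(size)
        return np.exp(rng.normal(0.0, self.multiplicative_sd, size))


NO_NOISE = NoiseSpec(0.0, None)


def gen_sweep(
    k: float,
    n: float,
    freq_range: tuple[float, float] = (0.1, 10.0),
    n_points: int = 21,
    noise: NoiseSpec = NO_NOISE,
    *,
    delta_deg: float = DEFAULT_DELTA_DEG,
) -> FrequencySweep:
    """Weak-gel frequency sweep G' = k f^n on a log-spaced grid in Hz.

    G'' is set from a constant target phase angle (``delta_deg``), i.e.
    G'' = G' tan(delta); noise multiplies G' point-wise before G'' is
    derived, so the generated phase angle stays exact.
    """
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    if n_points < 3:
        raise ValidationError("need at least 3 points")
    lo, hi = freq_range
    if not (0 < lo < hi):
        raise ValidationError(f"invalid frequency range {freq_range}")
    f = np.logspace(np.log10(lo), np.log10(hi), n_points)
    gp = k * f**n * noise.factors(n_points)
    gpp = gp * np.tan(np.radians(delta_deg))
    return FrequencySweep(frequency=f, storage_modulus=gp, loss_modulus=gpp)


def gen_suspension_series(
    lambda_prime: float,
    D: float,
    x_f_list,
    noise: NoiseSpec = NO_NOISE,
    *,
    delta_deg: float = DEFAULT_DELTA_DEG,
) -> SuspensionSeries:
    """Suspension series following the fractal scaling G' = lambda' x^(1/(3-D)).

    The stored modulus is the complex modulus G* = G' / cos(delta) with the
    constant generated phase angle, mirroring how such series are tabulated;
    fitting with ``use_storage_from_complex=True`` recovers lambda' exactly
    in the noiseless case.
    """
    if D >= 3:
        raise ValidationError(f"fractal dimension must be < 3, got {D}")
    if lambda_prime <= 0:
        raise ValidationError("lambda_prime must be positive")
    x = np.asarray(x_f_list, dtype=float)
    gp = lambda_prime * x ** (1.0 / (3.0 - D)) * noise.factors(x.size)
    g_star = gp / np.cos(np.radians(delta_deg))
    return SuspensionSeries(
        fiber_fraction=x,
        modulus=g_star,
        phase_angle=np.full(x.size, delta_deg),
    )


def gen_emulgel_series(
    psi: float,
    pair: PhasePair,
    phi_list,
    noise: NoiseSpec = NO_NOISE,
) -> pd.DataFrame:
    """Emulgel (phi, G_r, G*) points from the modified Palierne model.

    G_r = gr_modified(H, phi, psi) scaled by multiplicative noise;
    G* = G_r * G_c.  Raises if the model denominator is non-positive
    anywhere on the grid.
    """
    phi = np.asarray(phi_list, dtype=float)
    H = h_parameter(pair)
    g_r = np.asarray(gr_modified(H, phi, psi)) * noise.factors(phi.size)
    return pd.DataFrame(
        {"phi": phi, "g_r": g_r, "g_star_pa": g_r * pair.g_c}
    )


def gen_droplets(
    d_ln: float, sigma_ln: float, n: int, seed: int | None = None
) -> DropletPopulation:
    """n i.i.d. log-normal droplet diameters (um)."""
    if n < 1:
        raise ValidationError("need n >= 1 droplets")
    if sigma_ln < 0:
        raise ValidationError("sigma_ln must be >= 0")
    rng = np.random.default_rng(seed)
    d = rng.lognormal(mean=d_ln, sigma=sigma_ln, size=n)
    return DropletPopulation(diameters=d, sample_id="synthetic")
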