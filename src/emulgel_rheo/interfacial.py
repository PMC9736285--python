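"""Plateau (interface-saturation) interfacial tension estimation.

Pendant-drop tension-vs-concentration series decrease steeply at low
emulsifier content and level off once the interface saturates (the CMC for
a surfactant).  The saturation value is the gamma fed to the Palierne
interfacial term, estimated here as the mean of the largest terminal run of
concentration-sorted points whose relative spread stays within a tolerance.
An explicit concentration threshold can replace the heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ModelDomainError, ValidationError

__all__ = ["TensionSeries", "PlateauTension", "plateau_tension"]


@dataclass(frozen=True)
class TensionSeries:
    """Interfacial tension vs emulsifier/fiber content.

    ``lecithin_fraction`` is w/w in the oil phase, ``fiber_fraction`` w/w in
    the aqueous phase, ``gamma`` the measured tension in mN/m with optional
    per-point standard deviation ``gamma_sd``.
    """

    lecithin_fraction: np.ndarray
    fiber_fraction: np.ndarray
    gamma: np.ndarray
    gamma_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        lec = np.asarray(self.lecithin_fraction, dtype=float)
        fib = np.asarray(self.fiber_fraction, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        for name, arr in (("lecithin_fraction", lec), ("fiber_fraction", fib)):
            if np.any(arr < 0):
                raise ValidationError(f"{name} must be >= 0")
        if not (lec.shape == fib.shape == g.shape) or g.ndim != 1:
            raise ValidationError("series columns must be 1-D and equal length")
        if not np.all(g > 0):
            raise ValidationError("tensions must be positive")
        object.__setattr__(self, "lecithin_fraction", lec)
        object.__setattr__(self, "fiber_fraction", fib)
        object.__setattr__(self, "gamma", g)
        if self.gamma_sd is not None:
            sd = np.asarray(self.gamma_sd, dtype=float)
            if sd.shape != g.shape:
                raise ValidationError("gamma_sd shape mismatch")
            object.__setattr__(self, "gamma_sd", sd)

    def __len__(self) -> int:
        return int(self.gamma.size)


@dataclass(frozen=True)
class PlateauTension:
    """Plateau tension estimate: mean +/- sd over the member points."""

    gamma: float  # mN/m
    gamma_sd: float  # mN/m, sample sd over members (0 for 1 member)
    members: tuple[int, ...]  # indices into the concentration-sorted subset
    concentrations: tuple[float, ...]  # lecithin fractions of the members


def plateau_tension(
    series: TensionSeries,
    rel_tol: float = 0.25,
    *,
    concentration_threshold: float | None = None,
    pool_fiber_rows: bool = False,
) -> PlateauTension:
    """Estimate the saturation interfacial tension from a concentration series.

    The lecithin-only points (fiber_fraction == 0) are sorted by lecithin
    fraction; the plateau is the longest terminal run whose relative spread
    (max - min) / min is <= ``rel_tol`` (default 0.25), or, when
    ``concentration_threshold`` is given, all points at or above it.  With
    ``pool_fiber_rows`` the mixed lecithin+fiber points whose lecithin
    fraction is inside the plateau range are averaged in as well.

    Returns the mean and sample standard deviation over the member points.
    Raises :class:`ModelDomainError` when no run of >= 2 points qualifies.
    """
    if rel_tol < 0:
        raise ValidationError(f"rel_tol must be >= 0, got {rel_tol}")
    lec_only = series.fiber_fraction == 0
    if np.count_nonzero(lec_only) < 3:
        raise ModelDomainError("need >= 3 lecithin-only points")
    order = np.argsort(series.lecithin_fraction[lec_only], kind="stable")
    conc = series.lecithin_fraction[lec_only][order]
    gam = series.gamma[lec_only][order]

    if concentration_threshold is not None:
        member_mask = conc >= concentration_threshold
        start = int(np.argmax(member_mask)) if member_mask.any() else len(gam)
    else:
        # longest suffix with relative spread within tolerance
        start = len(gam) - 1
        for i in range(len(gam) - 2, -1, -1):
            window = gam[i:]
            lo, hi = window.min(), window.max()
            if (hi - lo) / lo <= rel_tol:
                start = i
            else:
                break
    members = tuple(range(start, len(gam)))
    if len(members) < 2:
        raise ModelDomainError("no plateau detected")

    values = list(gam[start:])
    concentrations = list(conc[start:])
    if pool_fiber_rows:
        mixed = (series.fiber_fraction > 0) & (series.lecithin_fraction >= conc[start])
        values.extend(series.gamma[mixed])
        concentrations.extend(series.lecithin_fraction[mixed])

    values = np.asarray(values)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return PlateauTension(
        gamma=float(np.mean(values)),
        gamma_sd=sd,
        members=members,
        concentrations=tuple(float(c) for c in concentrations),
    )
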