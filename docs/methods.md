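# Methods

This note records the models implemented in `emulgel_rheo`, the conventions
and defaults chosen where the experimental record leaves them open, and the
known limits of what the bundled data and synthetic tests can show.

## Process calculus

The rotor-stator specific power follows the calorimetric correlation
`P_s = a Ω^b` with a = 1.59e-10 W/g·rpm⁻ᵇ and b = 2.3, both overridable
(the calibration's significant digits are not documented beyond these
values). Specific energy is `E_s = P_s t`.

Two rounding conventions coexist in tabulated mixing schedules and both are
provided. The default inverts `t = E_s/P_s` at full precision; the
`table_convention=True` mode first rounds `P_s` to three decimals, which is
how some printed times were evidently produced (e.g. 45.2/0.051 = 886 s).
The bundled process table is internally inconsistent across its two energy
blocks: six of its eight (speed, energy) combinations reproduce exactly at
full precision, the 886 s row only under the rounded-power convention, and
one row (6000 rpm at 45.2 J/g, printed 580 s) matches neither exactly
(full precision gives 580.8 → 581). Likewise the headline 45.2 J/g is the
full-precision 45.25 J/g rounded down. Tests therefore assert the printed
schedule at the 0.5% consistency band the mixing record itself states,
with exact checks where a convention actually reproduces the entry.

## Weak-gel and fractal analysis

`G'(ω) = k ω^n` is fitted by ordinary least squares in log-log space — the
traces are near-linear there and no weighting scheme is implied by
triplicate-sd data. Sweeps are stored in Hz as measured; fitting on
ω in rad/s is a config switch that changes only k, never n or D. Two points
determine the law exactly and are accepted (r² = 1); a constant sweep gets
slope 0 and D = 2.5 without error.

The Muthukumar relation with d = 3 is used in closed form both ways:
`n = 3(5 − 2D)/(2(5 − D))` and `D = (15 − 10n)/(6 − 2n)`. Dimensions
outside (0, 3) are returned with a non-physical warning rather than raised,
so noisy fits remain inspectable.

The concentration scaling `G' = λ′ x_f^(1/(3−D))` is linear in λ′ once D is
fixed, so λ′ has the closed-form no-intercept least-squares solution.
Because the suspension table prints the complex modulus and phase angle,
the fit converts `G' = G* cos δ` by default (`use_storage_from_complex`).
The fractal dimension entering the fit is the average over all five
tabulated samples (2.440 ± 0.012); averaging only the x_f > 0.01 subset
(2.446 ± 0.008) is a config choice (`d_subset="above_1pct"`), but the
all-rows mean is the one consistent with the reported 2.44 ± 0.01.

## Droplet statistics

Diameters (µm) are modelled log-normal. The printed density formula for
these systems is typographically garbled; the standard log-normal pdf is
used, the only form consistent with the accompanying moment formulas
`d_s = exp(d_ln + σ_ln²/2)` and
`σ_s² = exp(2d_ln + σ_ln²)(exp(σ_ln²) − 1)`. `d_ln` is treated as the
dimensionless mean of ln(d/1 µm). Fitting uses log-space moments
(mean and ddof = 1 sd of ln d), identical to maximum likelihood for this
family and deterministic; at least 10 diameters are required. The Palierne
radius is half the arithmetic mean of the per-sample mean diameters of the
3%-fiber emulgels: R = (6.5 + 5.5)/2/2 = 3.0 µm.

## Plateau interfacial tension

Saturation is declared on the concentration-sorted lecithin-only series as
the longest terminal run whose relative spread (max − min)/min stays within
`rel_tol` (default 0.25, wide enough to group the scattered post-CMC points
but not the pre-CMC decade drops); an explicit concentration threshold can
replace the heuristic, and mixed fiber+lecithin rows can be pooled in. On
the bundled series the plateau is the last three lecithin-only points with
mean 1.44 ± 0.05 mN/m. The reported experimental estimate, 1.40 ± 0.08
mN/m, is not recoverable as the plain mean of any obvious subset of the
printed rows, so the γ fed to the Palierne kernel is a configurable
constant defaulting to 1.40 mN/m, and the recomputed plateau is logged
alongside it.

## Palierne chain

The kernel H uses γ in N/m, R in m and moduli in Pa so that γ/(R·G_c) is
dimensionless; the I/O boundary accepts mN/m and µm. The oil-phase modulus
G_d ≈ 11.1 Pa at 1 Hz is a config input (it is only available graphically
in the source record; 11.1 Pa reproduces the tabulated modulus ratios with
a single constant across all fiber fractions). Oil weight fractions convert
to volume fractions with density ratio ρ_oil/ρ_aq = 0.92, which reproduces
every printed volume fraction to 1 d.p. All moduli refer to 1 Hz.

ψ is fitted by unweighted least squares on G_r (not on absolute G*, not in
log space), matching the symmetric uncertainty reported for it; bounded
scalar minimization on (0, 1000] with a curvature-based standard error. On
the bundled six-point oil series with H = −0.270 the optimum is ψ = 15.7,
inside the reported 15 ± 2.

Negative model values of G_r (possible for H > 0 once 1 + 3Hφ < 0, and
reported as "<0" in the source comparison table) carry a non-physical
warning instead of being clamped; a non-positive denominator raises, and
the pipeline's comparison table marks such rows non-physical.

Two entries of the printed comparison table are known not to reproduce from
their own printed inputs, both through rounding of the continuous-phase
modulus: the 1%-fiber row (printed H = 0.084, direct evaluation 0.080) and
the 2.5%-fiber row (printed H = −0.253, direct evaluation −0.254). Tests
check the second to one unit in the last printed digit and exclude the
first, as the comparison is only claimed for x_f ≥ 0.02.

## Synthetic data

Generators emulate exactly the structures the fits assume: power-law sweeps
with constant phase angle (5.6°, the measured composition-independent
average), fractal-scaling suspension series stored as (G*, δ) pairs,
modified-Palierne emulgel series, and i.i.d. log-normal droplets. Noise is
multiplicative log-normal on moduli, default 3% (the relative sds of the
bundled triplicate data); each generator is a pure function of its
arguments including the seed. Because the noise model matches the fit
model, recovery tests demonstrate estimator correctness and calibration —
not robustness to the structured errors of real rheometry (inertia and
compliance artefacts, loading variability, drift), which these generators
deliberately do not emulate.

Recovery under the study conditions (grids of the bundled tables, 3–5%
noise, 200 seeds) keeps mean bias within ±0.01 on D, ±5% on λ′ and ±1 on ψ;
these are the calibration levels the test suite asserts.

## Problem sizes and determinism

Everything is desk-scale: tables of ≤ 16 rows, 21-point sweeps, Monte-Carlo
studies of 200 replicates (a few seconds in total). All stochastic tests use
fixed seeds; `scripts/acceptance.py` accepts a seed but its reported
quantities are deterministic functions of the bundled tables.

## Known limitations

- The crowding factor ψ is empirical: it absorbs polydispersity,
  deformability, irregular droplet shape and interactions, so it is
  formulation- and process-specific and should be refitted outside the
  0.2–3% fiber / ≤ 42% oil window it was calibrated on.
- The Palierne family is applied to 1 Hz scalars only; no frequency-
  dependent spectra are computed.
- The model-data comparison fails below 2% fiber, where the phases are
  similarly soft, the interfacial term dominates and the printed comparison
  itself reports large errors; the package reproduces this failure rather
  than fixing it.
- Strong-link fractal gels, stress-sweep/LVE detection and image-based
  droplet sizing are out of scope; only diameter lists are consumed.
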