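"""Weak-gel power-law fitting, the Muthukumar n<->D map, fractal scaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emulgel_rheo import (
    FrequencySweep,
    ModelDomainError,
    NonPhysicalResultWarning,
    SuspensionSeries,
    ValidationError,
    average_fractal_dimension,
    fit_fractal_dimension,
    fit_fractal_scaling,
    fit_power_law,
    fractal_dimension_from_slope,
    gen_suspension_series,
    gen_sweep,
    modulus_at,
    slope_from_fractal_dimension,
)
from emulgel_rheo.synthetic_data import NoiseSpec


# ------------------------------------------------------------ power-law fit

@given(
    k=st.floats(min_value=1e-2, max_value=1e6),
    n=st.floats(min_value=0.0, max_value=0.5),
)
def test_noiseless_power_law_recovered_exactly(k, n):
    sweep = gen_sweep(k, n, n_points=10)
    fit = fit_power_law(sweep)
    assert fit.k == pytest.approx(k, rel=1e-9)
    assert fit.n == pytest.approx(n, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0)


def test_two_point_sweep_closed_form_slope():
    sweep = FrequencySweep(frequency=[1.0, 10.0], storage_modulus=[100.0, 120.0])
    fit = fit_power_law(sweep)
    assert fit.n == pytest.approx(np.log10(1.2), rel=1e-12)
    assert fit.k == pytest.approx(100.0, rel=1e-12)


def test_noisy_slope_recovery_is_unbiased():
    """Mean slope over 100 noisy replicates stays within 0.01 of truth."""
    true_n = 0.07
    slopes = [
        fit_power_law(gen_sweep(100.0, true_n, noise=NoiseSpec(0.05, seed))).n
        for seed in range(100)
    ]
    assert np.mean(slopes) == pytest.approx(true_n, abs=0.01)


def test_rad_per_s_units_change_k_not_n():
    sweep = gen_sweep(100.0, 0.07)
    hz = fit_power_law(sweep, omega_units="hz")
    rad = fit_power_law(sweep, omega_units="rad_per_s")
    assert rad.n == pytest.approx(hz.n, abs=1e-12)
    assert rad.k == pytest.approx(hz.k / (2 * np.pi) ** hz.n, rel=1e-9)


def test_sweep_validation():
    with pytest.raises(ValidationError):
        FrequencySweep(frequency=[1.0], storage_modulus=[10.0])
    with pytest.raises(ValidationError):
        FrequencySweep(frequency=[1.0, 2.0, 2.0], storage_modulus=[1, 2, 3])
    with pytest.raises(ValidationError):
        FrequencySweep(frequency=[1.0, 2.0], storage_modulus=[1.0, -2.0])


# ----------------------------------------------------- Muthukumar relation

@pytest.mark.parametrize(
    "n, expected_D",
    [(0.0, 2.5), (0.0703, 2.440), (0.5, 2.0)],
)
def test_fractal_dimension_from_slope(n, expected_D):
    assert fractal_dimension_from_slope(n) == pytest.approx(expected_D, abs=5e-4)


@pytest.mark.parametrize("D, expected_n", [(2.5, 0.0), (2.44, 0.0703), (2.0, 0.5)])
def test_slope_from_fractal_dimension(D, expected_n):
    assert slope_from_fractal_dimension(D) == pytest.approx(expected_n, abs=5e-5)


@given(st.floats(min_value=0.0, max_value=1.4))
def test_slope_dimension_maps_are_exact_inverses(n):
    D = fractal_dimension_from_slope(n)
    assert slope_from_fractal_dimension(D) == pytest.approx(n, abs=1e-12)


def test_muthukumar_root_finding_cross_check():
    """The closed-form inverse agrees with numerically solving the forward
    relation n(D) = 3(5-2D)/(2(5-D))."""
    from scipy.optimize import brentq

    for n in (0.01, 0.0703, 0.2, 0.3):
        D_closed = fractal_dimension_from_slope(n)
        D_root = brentq(lambda D: slope_from_fractal_dimension(D) - n, 0.5, 2.5)
        assert D_closed == pytest.approx(D_root, abs=1e-10)


def test_non_physical_dimension_warns_but_returns():
    with pytest.warns(NonPhysicalResultWarning):
        D = fractal_dimension_from_slope(-4.0)  # D > 3
    assert D > 3

    with pytest.raises(ModelDomainError):
        fractal_dimension_from_slope(1.5)
    with pytest.raises(ModelDomainError):
        slope_from_fractal_dimension(5.0)


# ------------------------------------------------- fractal dimension fits

def test_fit_fractal_dimension_noiseless():
    true_D = 2.444
    sweep = gen_sweep(100.0, slope_from_fractal_dimension(true_D))
    fit = fit_fractal_dimension(sweep)
    assert fit.fractal_dimension == pytest.approx(true_D, abs=1e-4)


def test_flat_sweep_gives_boundary_dimension():
    sweep = FrequencySweep(
        frequency=[0.1, 1.0, 10.0], storage_modulus=[50.0, 50.0, 50.0]
    )
    fit = fit_fractal_dimension(sweep)
    assert fit.n == pytest.approx(0.0, abs=1e-12)
    assert fit.fractal_dimension == pytest.approx(2.5)


def test_dimension_recovery_at_measured_precision(table1):
    """Sweeps regenerated from each tabulated D with 1% noise refit to
    within +/- 0.01 per sample."""
    for i, D in enumerate(table1["fractal_dimension"]):
        sweep = gen_sweep(
            100.0, slope_from_fractal_dimension(D), noise=NoiseSpec(0.01, seed=i)
        )
        fit = fit_fractal_dimension(sweep)
        assert fit.fractal_dimension == pytest.approx(D, abs=0.01)


def test_two_step_fit_matches_grid_search_oracle():
    """Composing the log-log fit with the closed-form inversion agrees with
    a brute-force grid search over D (profiling out k) to 3 s.f."""

    def grid_search_D(sweep):
        logw = np.log10(sweep.frequency)
        logg = np.log10(sweep.storage_modulus)
        best = (np.inf, None)
        for D in np.arange(2.0, 2.6, 1e-4):
            slope = slope_from_fractal_dimension(D)
            intercept = np.mean(logg - slope * logw)
            sse = np.sum((logg - slope * logw - intercept) ** 2)
            if sse < best[0]:
                best = (sse, D)
        return best[1]

    for noise in (NoiseSpec(0.0, 0), NoiseSpec(0.01, 7)):
        sweep = gen_sweep(100.0, slope_from_fractal_dimension(2.44), noise=noise)
        two_step = fit_fractal_dimension(sweep).fractal_dimension
        assert two_step == pytest.approx(grid_search_D(sweep), abs=2e-3)


# ------------------------------------------------------ fractal scaling fit

def test_fractal_scaling_fit_on_measured_series(suspension_series):
    """G' = G* cos(delta) vs fiber fraction with D = 2.44 gives
    lambda' = 15.6e5 Pa within the stated 0.7e5."""
    fit = fit_fractal_scaling(suspension_series, 2.44)
    assert fit.lambda_prime == pytest.approx(15.6e5, abs=0.7e5)


def test_fractal_scaling_single_point_closed_form():
    series = SuspensionSeries(fiber_fraction=[0.03], modulus=[2986.0])
    fit = fit_fractal_scaling(series, 2.44, use_storage_from_complex=False)
    assert fit.lambda_prime == pytest.approx(2986.0 / 0.03 ** (1 / 0.56), rel=1e-12)
    assert fit.lambda_prime == pytest.approx(1.57e6, rel=0.01)


def test_fractal_scaling_noiseless_recovery_and_monotonicity():
    series = gen_suspension_series(1e6, 2.4, [0.005, 0.01, 0.02, 0.03])
    fit = fit_fractal_scaling(series, 2.4)
    assert fit.lambda_prime == pytest.approx(1e6, rel=1e-12)
    pred = fit.predict(np.linspace(0.001, 0.05, 20))
    assert np.all(np.diff(pred) > 0)


def test_fractal_scaling_rejects_unphysical_dimension(suspension_series):
    with pytest.raises(ModelDomainError):
        fit_fractal_scaling(suspension_series, 3.0)


# ------------------------------------------------------------- modulus_at

def test_modulus_at_exact_point_definition():
    sweep = FrequencySweep(
        frequency=[0.1, 1.0, 10.0],
        storage_modulus=[100.0, 100.0, 100.0],
        loss_modulus=[10.0, 10.0, 10.0],
    )
    g_star, delta = modulus_at(sweep, 1.0)
    assert g_star == pytest.approx(np.hypot(100, 10))
    assert delta == pytest.approx(np.degrees(np.arctan(0.1)), abs=1e-9)


def test_modulus_at_zero_loss_gives_zero_phase():
    sweep = FrequencySweep(
        frequency=[0.5, 1.0, 2.0],
        storage_modulus=[80.0, 100.0, 120.0],
        loss_modulus=[0.0, 0.0, 0.0],
    )
    _, delta = modulus_at(sweep, 1.3)
    assert delta == 0.0


def test_modulus_at_interpolates_power_law_exactly():
    k, n, tan_d = 200.0, 0.1, np.tan(np.radians(5.6))
    sweep = gen_sweep(k, n, delta_deg=5.6)
    target = 0.5  # mid-decade, not a grid point
    g_star, delta = modulus_at(sweep, target)
    expected_gp = k * target**n
    assert g_star == pytest.approx(expected_gp * np.hypot(1, tan_d), rel=1e-9)
    assert delta == pytest.approx(5.6, abs=1e-9)


def test_modulus_at_refuses_extrapolation():
    sweep = gen_sweep(100.0, 0.07, freq_range=(0.1, 10.0))
    with pytest.raises(ValidationError):
        modulus_at(sweep, 20.0)


# ------------------------------------------------------------- D averaging

def test_average_fractal_dimension_of_measured_values(table1):
    mean, sd = average_fractal_dimension(table1["fractal_dimension"])
    assert round(mean, 2) == 2.44
    assert round(sd, 2) == 0.01


@pytest.mark.parametrize(
    "values, mean, sd",
    [([2.4, 2.5], 2.45, None), ([2.44, 2.44, 2.44], 2.44, 0.0)],
)
def test_average_fractal_dimension_arithmetic(values, mean, sd):
    m, s = average_fractal_dimension(values)
    assert m == pytest.approx(mean)
    if sd is not None:
        assert s == pytest.approx(sd)
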