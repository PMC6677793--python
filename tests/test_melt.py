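"""Thermal-melt pipeline: normalization, derivative, Gaussian Tm fits."""
import numpy as np
import pytest

from tpmkit.errors import FitError, NormalizationError, ParameterError
from tpmkit.melt import (
    MeltCurve,
    ThermalMeltModel,
    average_replicates,
    delta_tm,
    fit_peaks,
    normalize_melt,
    smooth_derivative,
)
from tpmkit.synth import gen_melt_curve

GRID = np.arange(20.0, 65.1, 0.5)


def _sigmoid_curve(tm=45.0, scale=1.5, lo=-30.0, hi=-8.0, grid=GRID):
    f = 1.0 / (1.0 + np.exp(-(grid - tm) / scale))
    return MeltCurve(temperature=grid, signal=lo + (hi - lo) * f)


class TestNormalize:
    def test_ideal_sigmoid_crosses_half_at_midpoint(self):
        curve = normalize_melt(_sigmoid_curve(tm=45.0))
        f_at_tm = np.interp(45.0, curve.temperature, curve.signal)
        assert f_at_tm == pytest.approx(0.5, abs=0.01)
        assert curve.normalized

    def test_idempotent_on_normalized_curve(self):
        once = normalize_melt(_sigmoid_curve())
        twice = normalize_melt(once)
        np.testing.assert_allclose(twice.signal, once.signal, atol=1e-6)

    def test_sloped_baselines_still_cross_half_at_tm(self):
        df, _ = gen_melt_curve(seed=0, tms=(47.0,), widths=(2.0,))
        curve = normalize_melt(MeltCurve.from_dataframe(df))
        crossing = np.interp(0.5, curve.signal, curve.temperature)
        assert crossing == pytest.approx(47.0, abs=0.2)

    def test_minmax_mode(self):
        curve = normalize_melt(_sigmoid_curve(), method="minmax")
        assert curve.signal.min() == pytest.approx(0.0)
        assert curve.signal.max() == pytest.approx(1.0)

    def test_flat_curve_rejected(self):
        flat = MeltCurve(temperature=GRID, signal=np.full_like(GRID, -20.0))
        with pytest.raises(NormalizationError):
            normalize_melt(flat, method="minmax")
        short = MeltCurve(temperature=GRID[:12], signal=np.linspace(0, 1, 12))
        with pytest.raises(NormalizationError):
            normalize_melt(short, end_fraction=0.5)


class TestDerivative:
    def test_quadratic_reproduced_exactly_at_interior_points(self):
        a, b, c = 0.013, -1.2, 30.0
        curve = MeltCurve(temperature=GRID, signal=a * GRID**2 + b * GRID + c)
        deriv = smooth_derivative(curve, window=5, polyorder=2)
        np.testing.assert_allclose(deriv.signal[1:-1], 2 * a * GRID[1:-1] + b, atol=1e-12)

    def test_constant_signal_gives_zero(self):
        curve = MeltCurve(temperature=GRID, signal=np.full_like(GRID, 3.3))
        np.testing.assert_allclose(smooth_derivative(curve).signal, 0.0, atol=1e-12)

    def test_sine_matches_cosine_on_fine_grid(self):
        t = np.linspace(0.0, 2 * np.pi, 4001)
        curve = MeltCurve(temperature=t, signal=np.sin(t))
        deriv = smooth_derivative(curve, window=5, polyorder=2)
        assert np.max(np.abs(deriv.signal[2:-2] - np.cos(t[2:-2]))) < 1e-3

    @pytest.mark.parametrize("window,polyorder", [(4, 2), (3, 2), (999, 2)])
    def test_bad_windows_rejected(self, window, polyorder):
        with pytest.raises(ParameterError):
            smooth_derivative(_sigmoid_curve(), window=window, polyorder=polyorder)

    def test_nonuniform_grid_rejected(self):
        t = np.sort(np.concatenate([GRID, [30.17]]))
        with pytest.raises(ParameterError):
            smooth_derivative(MeltCurve(temperature=t, signal=np.zeros_like(t)))


class TestPeaks:
    def test_single_noiseless_transition_center_recovered(self):
        df, _ = gen_melt_curve(seed=0, tms=(52.0,), widths=(2.0,))
        res = ThermalMeltModel.from_dataframe(df).fit(1)
        assert res.tm[0] == pytest.approx(52.0, abs=0.1)

    def test_flat_derivative_is_a_fit_error(self):
        df, _ = gen_melt_curve(seed=0, tms=(45.0,), amplitude=0.0)
        with pytest.raises(FitError):
            ThermalMeltModel.from_dataframe(df, normalize=None).fit(1)

    def test_two_transitions_ten_degrees_apart(self):
        df, _ = gen_melt_curve(
            seed=0, tms=(42.0, 52.0), widths=(2.0, 2.0), weights=(0.5, 0.5)
        )
        res = ThermalMeltModel.from_dataframe(df).fit(2)
        assert res.tm[0] == pytest.approx(42.0, abs=0.3)
        assert res.tm[1] == pytest.approx(52.0, abs=0.3)

    def test_components_sorted_by_center(self):
        df, _ = gen_melt_curve(
            seed=0, tms=(50.0, 40.0), widths=(2.0, 2.0), weights=(0.5, 0.5)
        )
        res = ThermalMeltModel.from_dataframe(df).fit(2, init_centers=[51.0, 41.0])
        assert res.tm == sorted(res.tm)

    def test_positive_amplitudes_and_widths(self):
        df, _ = gen_melt_curve(seed=3, tms=(48.0,), noise_sd=0.01, n_replicates=2)
        res = ThermalMeltModel.from_dataframe(df).fit(1)
        comp = res.peaks.components[0]
        assert comp.amplitude > 0 and comp.sigma > 0
        assert GRID[0] <= comp.center <= GRID[-1]


class TestDeltaTm:
    def test_shift_is_difference_of_centers(self):
        a, _ = gen_melt_curve(seed=1, tms=(44.4,), widths=(2.0,))
        b, _ = gen_melt_curve(seed=2, tms=(46.5,), widths=(2.0,))
        fa = ThermalMeltModel.from_dataframe(a).fit(1).peaks
        fb = ThermalMeltModel.from_dataframe(b).fit(1).peaks
        d, se = delta_tm(fa, fb)
        assert d == pytest.approx(2.1, abs=0.1)

    def test_antisymmetry_and_identity(self):
        a, _ = gen_melt_curve(seed=1, tms=(44.9,), widths=(2.0,))
        b, _ = gen_melt_curve(seed=2, tms=(47.6,), widths=(2.0,))
        fa = ThermalMeltModel.from_dataframe(a).fit(1).peaks
        fb = ThermalMeltModel.from_dataframe(b).fit(1).peaks
        assert delta_tm(fa, fb)[0] == pytest.approx(-delta_tm(fb, fa)[0], abs=1e-12)
        assert delta_tm(fa, fa)[0] == 0.0

    def test_out_of_range_component(self):
        a, _ = gen_melt_curve(seed=1, tms=(44.4,))
        fa = ThermalMeltModel.from_dataframe(a).fit(1).peaks
        with pytest.raises(IndexError):
            delta_tm(fa, fa, component=3)


class TestPipeline:
    def test_pure_function_of_curve_and_config(self):
        df, _ = gen_melt_curve(seed=9, tms=(46.0,), noise_sd=0.02, n_replicates=3)
        r1 = ThermalMeltModel.from_dataframe(df).fit(1)
        r2 = ThermalMeltModel.from_dataframe(df).fit(1)
        assert r1.tm == r2.tm
        assert r1.peaks.rss == r2.peaks.rss

    def test_replicate_averaging_on_common_grid(self):
        c1 = _sigmoid_curve(tm=45.0)
        c2 = MeltCurve(temperature=GRID + 0.0, signal=c1.signal + 0.4)
        avg = average_replicates([c1, c2])
        np.testing.assert_allclose(avg.signal, c1.signal + 0.2, atol=1e-12)

    def test_noisy_replicates_recover_tm_within_half_degree(self):
        df, _ = gen_melt_curve(seed=4, tms=(44.4,), widths=(2.0,), noise_sd=0.02, n_replicates=3)
        res = ThermalMeltModel.from_dataframe(df).fit(1)
        assert res.tm[0] == pytest.approx(44.4, abs=0.5)
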