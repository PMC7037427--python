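"""Plate-kinetics operations: Beer-Lambert conversion, baseline handling,
windowed initial velocities, the Michaelis-Menten fit and replicate
aggregation, and the UV/ITC proportional calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dopatherm.exceptions import (
    DegenerateDataError,
    DopathermError,
    InsufficientDataError,
    UnidentifiableFitError,
)
from dopatherm.kinetics import (
    AbsorbanceTrace,
    InitialRate,
    MichaelisMenten,
    MichaelisMentenFit,
    RatePair,
    absorbance_to_concentration,
    aggregate_replicates,
    estimate_initial_velocity,
    fit_michaelis_menten,
    fit_proportional_ratio,
    read_plate_csv,
    subtract_baseline,
    write_plate_csv,
)

from conftest import DOUBLING_SERIES_MM, exact_rates


class TestBeerLambert:
    @pytest.mark.parametrize("a_mOD, eps, path, expected_mM", [
        (1110.0, 3700.0, 0.3, 1.000),
        (0.0, 3700.0, 0.3, 0.0),
        (37.0, 3700.0, 1.0, 0.010),
    ])
    def test_closed_form_conversions(self, a_mOD, eps, path, expected_mM):
        assert absorbance_to_concentration(a_mOD, eps, path) == pytest.approx(
            expected_mM, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(-1e4, 1e4), b=st.floats(-1e4, 1e4))
    def test_linearity(self, a, b):
        f = absorbance_to_concentration
        assert f(a + b) == pytest.approx(f(a) + f(b), abs=1e-9)

    def test_rejects_nonpositive_constants(self):
        with pytest.raises(DopathermError):
            absorbance_to_concentration(10.0, epsilon_M_cm=-1.0)
        with pytest.raises(DopathermError):
            absorbance_to_concentration(10.0, path_cm=0.0)


def _trace(t, a, temp=37.0, sub=1.5, blank=False):
    return AbsorbanceTrace(np.asarray(t, float), np.asarray(a, float),
                           temperature_C=temp, substrate_mM=0.0 if blank else sub,
                           is_blank=blank)


class TestBaseline:
    def test_trace_minus_itself_is_zero(self):
        t = np.arange(0, 100, 5.0)
        a = np.linspace(0, 50, t.size)
        blank = _trace(t, a, blank=True)
        out = subtract_baseline(_trace(t, a), blank)
        np.testing.assert_allclose(out.absorbance_mOD, 0.0, atol=1e-12)
        assert out.baseline_corrected

    def test_zero_blank_leaves_trace_unchanged(self):
        t = np.arange(0, 100, 5.0)
        a = np.linspace(0, 50, t.size)
        out = subtract_baseline(_trace(t, a), _trace(t, np.zeros_like(t), blank=True))
        np.testing.assert_array_equal(out.absorbance_mOD, a)

    def test_temperature_mismatch_rejected(self):
        t = np.arange(0, 100, 5.0)
        with pytest.raises(DopathermError, match="temperature"):
            subtract_baseline(_trace(t, t, temp=37.0),
                              _trace(t, t, temp=25.0, blank=True))

    def test_disjoint_time_ranges_rejected(self):
        with pytest.raises(DopathermError, match="overlap"):
            subtract_baseline(_trace([0, 5, 10], [1, 2, 3]),
                              _trace([1000, 1005, 1010], [0, 0, 0], blank=True))


class TestInitialVelocity:
    def test_exact_line_recovered_without_error(self):
        """A noise-free linear trace with concentration slope 0.010 mM/min
        yields exactly that velocity with zero standard error."""
        t = np.arange(0, 480 + 5, 5.0)
        slope_mM_min = 0.010
        conc = slope_mM_min * t / 60.0
        a = conc * 3700 * 0.3
        rate = estimate_initial_velocity(_trace(t, a))
        assert rate.v_initial_mM_min == pytest.approx(0.010, rel=1e-9)
        assert rate.se_mM_min == pytest.approx(0.0, abs=1e-12)

    def test_window_truncates_late_plateau(self):
        """A curve linear to 8 min then flat is fitted only on the window;
        the result matches an independent least-squares oracle on the
        windowed points, not the slope of the whole trace."""
        t = np.arange(0, 1200 + 5, 5.0)
        conc = np.where(t <= 480, 0.01 * t / 60.0, 0.01 * 8.0)
        a = conc * 3700 * 0.3
        rate = estimate_initial_velocity(_trace(t, a), window_s=480)
        mask = t <= 480
        oracle = np.polyfit(t[mask] / 60.0, conc[mask], 1)[0]
        assert rate.v_initial_mM_min == pytest.approx(oracle, rel=1e-9)
        full = np.polyfit(t / 60.0, conc, 1)[0]
        assert rate.v_initial_mM_min != pytest.approx(full, rel=1e-3)

    def test_two_point_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_initial_velocity(_trace([0, 5], [0, 1]))


class TestMichaelisMentenFit:
    def test_exact_recovery_from_noise_free_rates(self):
        """Rates generated from Km = 0.70 mM, Vmax = 0.038 mM/min on the
        doubling series are recovered to better than 1e-6 relative."""
        fit = fit_michaelis_menten(exact_rates(37.0, 0.70, 0.038))
        assert fit.km_mM == pytest.approx(0.70, rel=1e-6)
        assert fit.vmax_mM_min == pytest.approx(0.038, rel=1e-6)
        assert fit.se_km == pytest.approx(0.0, abs=1e-9)

    def test_optimum_beats_grid_oracle(self, rng):
        """The converged SSR never exceeds the minimum over a dense
        log-spaced (Km, Vmax) grid."""
        s = np.array(DOUBLING_SERIES_MM)
        v = 0.038 * s / (0.7 + s) + rng.normal(0, 0.002, s.size)
        model = MichaelisMenten(s, v, temperature_C=37.0)
        res = model.fit()
        km_grid = np.logspace(np.log10(s.min() / 100), np.log10(s.max() * 100), 400)
        vm_grid = np.logspace(np.log10(1e-4), np.log10(1.0), 400)
        KM, VM = np.meshgrid(km_grid, vm_grid, indexing="ij")
        pred = VM[:, :, None] * s[None, None, :] / (KM[:, :, None] + s[None, None, :])
        ssr_grid = ((pred - v[None, None, :]) ** 2).sum(axis=-1)
        assert res.ssr <= ssr_grid.min() + 1e-8

    def test_flat_rates_flagged_unidentifiable(self):
        rates = [InitialRate(s, 37.0, 0.03, 0.0, 10) for s in (0.5, 1.0, 2.0, 4.0)]
        with pytest.raises(UnidentifiableFitError):
            fit_michaelis_menten(rates)

    def test_single_concentration_rejected(self):
        rates = [InitialRate(1.0, 37.0, v, 0.0, 10) for v in (0.02, 0.021, 0.019)]
        with pytest.raises(UnidentifiableFitError):
            fit_michaelis_menten(rates)

    def test_mixed_temperatures_rejected(self):
        rates = exact_rates(37.0, 0.7, 0.038)[:3] + exact_rates(25.0, 0.4, 0.03)[:3]
        with pytest.raises(DopathermError, match="temperature"):
            fit_michaelis_menten(rates)


class TestAggregation:
    def _fit(self, temp, km, vmax=0.03):
        return MichaelisMentenFit(temp, km, vmax, 0.01, 0.001, 0.95, 7)

    def test_identical_fits_mean_equals_fit_sem_zero(self):
        fits = [self._fit(37.0, 0.7)] * 3
        (mean,) = aggregate_replicates(fits)
        assert mean.km_mM == pytest.approx(0.7, rel=1e-12)
        assert mean.se_km == pytest.approx(0.0, abs=1e-12)
        assert mean.n_rates == 3

    def test_two_fit_mean(self):
        (mean,) = aggregate_replicates([self._fit(37.0, 0.4), self._fit(37.0, 0.6)])
        assert mean.km_mM == pytest.approx(0.5)

    def test_grouping_by_temperature(self):
        fits = [self._fit(t, 0.5 + 0.01 * r) for t in (25.0, 31.0, 37.0, 43.0)
                for r in range(3)]
        means = aggregate_replicates(fits)
        assert [m.temperature_C for m in means] == [25.0, 31.0, 37.0, 43.0]
        assert all(m.n_rates == 3 for m in means)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            aggregate_replicates([])


class TestProportionalRatio:
    def test_exactly_proportional_pairs(self):
        """Pairs built with uv = 20.34 × rate give that ratio and adj R² 1."""
        rates = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        pairs = [RatePair(s, r, 20.34 * r) for s, r in zip(range(1, 7), rates)]
        fit = fit_proportional_ratio(pairs)
        assert fit.mean_ratio == pytest.approx(20.34, rel=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_identity_ratio(self):
        pairs = [RatePair(s, r, r) for s, r in zip((1, 2, 3), (0.5, 1.0, 2.0))]
        assert fit_proportional_ratio(pairs).mean_ratio == pytest.approx(1.0)

    def test_zero_rate_rejected(self):
        pairs = [RatePair(1, 0.0, 1.0), RatePair(2, 1.0, 2.0)]
        with pytest.raises(DegenerateDataError):
            fit_proportional_ratio(pairs)

    def test_all_zero_uv_rejected(self):
        pairs = [RatePair(1, 1.0, 0.0), RatePair(2, 2.0, 0.0)]
        with pytest.raises(DegenerateDataError):
            fit_proportional_ratio(pairs)


class TestPlateIO:
    def test_round_trip(self, tmp_path, noise_free_params):
        from dopatherm.synthetic import gen_progress_curves

        traces = gen_progress_curves(noise_free_params)
        path = tmp_path / "plate.csv"
        write_plate_csv(traces, path)
        back = read_plate_csv(path)
        assert len(back) == len(traces)
        key = lambda t: (t.temperature_C, t.substrate_mM, t.replicate_id, t.is_blank)
        orig = {key(t): t for t in traces}
        for tr in back:
            np.testing.assert_allclose(tr.absorbance_mOD,
                                       orig[key(tr)].absorbance_mOD, rtol=1e-12)

    def test_missing_column_rejected(self, tmp_path):
        from dopatherm.exceptions import SchemaError

        p = tmp_path / "bad.csv"
        p.write_text("time_s,absorbance_mOD\n0,1\n")
        with pytest.raises(SchemaError, match="missing"):
            read_plate_csv(p)
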