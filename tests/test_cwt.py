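import numpy as np
import pytest

from caprhythm import (
    TimeSeries,
    WaveletSpec,
    cwt_transform,
    default_scale_grid,
    dominant_period,
    period_to_scale,
    real_part_at_scale,
    scale_to_period,
    wavelet_eval,
)
from caprhythm.errors import DegenerateSeriesError, DomainError, ParameterError

CMOR = WaveletSpec.cmor(1.0, 1.5)
GRID_STEP = np.log(30 / 0.3) / 59  # log spacing of the default 60-point grid


def oracle_cwt(x, scales, spec, dt=1.0):
    """Brute-force direct sum over every (scale, position) pair."""
    n = len(x)
    W = np.empty((len(scales), n), dtype=complex)
    k = np.arange(n)
    for i, a in enumerate(scales):
        for b in range(n):
            W[i, b] = (dt / np.sqrt(a)) * np.sum(
                x * np.conj(wavelet_eval(spec, (k - b) / a))
            )
    return W


class TestMotherWavelets:
    def test_cmor_closed_form_at_zero(self):
        assert wavelet_eval(CMOR, 0.0) == pytest.approx(np.pi**-0.5 + 0j)

    def test_cmor_envelope_even(self):
        t = np.linspace(0.1, 4.0, 25)
        assert np.allclose(
            np.abs(wavelet_eval(CMOR, t)), np.abs(wavelet_eval(CMOR, -t))
        )

    def test_cmor_l2_norm_frozen(self):
        # the standard cmor normalization has L2 norm^2 = 1/sqrt(2*pi*fb)
        t = np.linspace(-10, 10, 200_001)
        energy = np.trapezoid(np.abs(wavelet_eval(CMOR, t)) ** 2, t)
        assert energy == pytest.approx(1 / np.sqrt(2 * np.pi), abs=1e-9)

    def test_cgau_unit_l2_norm(self):
        t = np.linspace(-10, 10, 200_001)
        for order in (1, 2):
            energy = np.trapezoid(
                np.abs(wavelet_eval(WaveletSpec.cgau(order), t)) ** 2, t
            )
            assert energy == pytest.approx(1.0, abs=1e-6)

    def test_cgau1_center_frequency(self):
        # analytic argmax of |omega| * exp(-(omega+1)^2/4) is |omega| = 2,
        # i.e. 1/pi cycles per unit time
        spec = WaveletSpec.cgau(1)
        assert spec.center_frequency == pytest.approx(1 / np.pi, abs=2e-3)

    def test_cgau1_center_frequency_vs_pywavelets(self):
        import pywt

        spec = WaveletSpec.cgau(1)
        assert spec.center_frequency == pytest.approx(
            pywt.central_frequency("cgau1", precision=12), rel=0.1
        )

    def test_cmor_matches_pywavelets_samples(self):
        import pywt

        psi, t = pywt.ContinuousWavelet("cmor1-1.5").wavefun(10)
        assert np.allclose(wavelet_eval(CMOR, t), psi, atol=1e-8)

    def test_unsupported_family(self):
        with pytest.raises(ParameterError):
            WaveletSpec("mexh")
        with pytest.raises(ParameterError):
            WaveletSpec.from_name("db4")


class TestScalePeriodConversion:
    def test_published_endpoints_exact(self):
        assert scale_to_period(30.0, CMOR, 1.0) == pytest.approx(20.0, abs=1e-12)
        assert scale_to_period(0.3, CMOR, 1.0) == pytest.approx(0.2, abs=1e-12)

    def test_identity_case(self):
        assert scale_to_period(CMOR.center_frequency, CMOR, 1.0) == pytest.approx(1.0)

    def test_round_trip(self):
        for a in (0.3, 1.0, 7.5, 30.0):
            assert period_to_scale(
                scale_to_period(a, CMOR, 1.0), CMOR, 1.0
            ) == pytest.approx(a, abs=1e-12)

    def test_strictly_increasing_in_scale(self):
        grid = default_scale_grid()
        periods = [scale_to_period(a, CMOR, 1.0) for a in grid]
        assert np.all(np.diff(periods) > 0)

    def test_matches_pywavelets_scale2frequency(self):
        import pywt

        for a in (0.3, 3.0, 30.0):
            ours = 1.0 / scale_to_period(a, CMOR, 1.0)
            assert ours == pytest.approx(pywt.scale2frequency("cmor1-1.5", a))

    def test_domain(self):
        with pytest.raises(DomainError):
            scale_to_period(-1.0, CMOR, 1.0)


class TestTransform:
    def test_zero_series_zero_coefficients(self):
        ts = TimeSeries(np.arange(16.0), np.zeros(16))
        res = cwt_transform(ts, np.array([1.0, 4.0]), CMOR)
        assert np.all(res.coefficients == 0)

    def test_constant_series_small_far_from_edges(self):
        # the zero-mean wavelet annihilates constants once the support fits
        # and the oscillation is resolved by the sampling (a >~ 2*fc)
        ts = TimeSeries(np.arange(64.0), np.full(64, 5.0))
        res = cwt_transform(ts, np.array([4.0, 6.0]), CMOR)
        far = np.abs(np.arange(64) - 31.5) < 8
        assert np.max(np.abs(res.coefficients[:, far])) < 1e-6

    def test_impulse_reproduces_wavelet(self):
        n, k = 24, 9
        x = np.zeros(n)
        x[k] = 1.0
        ts = TimeSeries(np.arange(float(n)), x)
        scales = np.array([0.8, 2.0, 5.0])
        res = cwt_transform(ts, scales, CMOR)
        b = np.arange(n)
        for i, a in enumerate(scales):
            expected = np.conj(wavelet_eval(CMOR, (k - b) / a)) / np.sqrt(a)
            assert np.allclose(res.coefficients[i], expected, atol=1e-12)

    def test_linear_in_input(self, rng):
        t = np.arange(20.0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        scales = np.array([1.0, 3.0])
        wx = cwt_transform(TimeSeries(t, x), scales, CMOR).coefficients
        wy = cwt_transform(TimeSeries(t, y), scales, CMOR).coefficients
        wz = cwt_transform(TimeSeries(t, 2 * x - 3 * y), scales, CMOR).coefficients
        assert np.allclose(wz, 2 * wx - 3 * wy, atol=1e-9)

    def test_matches_direct_sum_oracle(self, rng):
        spec = CMOR
        scales = np.geomspace(0.5, 8.0, 6)
        for _ in range(100):
            n = int(rng.integers(8, 49))
            x = rng.normal(size=n)
            ts = TimeSeries(np.arange(float(n)), x)
            res = cwt_transform(ts, scales, spec)
            assert np.allclose(
                res.coefficients, oracle_cwt(x, scales, spec), atol=1e-10
            )

    def test_empty_or_bad_scales(self, rng):
        ts = TimeSeries(np.arange(10.0), rng.normal(size=10))
        with pytest.raises(ParameterError):
            cwt_transform(ts, np.array([]), CMOR)
        with pytest.raises(ParameterError):
            cwt_transform(ts, np.array([2.0, 1.0]), CMOR)


class TestDominantPeriod:
    @pytest.mark.parametrize("period", [12.0, 6.0])
    def test_pure_sinusoid_recovered(self, period):
        m = np.arange(1.0, 37.0)
        ts = TimeSeries(m, np.cos(2 * np.pi * m / period), time_unit="month")
        dom = dominant_period(cwt_transform(ts))
        assert abs(np.log(dom / period)) <= GRID_STEP + 1e-9

    def test_larger_amplitude_component_wins(self):
        m = np.arange(1.0, 37.0)
        y = 3.0 * np.cos(2 * np.pi * m / 6) + 1.0 * np.cos(2 * np.pi * m / 12)
        dom = dominant_period(cwt_transform(TimeSeries(m, y, time_unit="month")))
        assert abs(np.log(dom / 6.0)) <= GRID_STEP + 1e-9

    def test_scale_covariance(self):
        # stretching the period by k moves the dominant period by k
        t = np.arange(0.0, 96.0)
        doms = []
        for period in (8.0, 16.0):
            ts = TimeSeries(t, np.cos(2 * np.pi * t / period))
            doms.append(dominant_period(cwt_transform(ts)))
        assert abs(np.log(doms[1] / doms[0] / 2.0)) <= 2 * GRID_STEP + 1e-9

    def test_agreement_with_pywavelets_power_argmax(self):
        import pywt

        m = np.arange(1.0, 37.0)
        y = np.cos(2 * np.pi * m / 12)
        grid = default_scale_grid()
        ours = dominant_period(cwt_transform(TimeSeries(m, y, time_unit="month")),
                               exclude_cone=False)
        coefs, freqs = pywt.cwt(y, grid, "cmor1-1.5", sampling_period=1.0)
        theirs = 1.0 / freqs[int(np.argmax(np.mean(np.abs(coefs) ** 2, axis=1)))]
        assert abs(np.log(ours / theirs)) <= GRID_STEP + 1e-9

    def test_refined_peak_within_one_grid_step_of_argmax(self):
        m = np.arange(1.0, 37.0)
        for period in (6.0, 12.0):
            ts = TimeSeries(m, np.cos(2 * np.pi * m / period), time_unit="month")
            res = cwt_transform(ts)
            coarse = dominant_period(res)
            fine = dominant_period(res, refine=True)
            assert abs(np.log(fine / coarse)) <= GRID_STEP + 1e-9
            # refinement lands closer to the true period than the grid point
            assert abs(np.log(fine / period)) <= abs(np.log(coarse / period)) + 1e-9

    def test_degenerate_when_everything_in_cone(self):
        ts = TimeSeries(np.arange(8.0), np.cos(np.arange(8.0)))
        res = cwt_transform(ts, np.array([20.0, 30.0]), CMOR)
        with pytest.raises(DegenerateSeriesError):
            dominant_period(res, exclude_cone=True)


class TestRealPartExtraction:
    def test_oscillates_at_queried_period(self):
        m = np.arange(1.0, 37.0)
        ts = TimeSeries(m, np.cos(2 * np.pi * m / 12), time_unit="month")
        row = real_part_at_scale(cwt_transform(ts), 12.0)
        assert len(row) == len(ts)
        # zero crossings of the interior stretch are ~6 months apart
        mid = row.values[6:30]
        crossings = np.flatnonzero(np.diff(np.sign(mid)) != 0)
        spacing = np.diff(crossings)
        assert np.all(np.abs(spacing - 6.0) <= 1)

    def test_zero_series_zero_output(self):
        ts = TimeSeries(np.arange(1.0, 37.0), np.zeros(36), time_unit="month")
        row = real_part_at_scale(cwt_transform(ts), 10.0)
        assert np.all(row.values == 0)

    def test_period_outside_range_rejected(self):
        ts = TimeSeries(np.arange(1.0, 37.0), np.cos(np.arange(36.0)),
                        time_unit="month")
        res = cwt_transform(ts)
        with pytest.raises(ParameterError):
            real_part_at_scale(res, 100.0)


def test_cone_of_influence_geometry():
    ts = TimeSeries(np.arange(36.0), np.cos(np.arange(36.0)))
    res = cwt_transform(ts, np.array([1.0, 18.0]), CMOR)
    # small scale: only a thin edge strip is contaminated
    assert res.in_cone[0].sum() == 2
    # the 12-month scale keeps an interior window clean on 36 points
    clean = ~res.in_cone[1]
    assert clean.sum() > 0
    assert clean[18] and not clean[0]


def test_long_format_export_shape(tmp_path):
    ts = TimeSeries(np.arange(12.0), np.cos(np.arange(12.0)))
    res = cwt_transform(ts, np.array([1.0, 2.0]), CMOR)
    frame = res.to_frame()
    assert list(frame.columns) == ["scale", "period", "time", "re", "im", "in_cone"]
    assert len(frame) == 2 * 12
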