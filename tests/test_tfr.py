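"""Morlet ERSP tests: cycle law, convolution oracle, baseline algebra."""

import numpy as np
import pytest

from swallow_ersp.tfr import (
    TimeFrequencyMap,
    average_trials,
    make_wavelet_plan,
    morlet_kernel,
    prestimulus_db_correction,
    single_trial_full_epoch_baseline,
    trial_power,
)

RATE = 512.0


class TestWaveletPlan:
    def test_cycle_law_anchors(self):
        plan = make_wavelet_plan(rate=RATE)
        assert plan.cycles[np.argmin(np.abs(plan.freqs - 7.0))] == pytest.approx(3.0)
        assert plan.cycles[np.argmin(np.abs(plan.freqs - 30.0))] == pytest.approx(20.0)

    def test_cycle_law_midpoint(self):
        plan = make_wavelet_plan(f_grid_spacing=0.25, rate=RATE)
        i = np.argmin(np.abs(plan.freqs - 18.5))
        assert plan.cycles[i] == pytest.approx(11.5)

    def test_default_grid_has_half_hz_spacing(self):
        plan = make_wavelet_plan(rate=RATE)
        assert len(plan.freqs) == 47
        np.testing.assert_allclose(np.diff(plan.freqs), 0.5)

    def test_grid_outside_range_rejected(self):
        from swallow_ersp.tfr import WaveletPlan
        with pytest.raises(ValueError, match=r"\[7.0, 30.0\]"):
            WaveletPlan(freqs=np.array([5.0, 10.0]),
                        cycles=np.array([3.0, 5.0]), rate=RATE)

    def test_rate_below_nyquist_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            make_wavelet_plan(rate=50.0)


def _direct_convolution_power(x, plan):
    """Brute-force time-domain oracle for the Morlet power."""
    n = len(x)
    out = np.empty((n, len(plan.freqs)))
    for j, (f, c) in enumerate(zip(plan.freqs, plan.cycles)):
        k = morlet_kernel(f, c, plan.rate)
        conv = np.convolve(x, k, mode="same")
        out[:, j] = np.abs(conv) ** 2
    return out


class TestTrialPower:
    def test_pure_sine_localizes_at_its_frequency(self):
        plan = make_wavelet_plan(rate=RATE)
        t = np.arange(int(6 * RATE)) / RATE
        x = 2.0 * np.sin(2 * np.pi * 10.0 * t)
        m = trial_power(x, plan)
        interior = m.valid.all(axis=1)
        vals = m.values[interior]
        peak_freq = plan.freqs[np.argmax(vals.mean(axis=0))]
        assert peak_freq == pytest.approx(10.0, abs=0.5)
        j10 = np.argmin(np.abs(plan.freqs - 10.0))
        row = vals[:, j10]
        assert row.std() / row.mean() < 0.01  # constant over interior times

    def test_deterministic(self):
        plan = make_wavelet_plan(rate=RATE)
        x = np.random.default_rng(0).normal(size=int(6 * RATE))
        a = trial_power(x, plan)
        b = trial_power(x, plan)
        np.testing.assert_array_equal(a.values, b.values)

    def test_fft_path_equals_direct_convolution(self):
        """1 s segment: FFT convolution vs brute-force time-domain oracle."""
        plan = make_wavelet_plan(rate=RATE, n_times=10 ** 9)  # no decimation
        x = np.random.default_rng(1).normal(size=int(1.0 * RATE))
        m = trial_power(x, plan)
        oracle = _direct_convolution_power(x, plan)
        np.testing.assert_allclose(m.values, oracle, rtol=1e-6, atol=1e-12)

    def test_edge_cells_are_masked_not_zeroed(self):
        plan = make_wavelet_plan(rate=RATE)
        x = np.ones(int(6 * RATE))
        m = trial_power(x, plan)
        # low frequencies have wide support: first output sample invalid
        assert not m.valid[0, 0]
        assert m.valid[m.values.shape[0] // 2].all()

    def test_nan_input_rejected(self):
        plan = make_wavelet_plan(rate=RATE)
        x = np.zeros(int(6 * RATE))
        x[10] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            trial_power(x, plan)


def _map_from(values, stage="raw_power", valid=None, freqs=None, times=None):
    values = np.asarray(values, float)
    nt, nf = values.shape
    return TimeFrequencyMap(
        values=values,
        valid=np.ones_like(values, bool) if valid is None else valid,
        time_axis_ms=np.linspace(-1000, 4990, nt) if times is None else times,
        freqs=np.linspace(7, 30, nf) if freqs is None else freqs,
        stage=stage)


class TestSingleTrialBaseline:
    def test_constant_row_becomes_ones(self):
        m = _map_from(np.full((20, 3), 7.0))
        out = single_trial_full_epoch_baseline(m)
        np.testing.assert_allclose(out.values, 1.0)
        assert out.stage == "trial_normalized"

    def test_mean_division(self):
        m = _map_from(np.array([[1.0], [3.0]]))
        out = single_trial_full_epoch_baseline(m)
        np.testing.assert_allclose(out.values[:, 0], [0.5, 1.5])

    def test_output_column_mean_is_one(self):
        rng = np.random.default_rng(2)
        m = _map_from(rng.exponential(size=(50, 4)))
        out = single_trial_full_epoch_baseline(m)
        np.testing.assert_allclose(out.values.mean(axis=0), 1.0, atol=1e-12)

    def test_all_masked_column_raises(self):
        m = _map_from(np.ones((10, 2)))
        m.valid[:, 1] = False
        with pytest.raises(ValueError, match="no valid samples"):
            single_trial_full_epoch_baseline(m)


class TestAverageTrials:
    def test_identical_maps_average_to_themselves(self):
        m = _map_from(np.random.default_rng(3).exponential(size=(10, 4)),
                      stage="trial_normalized")
        out = average_trials([m, m, m])
        np.testing.assert_allclose(out.values, m.values)
        assert out.stage == "averaged"

    def test_mean_of_two_constants(self):
        a = _map_from(np.full((10, 4), 0.5), stage="trial_normalized")
        b = _map_from(np.full((10, 4), 1.5), stage="trial_normalized")
        np.testing.assert_allclose(average_trials([a, b]).values, 1.0)

    def test_n_trials_recorded(self):
        maps = [_map_from(np.ones((5, 2)), stage="trial_normalized")
                for _ in range(40)]
        assert average_trials(maps).n_trials == 40

    def test_grid_mismatch_rejected(self):
        a = _map_from(np.ones((10, 4)), stage="trial_normalized")
        b = _map_from(np.ones((12, 4)), stage="trial_normalized")
        with pytest.raises(ValueError, match="grid"):
            average_trials([a, b])


class TestDbCorrection:
    def test_time_constant_map_gives_zero_db(self):
        m = _map_from(np.full((60, 4), 3.7), stage="averaged")
        out = prestimulus_db_correction(m)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)
        assert out.stage == "db_corrected"

    def test_half_power_is_minus_3db(self):
        vals = np.ones((60, 2))
        times = np.linspace(-1000, 4900, 60)
        vals[times > 0, :] = 0.5
        m = _map_from(vals, stage="averaged", times=times)
        out = prestimulus_db_correction(m)
        np.testing.assert_allclose(out.values[times > 0, 0], -3.0103, atol=1e-3)

    def test_baseline_linear_ratio_mean_is_one(self):
        rng = np.random.default_rng(4)
        m = _map_from(rng.exponential(size=(80, 5)) + 0.1, stage="averaged")
        out = prestimulus_db_correction(m)
        in_bl = (out.time_axis_ms >= -1000) & (out.time_axis_ms < 0)
        lin = 10 ** (out.values[in_bl] / 10)
        np.testing.assert_allclose(lin.mean(axis=0), 1.0, atol=1e-6)

    def test_nonpositive_baseline_rejected(self):
        m = _map_from(np.zeros((60, 2)), stage="averaged")
        with pytest.raises(ValueError, match="baseline"):
            prestimulus_db_correction(m)


def test_amplitude_scaling_invariance():
    """x -> k*x multiplies raw power by k^2 and leaves dB output unchanged."""
    plan = make_wavelet_plan(rate=RATE)
    rng = np.random.default_rng(5)
    x = rng.normal(size=int(6 * RATE))
    k = 3.7
    raw1 = trial_power(x, plan)
    raw2 = trial_power(k * x, plan)
    np.testing.assert_allclose(raw2.values, k * k * raw1.values, rtol=1e-9)

    def chain(raw):
        n = single_trial_full_epoch_baseline(raw)
        avg = average_trials([n])
        return prestimulus_db_correction(avg)

    d1, d2 = chain(raw1), chain(raw2)
    ok = d1.valid
    np.testing.assert_allclose(d2.values[ok], d1.values[ok], atol=1e-9)


def test_erd_onset_latency_within_wavelet_resolution(healthy_alpha_epochs):
    """The half-depth crossing of the measured alpha ERD falls within one
    wavelet temporal SD of the generative ERD onset ramp midpoint."""
    from swallow_ersp.biomarkers import ALPHA, compute_ero
    from swallow_ersp.synthgen import group_preset
    from swallow_ersp.tfr import ersp_from_epochs

    m = ersp_from_epochs(healthy_alpha_epochs, "C3")
    tr = compute_ero(m, ALPHA)
    sel = tr.valid & (tr.time_axis_ms > -500) & (tr.time_axis_ms < 2000)
    t = tr.time_axis_ms[sel]
    v = tr.values[sel]
    plateau = np.median(v[(t > 800) & (t < 1800)])
    half = plateau / 2.0
    crossing = t[np.argmax(v < half)]  # first time below half depth
    p = group_preset("healthy")
    onset_mid = p.erd_onset_ms + p.ramp_ms / 2.0  # trial jitter is uniform +-100 ms
    plan = make_wavelet_plan(rate=RATE)
    sigma_ms = plan.sigma_t(10.0) * 1000.0
    assert abs(crossing - onset_mid) < sigma_ms + p.trial_jitter_ms
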