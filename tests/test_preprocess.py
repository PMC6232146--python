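import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grasprsa import preprocess as pp
from grasprsa.protocol import generate_protocol
from grasprsa.synth import inject_artifact_trials


# ---------------------------------------------------------------------------
# filtering / resampling
# ---------------------------------------------------------------------------
class TestBandpass:
    def test_passband_tone_preserved_within_5_percent(self):
        fs, f0 = 1000.0, 10.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = pp.bandpass_filter(x, fs, 0.1, 40.0)
        mid = slice(int(2 * fs), int(8 * fs))
        amp = np.sqrt(2) * y[mid].std()
        assert abs(amp - 1.0) < 0.05

    def test_dc_removed(self):
        fs = 1000.0
        y = pp.bandpass_filter(np.full(int(10 * fs), 3.0), fs, 0.1, 40.0)
        assert np.abs(y[int(2 * fs):int(8 * fs)]).max() < 0.05

    def test_zero_phase_no_lag(self):
        fs, f0 = 1000.0, 10.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = pp.bandpass_filter(x, fs, 0.1, 40.0)
        mid = slice(int(2 * fs), int(8 * fs))
        lags = np.arange(-20, 21)
        cc = [np.dot(x[mid], np.roll(y, k)[mid]) for k in lags]
        assert lags[int(np.argmax(cc))] == 0

    def test_filter_plus_downsample_attenuates_50hz_by_20db(self):
        """The band-pass + decimation chain must keep a 10-Hz tone in its
        bin and knock a 50-Hz tone down by >= 20 dB."""
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t) + np.sin(2 * np.pi * 50.0 * t)
        y = pp.downsample(pp.bandpass_filter(x, fs, 0.1, 40.0), fs, 100.0)
        mid = y[500:-500]
        spec = np.abs(np.fft.rfft(mid)) / mid.size
        freqs = np.fft.rfftfreq(mid.size, 1 / 100.0)
        p10 = spec[np.argmin(np.abs(freqs - 10.0))]
        p50 = spec[np.argmin(np.abs(freqs - 49.9))]
        assert freqs[np.argmax(spec)] == pytest.approx(10.0, abs=0.1)
        assert 20 * np.log10(max(p50, 1e-12) / p10) < -20

    def test_bad_cutoffs_raise(self):
        x = np.zeros(1000)
        with pytest.raises(ValueError):
            pp.bandpass_filter(x, 100.0, 0.1, 60.0)   # above Nyquist
        with pytest.raises(ValueError):
            pp.bandpass_filter(np.zeros(10), 100.0, 0.1, 40.0)  # too short


class TestDownsample:
    def test_length_and_rate(self):
        x = np.random.default_rng(0).standard_normal((3, 15000))
        y = pp.downsample(x, 1000.0, 100.0)
        assert y.shape == (3, 1500)

    def test_constant_preserved(self):
        y = pp.downsample(np.full(5000, 2.5), 1000.0, 100.0)
        np.testing.assert_allclose(y[10:-10], 2.5, atol=1e-6)

    def test_tone_keeps_spectral_peak(self):
        fs = 1000.0
        t = np.arange(int(15 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = pp.downsample(x, fs, 100.0)
        spec = np.abs(np.fft.rfft(y))
        freqs = np.fft.rfftfreq(y.size, 1 / 100.0)
        assert abs(freqs[np.argmax(spec)] - 10.0) < 0.1

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            pp.downsample(np.zeros(1000), 250.0, 100.0)


# ---------------------------------------------------------------------------
# epoching and rejection
# ---------------------------------------------------------------------------
class TestEpoching:
    def test_epoch_count_and_shapes(self, small_session):
        epochs = pp.epoch_trials(small_session)
        proto = small_session.protocol
        assert len(epochs) == proto.n_trials
        ep = epochs[0]
        assert ep.eeg.shape == (61, 1500)
        assert ep.emg.shape == (8, 3000)
        assert ep.joints.shape == (19, 1500)
        assert ep.accel.shape == (3, 750)

    def test_epochs_reordered_by_condition(self, small_session):
        epochs = pp.epoch_trials(small_session)
        keys = [(e.condition, e.repetition) for e in epochs]
        assert keys == sorted(keys)

    def test_clean_session_keeps_everything(self, small_session):
        epochs = pp.epoch_trials(small_session)
        kept, report = pp.reject_trials(epochs, pp.RejectionRules(),
                                        small_session.protocol)
        assert len(kept) == len(epochs)
        assert report == []

    def test_injected_bad_trials_rejected_with_matching_reasons(
            self, small_session):
        bad = [(1, "movement_during_observation"), (4, "tracking_glitch")]
        rec = inject_artifact_trials(small_session, bad, seed=9)
        epochs = pp.epoch_trials(rec)
        kept, report = pp.reject_trials(epochs, pp.RejectionRules(),
                                        rec.protocol)
        trial_reports = [r for r in report if r["trial"] is not None]
        assert len(trial_reports) == 2
        assert len(kept) == len(epochs) - 2
        reasons = {r["reason"] for r in trial_reports}
        assert reasons == {"execution", "tracking"}

    def test_all_trials_of_condition_rejected_flags_condition(
            self, small_session):
        # knock out both repetitions of the condition presented first
        rec = inject_artifact_trials(
            small_session, [(0, "tracking_glitch"), (1, "tracking_glitch")],
            seed=9)
        epochs = pp.epoch_trials(rec)
        kept, report = pp.reject_trials(epochs, pp.RejectionRules(),
                                        rec.protocol)
        unusable = [r for r in report if r["reason"] == "condition_unusable"]
        assert len(unusable) == 1


# ---------------------------------------------------------------------------
# change-point detection
# ---------------------------------------------------------------------------
def oracle_changepoint(y, min_seg=5, min_improvement=0.1):
    """Exhaustive-split brute force with explicit least-squares fits."""
    y = np.asarray(y, dtype=float)
    n = y.size

    def sse(seg):
        t = np.arange(seg.size)
        coef = np.polyfit(t, seg, 1)
        return float(((seg - np.polyval(coef, t)) ** 2).sum())

    best_tau, best = None, np.inf
    for tau in range(min_seg, n - min_seg + 1):
        total = sse(y[:tau]) + sse(y[tau:])
        if total < best - 1e-12:
            best, best_tau = total, tau
    sse0 = sse(y)
    if sse0 <= 1e-10 * max(1.0, float(np.dot(y, y))):
        return None
    if (sse0 - best) / sse0 < min_improvement:
        return None
    return best_tau


class TestChangepoint:
    def test_step_signal_split_at_step(self):
        y = np.concatenate([np.zeros(50), np.ones(50)])
        assert pp.detect_changepoint_linear(y) == 50

    def test_constant_signal_gives_none(self):
        assert pp.detect_changepoint_linear(np.full(60, 1.3)) is None

    def test_pure_ramp_gives_none(self):
        assert pp.detect_changepoint_linear(0.5 * np.arange(80)) is None

    def test_two_slope_ramp_matches_bruteforce(self):
        t = np.arange(100, dtype=float)
        y = np.where(t < 37, 0.2 * t, 0.2 * 37 + 1.5 * (t - 37))
        tau = pp.detect_changepoint_linear(y)
        assert tau == oracle_changepoint(y) == 37

    @pytest.mark.parametrize("n,kink,m1,m2,jump", [
        (40, 13, 0.0, 2.0, 0.0),
        (80, 29, -0.5, 0.7, 1.0),
        (200, 101, 0.3, -1.1, -2.0),
        (120, 17, 0.0, 0.0, 3.0),
        (60, 43, 1.0, 1.0, -1.5),
    ])
    def test_equals_exhaustive_oracle_on_piecewise_signals(
            self, n, kink, m1, m2, jump):
        t = np.arange(n, dtype=float)
        y = np.where(t < kink, m1 * t,
                     m1 * kink + jump + m2 * (t - kink))
        assert pp.detect_changepoint_linear(y) == oracle_changepoint(y)

    def test_window_too_short_raises(self):
        with pytest.raises(ValueError):
            pp.detect_changepoint_linear(np.zeros(8), min_seg=5)


# ---------------------------------------------------------------------------
# Morlet TFR and ERD/S
# ---------------------------------------------------------------------------
class TestMorletTFR:
    fs = 100.0

    def _tone(self, f0, amp=1.0, seconds=15.0):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return amp * np.sin(2 * np.pi * f0 * t)

    def test_tone_peaks_at_its_frequency_bin(self):
        power, valid = pp.morlet_tfr(self._tone(10.0), self.fs)
        mid = power[0, :, 400:1100].mean(axis=1)
        from grasprsa.searchlight import FREQ_GRID
        assert FREQ_GRID[np.argmax(mid)] == 10.0

    def test_two_tones_give_two_local_maxima(self):
        x = self._tone(6.0) + self._tone(20.0)
        power, _ = pp.morlet_tfr(x, self.fs)
        from grasprsa.searchlight import FREQ_GRID
        mid = power[0, :, 400:1100].mean(axis=1)
        peaks = [i for i in range(1, len(mid) - 1)
                 if mid[i] > mid[i - 1] and mid[i] > mid[i + 1]
                 and mid[i] > 0.1 * mid.max()]
        assert {float(FREQ_GRID[i]) for i in peaks} >= {6.0, 20.0}

    def test_doubled_amplitude_quadruples_power(self):
        p1, _ = pp.morlet_tfr(self._tone(12.0, 1.0), self.fs)
        p2, _ = pp.morlet_tfr(self._tone(12.0, 2.0), self.fs)
        mid = slice(400, 1100)
        ratio = p2[0, 23, mid].mean() / p1[0, 23, mid].mean()
        assert abs(ratio - 4.0) < 0.08

    def test_long_wavelets_flagged_invalid(self):
        x = np.random.default_rng(0).standard_normal(int(2 * self.fs))
        _, valid = pp.morlet_tfr(x, self.fs)
        assert not valid[0]          # 0.5-Hz wavelet longer than 2 s
        assert valid[-1]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            pp.morlet_tfr(np.zeros(100), self.fs, freqs=np.array([]))

    def test_matches_mne_oracle(self):
        """Independent cross-check against mne's Morlet implementation on a
        noisy two-tone signal: power profiles per frequency correlate near
        1 away from the edges."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(5)
        x = (self._tone(8.0) + 0.5 * self._tone(25.0)
             + 0.1 * rng.standard_normal(1500))
        freqs = np.array([4.0, 8.0, 15.0, 25.0])
        cycles = np.array([3.0, 4.0, 5.0, 6.0])
        mine, _ = pp.morlet_tfr(x, self.fs, freqs=freqs, cycles=cycles)
        theirs = mne.time_frequency.tfr_array_morlet(
            x[None, None, :], self.fs, freqs, n_cycles=cycles,
            output="power", verbose="error")[0, 0]
        for k in range(len(freqs)):
            a, b = mine[0, k, 300:1200], theirs[k, 300:1200]
            r = np.corrcoef(a, b)[0, 1]
            assert r > 0.99


class TestERDS:
    def test_closed_form_percent_change(self):
        base = np.full((2, 3), 4.0)
        move = np.stack([np.full((2, 3), 4.0), np.full((2, 3), 2.0),
                         np.full((2, 3), 8.0)], axis=-1)
        erds = pp.compute_erds(move, base)
        np.testing.assert_allclose(erds.values[..., 0], 0.0)
        np.testing.assert_allclose(erds.values[..., 1], -50.0)
        np.testing.assert_allclose(erds.values[..., 2], 100.0)
        assert erds.values.min() >= -100.0

    def test_nonpositive_baseline_names_offender(self):
        base = np.ones((2, 3))
        base[1, 2] = 0.0
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            pp.compute_erds(np.ones((2, 3, 4)), base)


# ---------------------------------------------------------------------------
# EMG envelope
# ---------------------------------------------------------------------------
class TestEMGEnvelope:
    def test_unit_variance_tone_gives_sqrt2_envelope(self):
        t = np.arange(4000) / 200.0
        x = np.sin(2 * np.pi * 20.0 * t)
        x = x / x.std()
        env = pp.emg_envelope(x)
        inner = env[0, 200:-200]
        np.testing.assert_allclose(inner, np.sqrt(2), rtol=0.02)

    def test_envelope_recovers_modulator(self):
        rng = np.random.default_rng(3)
        t = np.arange(6000) / 200.0
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        x = mod * np.sin(2 * np.pi * 30.0 * t) \
            + 0.01 * rng.standard_normal(t.size)
        env = pp.emg_envelope(x)[0]
        sl = slice(300, -300)
        r = np.corrcoef(env[sl], mod[sl])[0, 1]
        assert r > 0.99

    def test_envelope_nonnegative_and_constant_channel_rejected(self):
        x = np.random.default_rng(0).standard_normal((3, 1000))
        assert (pp.emg_envelope(x) >= 0).all()
        x[1] = 2.0
        with pytest.raises(ValueError, match="channel 1"):
            pp.emg_envelope(x)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------
class TestInterpolation:
    def test_constant_and_linear_reproduced_exactly(self):
        t = np.sort(np.random.default_rng(1).uniform(0, 10, 200))
        const = np.full((1, t.size), 0.7)
        grid, out = pp.interpolate_kinematics(t, const, 100.0, 0.0, 9.0)
        np.testing.assert_allclose(out, 0.7, atol=1e-9)
        lin = (0.05 * t)[None, :]
        grid, out = pp.interpolate_kinematics(t, lin, 100.0, 0.5, 8.0)
        np.testing.assert_allclose(out[0], 0.05 * grid, atol=1e-6)

    def test_grid_spacing_is_10ms(self):
        t = np.linspace(0, 5, 300)
        grid, _ = pp.interpolate_kinematics(t, np.sin(t)[None], 100.0)
        np.testing.assert_allclose(np.diff(grid), 0.01, atol=1e-12)

    def test_duplicate_timestamps_rejected(self):
        t = np.array([0.0, 0.1, 0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="duplicate"):
            pp.interpolate_kinematics(t, np.zeros((1, 5)), 100.0)

    def test_wraparound_trace_interpolated_smoothly(self):
        # angles walking through +pi must not produce 2*pi jumps
        from grasprsa.synth import wrap_angle
        t = np.linspace(0, 2, 150)
        raw = 3.0 + 0.5 * t                     # crosses pi
        grid, out = pp.interpolate_kinematics(t, wrap_angle(raw)[None],
                                              100.0)
        steps = np.abs(wrap_angle(np.diff(out[0])))
        assert steps.max() < 0.05


class TestCircularMean:
    def test_simple_mean(self):
        assert pp.circular_mean(np.deg2rad([0.0, 90.0])) == \
            pytest.approx(np.deg2rad(45.0))

    def test_wraparound_gives_180_not_0(self):
        m = pp.circular_mean(np.deg2rad([179.0, -179.0]))
        assert abs(abs(m) - np.pi) < 1e-9

    def test_zero_resultant_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            pp.circular_mean(np.deg2rad([0.0, 180.0]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-3.0, 3.0), min_size=2, max_size=20),
           st.floats(-3.0, 3.0))
    def test_rotation_equivariance(self, angles, shift):
        """Rotating all angles rotates the mean by the same amount."""
        from grasprsa.synth import wrap_angle
        a = np.asarray(angles)
        try:
            m0 = pp.circular_mean(a)
        except ValueError:
            return
        m1 = pp.circular_mean(wrap_angle(a + shift))
        assert abs(wrap_angle(m1 - m0 - shift)) < 1e-6


class TestKinematicPCA:
    def test_rank1_data_first_component_explains_all(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.standard_normal(19), rng.standard_normal(500))
        res = pp.kinematic_pca(X, n_components=5)
        assert res.variance_fractions[0] > 1 - 1e-9

    def test_five_synergies_with_5pct_noise_explain_95pct(self):
        rng = np.random.default_rng(7)
        B, _ = np.linalg.qr(rng.standard_normal((19, 5)))
        scores = rng.standard_normal((5, 2000))
        X = B @ scores
        X += 0.05 * X.std() * rng.standard_normal(X.shape)
        res = pp.kinematic_pca(X, n_components=5)
        assert res.variance_fractions.sum() >= 0.95

    def test_low_rank_warns_and_returns_available(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.standard_normal(19), rng.standard_normal(100))
        with pytest.warns(UserWarning, match="directions"):
            res = pp.kinematic_pca(X, n_components=5)
        assert res.components.shape[0] < 5


class TestAveraging:
    def test_single_subject_single_repetition_is_identity(self):
        v = np.arange(6.0)[None, :]
        conds, group, log = pp.average_condition_patterns([{1: v}])
        np.testing.assert_array_equal(group[0], v[0])
        assert log == []

    def test_opposite_subjects_average_to_zero(self):
        v = np.arange(1.0, 5.0)
        conds, group, _ = pp.average_condition_patterns(
            [{1: v[None]}, {1: -v[None]}])
        np.testing.assert_allclose(group[0], 0.0)

    def test_subject_order_irrelevant(self, rng):
        subs = [{c: rng.standard_normal((3, 8)) for c in (1, 2)}
                for _ in range(4)]
        _, a, _ = pp.average_condition_patterns(subs)
        _, b, _ = pp.average_condition_patterns(subs[::-1])
        np.testing.assert_allclose(a, b)

    def test_missing_condition_excluded_and_logged(self, rng):
        subs = [{1: rng.standard_normal((2, 4)), 2: rng.standard_normal((2, 4))},
                {1: rng.standard_normal((2, 4))}]
        conds, group, log = pp.average_condition_patterns(subs)
        assert conds == [1, 2]
        assert log and log[0]["condition"] == 2 and log[0]["subject"] == 1


class TestComponentAlignment:
    def test_permuted_flipped_basis_realigned(self, rng):
        ref = rng.standard_normal((5, 19))
        perm = np.array([3, 0, 4, 1, 2])
        signs = np.array([1, -1, 1, -1, 1.0])
        comp = ref[perm] * signs[:, None]
        p, s = pp.align_components(ref, comp)
        restored = comp[p] * s[:, None]
        np.testing.assert_allclose(restored, ref, atol=1e-12)
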