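"""Preprocessing: from raw streams to per-trial, analysis-ready features.

The chain follows standard sensorimotor-EEG practice: Butterworth band-pass
(0.1-40 Hz, fourth order, zero phase) and downsampling to 100 Hz; epoching
into 15-s trials reordered by condition; movement-onset detection from the
accelerometer by piecewise-linear change-point fitting; trial rejection
(movement during observation, tracking glitches); Morlet time-frequency
power on a 0.5-Hz grid and ERD/S as percent power change against the
fixation baseline; Hilbert envelopes for EMG; cubic-spline resampling and
PCA synergies for the joint angles; and within-subject / across-subject
averaging to one group-level pattern per condition (circular mean for raw
angles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .searchlight import FREQ_GRID
from .synth import MultimodalRecording, wrap_angle

BASELINE_WINDOW_S = (1.0, 3.0)   # fixation interval used for ERD/S baseline


# ---------------------------------------------------------------------------
# filtering / resampling
# ---------------------------------------------------------------------------
def bandpass_filter(x: np.ndarray, fs: float, low_hz: float = 0.1,
                    high_hz: float = 40.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"need 0 < low < high < Nyquist ({nyq} Hz); got "
            f"[{low_hz}, {high_hz}]")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                     output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if np.asarray(x).shape[-1] <= padlen:
        raise ValueError(
            f"signal of length {np.asarray(x).shape[-1]} is too short for "
            f"zero-phase filtering (needs > {padlen} samples)")
    return sps.sosfiltfilt(sos, x, axis=-1)


def downsample(x: np.ndarray, from_hz: float, to_hz: float = 100.0
               ) -> np.ndarray:
    """Integer-ratio decimation with internal anti-alias filtering.

    Output length is ``ceil(n * to_hz / from_hz)``.  Irregularly sampled
    traces go through :func:`interpolate_kinematics` instead.
    """
    ratio = from_hz / to_hz
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"from_hz ({from_hz}) must be an integer multiple of to_hz "
            f"({to_hz})")
    if q == 1:
        return np.asarray(x)
    return sps.decimate(np.asarray(x, dtype=float), q, ftype="fir",
                        zero_phase=True, axis=-1)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------
@dataclass
class TrialEpoch:
    """One 15-s trial, all modalities time-locked to the trial start."""

    condition: int
    repetition: int
    eeg: np.ndarray            # (61, duration * eeg_hz)
    emg: np.ndarray            # (8, duration * emg_hz)
    joints: np.ndarray         # (19, duration * 100) after interpolation
    accel: np.ndarray          # (3, duration * accel_hz)
    onset_sample: int | None = None   # 100-Hz samples after the execute cue
    onset_s: float | None = None      # seconds after trial start
    rejected: bool = False
    reason: str | None = None


def epoch_trials(recording: MultimodalRecording, duration_s: float = 15.0,
                 joints_hz: float = 100.0) -> list[TrialEpoch]:
    """Cut the session into per-trial epochs, reordered by condition.

    Trials whose streams do not cover the full window are kept but marked
    rejected with reason ``"incomplete"``.  Output order is ascending
    condition id, then repetition index (the common condition order).
    """
    proto = recording.protocol
    starts = [(e["time_s"], e["condition"], e["repetition"])
              for e in recording.events if e["label"] == "trial_start"]
    epochs = []
    for t0, cond, rep in starts:
        ep = TrialEpoch(condition=cond, repetition=rep, eeg=None, emg=None,
                        joints=None, accel=None)
        complete = True
        for attr, stream, fs in (
                ("eeg", recording.eeg, recording.eeg_hz),
                ("emg", recording.emg, proto.emg_hz),
                ("accel", recording.accel, proto.accel_hz)):
            i0 = int(round(t0 * fs))
            n = int(round(duration_s * fs))
            seg = stream[:, i0:i0 + n]
            if seg.shape[1] < n:
                complete = False
            setattr(ep, attr, seg)
        mask = (recording.joint_t >= t0) & (recording.joint_t < t0 + duration_s)
        if mask.sum() >= 4:
            ep.joints = interpolate_kinematics(
                recording.joint_t[mask], recording.joints[:, mask],
                target_hz=joints_hz, t_start=t0, duration_s=duration_s)[1]
        else:
            complete = False
        if not complete:
            ep.rejected, ep.reason = True, "incomplete"
        epochs.append(ep)
    epochs.sort(key=lambda e: (e.condition, e.repetition))
    return epochs


# ---------------------------------------------------------------------------
# movement onset (piecewise-linear change point)
# ---------------------------------------------------------------------------
def _linear_sse_prefix(y: np.ndarray):
    """Closed-form SSE of a mean+slope fit on [i, j), via prefix sums."""
    n = y.size
    t = np.arange(n, dtype=float)
    pad = lambda a: np.concatenate([[0.0], np.cumsum(a)])
    S1, St, Stt = pad(np.ones(n)), pad(t), pad(t * t)
    Sy, Sty, Syy = pad(y), pad(t * y), pad(y * y)

    def sse(i, j):
        i, j = np.asarray(i), np.asarray(j)
        nw = S1[j] - S1[i]
        st, stt = St[j] - St[i], Stt[j] - Stt[i]
        sy, sty, syy = Sy[j] - Sy[i], Sty[j] - Sty[i], Syy[j] - Syy[i]
        stt_c = stt - st * st / nw
        sty_c = sty - st * sy / nw
        syy_c = syy - sy * sy / nw
        with np.errstate(divide="ignore", invalid="ignore"):
            fit = np.where(stt_c > 1e-12, sty_c ** 2 / np.where(
                stt_c > 1e-12, stt_c, 1.0), 0.0)
        return np.maximum(syy_c - fit, 0.0)

    return sse


def detect_changepoint_linear(y: np.ndarray, min_seg: int = 5,
                              min_improvement: float = 0.1,
                              abs_tol: float = 1e-10) -> int | None:
    """First abrupt change of mean and slope of a 1-D signal.

    Over every admissible split point ``tau``, fit independent mean+slope
    segments before and after and return the ``tau`` minimizing the total
    squared residual -- provided the relative improvement over the single
    unsplit fit exceeds ``min_improvement``; otherwise ``None`` (no change).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 2 * min_seg:
        raise ValueError(
            f"window of {n} samples is shorter than two minimum segments "
            f"({2 * min_seg})")
    sse = _linear_sse_prefix(y)
    taus = np.arange(min_seg, n - min_seg + 1)
    total = sse(np.zeros_like(taus), taus) + sse(taus, np.full_like(taus, n))
    sse0 = float(sse(0, n))
    # first split within floating-point slack of the minimum (ties happen
    # when the change point lies on both segment lines)
    tol = 1e-9 * (1.0 + sse0)
    best = int(np.flatnonzero(total <= total.min() + tol)[0])
    if sse0 <= abs_tol * max(1.0, float(np.dot(y, y))):
        return None
    if (sse0 - float(total[best])) / sse0 < min_improvement:
        return None
    return int(taus[best])


def detect_movement_onset(accel_trial: np.ndarray, fs: float,
                          cue_s: float, search_s: float = 1.0,
                          min_seg: int = 5,
                          min_improvement: float = 0.1) -> int | None:
    """Movement onset inside the first second after the execute cue.

    The three accelerometer axes are combined into a Euclidean magnitude
    and the change point is found on that magnitude.  Returns the onset as
    a sample index relative to the trial start (at the accelerometer rate),
    or ``None`` when no abrupt change is present.
    """
    a = np.atleast_2d(np.asarray(accel_trial, dtype=float))
    i0 = int(round(cue_s * fs))
    i1 = min(int(round((cue_s + search_s) * fs)), a.shape[1])
    if i1 <= i0:
        raise ValueError("search window lies outside the trial")
    mag = np.linalg.norm(a[:, i0:i1], axis=0)
    tau = detect_changepoint_linear(mag, min_seg=min_seg,
                                    min_improvement=min_improvement)
    return None if tau is None else i0 + tau


# ---------------------------------------------------------------------------
# trial rejection
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class RejectionRules:
    """Thresholds for behavioral trial rejection.

    ``observation_sd``: reject when the observation-phase accelerometer
    magnitude deviates from the fixation baseline by more than this many
    baseline standard deviations (task executed incorrectly).
    ``joint_jump_rad``: reject when any single-step joint-angle jump exceeds
    this (hand tracked incorrectly, e.g. swapped fingers).
    """

    observation_sd: float = 5.0
    joint_jump_rad: float = float(np.deg2rad(60.0))
    min_baseline_sd: float = 1e-6
    # genuine movement bursts are sustained, sensor noise is not: the
    # magnitude is smoothed and the threshold must be exceeded continuously
    # for min_duration_s
    smooth_s: float = 0.1
    min_duration_s: float = 0.2


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def reject_trials(epochs: list[TrialEpoch], rules: RejectionRules,
                  protocol) -> tuple[list[TrialEpoch], list[dict]]:
    """Apply the rejection rules; returns kept epochs and a report.

    The report lists every rejected trial with its reason.  If all trials
    of some condition are rejected, that condition is flagged unusable in
    the report (entry with reason ``"condition_unusable"``).
    """
    fix0, fix1 = 0.0, protocol.phase_onsets_s[1]
    obs0, obs1 = protocol.phase_onsets_s[1], protocol.phase_onsets_s[2]
    fs_a = protocol.accel_hz
    report, kept = [], []
    for i, ep in enumerate(epochs):
        if ep.rejected:
            report.append({"trial": i, "condition": ep.condition,
                           "repetition": ep.repetition, "reason": ep.reason})
            continue
        mag = np.linalg.norm(ep.accel, axis=0)
        k = max(1, int(round(rules.smooth_s * fs_a)))
        mag = np.convolve(mag, np.ones(k) / k, mode="same")
        base = mag[int(fix0 * fs_a):int(fix1 * fs_a)]
        obs = mag[int(obs0 * fs_a):int(obs1 * fs_a)]
        sd = max(base.std(), rules.min_baseline_sd)
        above = np.abs(obs - base.mean()) > rules.observation_sd * sd
        if _longest_run(above) >= max(1, int(round(rules.min_duration_s
                                                   * fs_a))):
            ep.rejected, ep.reason = True, "execution"
        else:
            step = np.abs(wrap_angle(np.diff(ep.joints, axis=-1)))
            if step.max() > rules.joint_jump_rad:
                ep.rejected, ep.reason = True, "tracking"
        if ep.rejected:
            report.append({"trial": i, "condition": ep.condition,
                           "repetition": ep.repetition, "reason": ep.reason})
        else:
            kept.append(ep)
    surviving = {ep.condition for ep in kept}
    for cond in sorted({ep.condition for ep in epochs} - surviving):
        report.append({"trial": None, "condition": cond, "repetition": None,
                       "reason": "condition_unusable"})
    return kept, report


# ---------------------------------------------------------------------------
# Morlet time-frequency power
# ---------------------------------------------------------------------------
def default_cycles(freqs: np.ndarray = FREQ_GRID, lo: float = 3.0,
                   hi: float = 8.0) -> np.ndarray:
    """Wavelet width: linearly increasing ``lo`` -> ``hi`` cycles across
    the grid (default 3 -> 8)."""
    f = np.asarray(freqs, dtype=float)
    if f.size == 1:
        return np.array([lo])
    return lo + (hi - lo) * (f - f[0]) / (f[-1] - f[0])


def morlet_wavelet(freq: float, n_cycles: float, fs: float,
                   trunc_sd: float = 3.5) -> np.ndarray:
    """Complex Morlet wavelet, unit L2 norm, Gaussian truncated at
    ``trunc_sd`` standard deviations."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(trunc_sd * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    return (w / np.linalg.norm(w)).astype(np.complex64)


def _batched_wavelet_power(x: np.ndarray, fs: float, freqs: np.ndarray,
                           cycles: np.ndarray, trunc_sd: float = 3.5):
    """Yield ``(freq_index, power)`` for a batch of signals.

    ``x`` is (batch, T); power is (batch, T), float32, aligned with the
    input ('same' convolution).  Frequencies are processed grouped by FFT
    size so each forward transform is reused.
    """
    x = np.ascontiguousarray(x, dtype=np.float32)
    L = x.shape[-1]
    ws = [morlet_wavelet(f, c, fs, trunc_sd) for f, c in zip(freqs, cycles)]
    sizes = [sfft.next_fast_len(L + len(w) - 1) for w in ws]
    order = np.argsort(sizes, kind="stable")
    xc = x.astype(np.complex64)
    current_n, X = None, None
    for fi in order:
        n = sizes[fi]
        if n != current_n:
            X = sfft.fft(xc, n, axis=-1)
            current_n = n
        w = ws[fi]
        W = sfft.fft(w, n)
        y = sfft.ifft(X * W[None, :], axis=-1)
        off = (len(w) - 1) // 2
        seg = y[:, off:off + L]
        yield int(fi), (np.abs(seg) ** 2).astype(np.float32)


def morlet_tfr(epoch: np.ndarray, fs: float,
               freqs: np.ndarray = FREQ_GRID,
               cycles: np.ndarray | None = None,
               trunc_sd: float = 3.5):
    """Morlet wavelet power of a (channels x time) epoch.

    Returns ``(power, valid)`` where power is (channels, n_freqs, time) and
    ``valid`` flags frequency bins whose wavelet fits inside the epoch;
    longer-wavelet bins are computed but marked invalid rather than
    silently zero-padded.
    """
    epoch = np.atleast_2d(epoch)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if cycles is None:
        cycles = default_cycles(freqs)
    cycles = np.broadcast_to(np.asarray(cycles, dtype=float), freqs.shape)
    n_ch, T = epoch.shape
    power = np.empty((n_ch, freqs.size, T), dtype=np.float32)
    valid = np.empty(freqs.size, dtype=bool)
    for fi, p in _batched_wavelet_power(epoch, fs, freqs, cycles, trunc_sd):
        power[:, fi, :] = p
        wlen = 2 * int(np.ceil(trunc_sd * cycles[fi]
                               / (2 * np.pi * freqs[fi]) * fs)) + 1
        valid[fi] = wlen <= T
    return power, valid


def trial_power_features(eeg_epochs: np.ndarray, fs: float,
                         exec_starts: np.ndarray, n_exec: int,
                         freqs: np.ndarray = FREQ_GRID,
                         cycles: np.ndarray | None = None,
                         baseline_window_s=BASELINE_WINDOW_S,
                         trunc_sd: float = 3.5):
    """Baseline and execution-window Morlet power for a stack of epochs.

    ``eeg_epochs`` is (n_trials, channels, T); ``exec_starts`` gives, per
    trial, the first 100-Hz sample (relative to trial start) of the
    movement-execution segment.  Returns ``(baseline, exec_power)`` with
    shapes (n_trials, ch, n_freqs) and (n_trials, ch, n_freqs, n_exec);
    baseline is the mean power over the fixation interval.
    """
    n_tr, n_ch, T = eeg_epochs.shape
    freqs = np.asarray(freqs, dtype=float)
    if cycles is None:
        cycles = default_cycles(freqs)
    cycles = np.broadcast_to(np.asarray(cycles, dtype=float), freqs.shape)
    b0, b1 = (int(round(s * fs)) for s in baseline_window_s)
    idx = np.asarray(exec_starts)[:, None] + np.arange(n_exec)[None, :]
    if idx.max() >= T:
        raise ValueError("execution window exceeds the epoch")
    baseline = np.empty((n_tr, n_ch, freqs.size), dtype=np.float32)
    exec_power = np.empty((n_tr, n_ch, freqs.size, n_exec), dtype=np.float32)
    flat = eeg_epochs.reshape(n_tr * n_ch, T)
    for fi, p in _batched_wavelet_power(flat, fs, freqs, cycles, trunc_sd):
        p = p.reshape(n_tr, n_ch, T)
        baseline[:, :, fi] = p[:, :, b0:b1].mean(axis=-1)
        exec_power[:, :, fi, :] = np.take_along_axis(
            p, idx[:, None, :], axis=2)
    return baseline, exec_power


# ---------------------------------------------------------------------------
# ERD/S
# ---------------------------------------------------------------------------
@dataclass
class ERDSMap:
    """ERD/S as percent power change: channels x frequency bins x time."""

    values: np.ndarray
    baseline_power: np.ndarray      # (channels, n_freqs)
    freqs: np.ndarray = field(default_factory=lambda: FREQ_GRID.copy())
    channel_names: tuple[str, ...] = ()
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def compute_erds(power_movement: np.ndarray, baseline_power: np.ndarray,
                 **map_kwargs) -> ERDSMap:
    """ERD/S = (P_movement - P_baseline) / P_baseline * 100 %.

    ``baseline_power`` is the per-subject mean power over the fixation
    interval of all trials (channels x frequency bins); no clipping is
    applied, so values are bounded below by -100 %.
    """
    P = np.asarray(power_movement, dtype=float)
    B = np.asarray(baseline_power, dtype=float)
    bad = ~(B > 0)
    if bad.any():
        ch, fq = np.argwhere(bad)[0]
        raise ValueError(
            f"baseline power must be positive; offending (channel, bin) = "
            f"({ch}, {fq})")
    values = (P - B[..., None]) / B[..., None] * 100.0
    return ERDSMap(values=values, baseline_power=B, **map_kwargs)


# ---------------------------------------------------------------------------
# EMG envelope
# ---------------------------------------------------------------------------
def emg_envelope(emg_trial: np.ndarray) -> np.ndarray:
    """Per-channel z-score followed by the analytic-signal magnitude.

    The phrase order standardize -> Hilbert magnitude is recorded in the
    output contract: the result is the envelope of the standardized signal
    and is everywhere non-negative.
    """
    x = np.atleast_2d(np.asarray(emg_trial, dtype=float))
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd < 1e-12):
        ch = int(np.flatnonzero(sd.ravel() < 1e-12)[0])
        raise ValueError(f"EMG channel {ch} has (near-)zero variance")
    z = (x - x.mean(axis=-1, keepdims=True)) / sd
    return np.abs(sps.hilbert(z, axis=-1))


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------
def interpolate_kinematics(timestamps: np.ndarray, values: np.ndarray,
                           target_hz: float = 100.0,
                           t_start: float | None = None,
                           duration_s: float | None = None):
    """Cubic-spline resampling of irregular angle traces to a fixed rate.

    Angles are unwrapped along time before splining and re-wrapped to
    (-pi, pi] afterwards.  Returns ``(grid_times, values_on_grid)``.
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if t.size < 4:
        raise ValueError("need at least 4 samples per trace")
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps")
    if np.any(dt < 0):
        raise ValueError("timestamps must be strictly increasing")
    t0 = t[0] if t_start is None else float(t_start)
    dur = (t[-1] - t0) if duration_s is None else float(duration_s)
    grid = t0 + np.arange(int(round(dur * target_hz))) / target_hz
    spline = CubicSpline(t, np.unwrap(v, axis=-1), axis=-1, extrapolate=True)
    return grid, wrap_angle(spline(grid))


def circular_mean(angles: np.ndarray, axis=None, tol: float = 1e-9
                  ) -> np.ndarray | float:
    """Mean direction of angles in radians, result in (-pi, pi].

    Raises when the resultant vector length is below ``tol`` (near-uniform
    angles have no defined mean direction).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle set")
    C = np.cos(a).mean(axis=axis)
    S = np.sin(a).mean(axis=axis)
    R = np.hypot(C, S)
    if np.any(R < tol):
        raise ValueError("circular mean undefined: resultant length "
                         f"below {tol}")
    ang = np.arctan2(S, C)
    ang = np.where(ang <= -np.pi, np.pi, ang)
    return float(ang) if np.isscalar(R) or ang.ndim == 0 else ang


@dataclass
class KinematicPCA:
    """Subject-level kinematic synergies (principal components)."""

    components: np.ndarray          # (k, 19) loadings
    scores: np.ndarray              # (k, T) component trajectories
    variance_fractions: np.ndarray  # (k,)
    mean: np.ndarray                # (19,)

    def project(self, joints: np.ndarray) -> np.ndarray:
        return self.components @ (np.asarray(joints) - self.mean[:, None])


def kinematic_pca(joints: np.ndarray, n_components: int = 5) -> KinematicPCA:
    """PCA of (19 x time) joint angles; retains ``n_components`` synergies.

    If fewer nonzero-variance directions exist, all available components
    are returned with a warning.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(joints, dtype=float)
    if X.ndim != 2:
        raise ValueError("joints must be (traces, time)")
    if X.shape[1] <= X.shape[0]:
        raise ValueError("need more time samples than traces")
    var = X.var(axis=1)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=1, keepdims=True)))
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"only {k} nonzero-variance directions available "
            f"(requested {n_components})")
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X.T).T
    return KinematicPCA(components=pca.components_, scores=scores,
                        variance_fractions=pca.explained_variance_ratio_,
                        mean=pca.mean_)


def align_components(reference: np.ndarray, components: np.ndarray):
    """Match components to a reference basis by greedy maximal |cosine|.

    Subject-specific PCA bases are only defined up to order and sign; this
    returns ``(perm, signs)`` such that ``components[perm] * signs[:, None]``
    is commensurable with ``reference`` for cross-subject averaging.
    """
    ref = np.asarray(reference, dtype=float)
    comp = np.asarray(components, dtype=float)
    sim = (ref / np.linalg.norm(ref, axis=1, keepdims=True)) @ \
        (comp / np.linalg.norm(comp, axis=1, keepdims=True)).T
    k = min(sim.shape)
    perm = np.full(ref.shape[0], -1, dtype=int)
    signs = np.ones(ref.shape[0])
    free_r, free_c = set(range(sim.shape[0])), set(range(sim.shape[1]))
    for _ in range(k):
        best = max(((abs(sim[r, c]), r, c) for r in free_r for c in free_c))
        _, r, c = best
        perm[r], signs[r] = c, np.sign(sim[r, c]) or 1.0
        free_r.discard(r)
        free_c.discard(c)
    return perm, signs


# ---------------------------------------------------------------------------
# condition averaging
# ---------------------------------------------------------------------------
def average_condition_patterns(subject_patterns, circular: bool = False):
    """Group-level pattern per condition.

    ``subject_patterns`` is a sequence (one entry per subject) of mappings
    ``condition_id -> (n_repetitions, n_features)`` containing the surviving
    repetitions.  Repetitions are averaged within subject first, then the
    subject means are averaged; a subject with zero surviving repetitions
    of a condition is excluded from that condition's group mean and logged.
    The circular mean is used in both steps when ``circular=True`` (raw
    joint angles).

    Returns ``(conditions, group, log)`` with ``group`` shaped
    (n_conditions, n_features).
    """
    conditions = sorted({c for subj in subject_patterns for c in subj})
    mean = (lambda a: circular_mean(a, axis=0)) if circular \
        else (lambda a: np.asarray(a).mean(axis=0))
    group, log = [], []
    for cond in conditions:
        subj_means = []
        for si, subj in enumerate(subject_patterns):
            reps = subj.get(cond)
            if reps is None or len(reps) == 0:
                log.append({"condition": cond, "subject": si,
                            "note": "no surviving repetitions; excluded"})
                continue
            subj_means.append(mean(np.asarray(reps)))
        if not subj_means:
            raise ValueError(f"condition {cond} has no surviving data in "
                             "any subject")
        group.append(mean(np.asarray(subj_means)))
    return conditions, np.asarray(group), log
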