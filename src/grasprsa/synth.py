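"""Synthetic multimodal grasping sessions.

Generates EEG (61 ch + 3 EOG), 8-channel EMG, 19 joint-angle traces at a
variable 80-120 Hz rate and a 3-axis accelerometer for a block-randomized
33-condition protocol, with

* a condition-similarity effect planted in one searchlight cell: during
  movement execution, oscillatory power in the target channel/frequency
  neighborhood is suppressed (an ERD) by a condition-specific depth whose
  between-condition structure follows a supplied model RDM;
* synergy-driven EMG envelopes and joint angles whose condition similarity
  follows the supplied activation/score vectors;
* an abrupt mean-and-slope change of the accelerometer at each movement
  onset, with ground truth returned for validation;
* injectable bad trials (movement during observation, tracking glitches)
  for exercising trial rejection.

Everything is deterministic given the seeds carried by the specs.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from .protocol import EffectSpec, ProtocolSpec, Taxonomy, default_taxonomy
from .searchlight import SearchlightLayout, default_layout, CHANNELS_61

EOG_CHANNELS = ("EOG-left", "EOG-right", "EOG-above")
EMG_CHANNELS = tuple(f"M{i + 1}" for i in range(8))
N_JOINTS = 19

#: default movement-onset latency after the execute cue, in seconds
ONSET_LATENCY_S = 0.3


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------
@dataclass
class MultimodalRecording:
    """One subject's synchronized raw streams plus event markers."""

    protocol: ProtocolSpec
    eeg: np.ndarray            # (61, T_eeg)
    eog: np.ndarray            # (3, T_eeg)
    emg: np.ndarray            # (8, T_emg)
    joint_t: np.ndarray        # (n_samples,) strictly increasing timestamps [s]
    joints: np.ndarray         # (19, n_samples), radians in (-pi, pi]
    accel: np.ndarray          # (3, T_accel)
    events: list[dict]
    eeg_channels: tuple[str, ...] = CHANNELS_61
    truth: dict = field(default_factory=dict)

    @property
    def eeg_hz(self) -> float:
        return self.protocol.eeg_hz

    def copy(self) -> "MultimodalRecording":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------
def wrap_angle(x: np.ndarray) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    return np.pi - (np.pi - np.asarray(x)) % (2 * np.pi)


def draw_onset_latencies(protocol: ProtocolSpec, jitter_sd: float,
                         seed: int, latency_s: float = ONSET_LATENCY_S):
    """Movement-onset latency after the execute cue for every trial.

    Latencies are ``latency_s`` plus Gaussian jitter, clipped into
    (0.02 s, 0.98 s) so every onset falls within the first second of the
    execution phase; clipped trials are flagged.
    """
    if jitter_sd < 0:
        raise ValueError("onset_jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lat = latency_s + jitter_sd * rng.standard_normal(protocol.n_trials)
    clipped = (lat <= 0.02) | (lat >= 0.98)
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} onset(s) clipped into the "
                      "execution phase")
    return np.clip(lat, 0.02, 0.98), clipped


def model_embedding(model_rdm: np.ndarray, n_dims: int = 8) -> np.ndarray:
    """Low-dimensional condition coordinates whose Euclidean geometry
    approximates a dissimilarity matrix (classical scaling)."""
    D = np.asarray(model_rdm, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(G)
    keep = np.argsort(w)[::-1][: min(n_dims, n - 1)]
    w = np.clip(w[keep], 0.0, None)
    X = V[:, keep] * np.sqrt(w)
    scale = np.sqrt((X ** 2).sum(1).mean())
    return X / scale if scale > 0 else X


def _movement_profile(t: np.ndarray, onset_s: float, end_s: float,
                      ramp_s: float = 0.15) -> np.ndarray:
    """0 -> 1 envelope between onset and end with smooth cosine ramps."""
    up = np.clip((t - onset_s) / ramp_s, 0.0, 1.0)
    down = np.clip((end_s - t) / ramp_s, 0.0, 1.0)
    smooth = lambda u: 0.5 - 0.5 * np.cos(np.pi * u)
    return smooth(up) * smooth(down)


def _pink_noise(rng, shape, n_samples, fs):
    """1/f-amplitude-weighted Gaussian noise, unit standard deviation."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    weight = np.zeros_like(freqs)
    weight[1:] = freqs[1:] ** -0.5
    spec = rng.standard_normal(shape + (freqs.size,)) \
        + 1j * rng.standard_normal(shape + (freqs.size,))
    x = np.fft.irfft(spec * weight, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------
def condition_erd_depths(effect: EffectSpec, n_conditions: int,
                         taxonomy: Taxonomy | None = None) -> np.ndarray:
    """Per-(condition, member channel, member bin) ERD depth in [0.05, 0.95].

    Depths are ``erd_depth`` plus an effect-size-scaled projection of the
    model-RDM embedding, so that between-condition differences in ERD follow
    the model's similarity structure.  At ``effect_size = 0`` the depth is
    identical for all conditions.
    """
    from .rsa import categorical_rdm  # local import to avoid a cycle

    if effect.model_rdm is not None:
        D = np.asarray(effect.model_rdm, dtype=float)
    else:
        tax = taxonomy if taxonomy is not None else default_taxonomy(n_conditions)
        D = categorical_rdm(tax, "object_shape").matrix
    if D.shape != (n_conditions, n_conditions):
        raise ValueError(
            f"model RDM is {D.shape}, expected ({n_conditions}, {n_conditions})")
    X = model_embedding(D)                              # (n_cond, q)
    rng = np.random.default_rng(effect.seed)
    W = rng.standard_normal((X.shape[1], 5, 5))         # per (channel, bin)
    Z = np.einsum("cq,qmb->cmb", X, W)
    sd = Z.std()
    if sd > 0:
        Z = Z / sd
    depths = effect.erd_depth + 0.12 * effect.effect_size * Z
    return np.clip(depths, 0.05, 0.95)


def synthesize_eeg(protocol: ProtocolSpec, effect: EffectSpec,
                   layout: SearchlightLayout,
                   taxonomy: Taxonomy | None = None,
                   seed: int | None = None,
                   onset_latencies_s: np.ndarray | None = None):
    """EEG + EOG streams with a planted searchlight ERD effect.

    Background activity is 1/f-weighted noise plus ongoing 10-Hz and 22-Hz
    oscillations with random phase on every channel (condition independent).
    On the five channels of the target channel neighborhood, five additional
    oscillators at the target frequency-neighborhood bin centers are
    suppressed during movement execution by condition-specific depths from
    :func:`condition_erd_depths`.

    Returns ``(eeg, eog, info)`` where ``info`` holds the planted depths and
    the onset latencies used.
    """
    n_ch_nb = layout.n_channel_nbs
    n_fq_nb = layout.n_frequency_nbs
    if not 0 <= effect.target_channel_nb < n_ch_nb:
        raise ValueError(f"unknown channel neighborhood {effect.target_channel_nb}")
    if not 0 <= effect.target_frequency_nb < n_fq_nb:
        raise ValueError(f"unknown frequency neighborhood {effect.target_frequency_nb}")

    seed = effect.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    fs = protocol.eeg_hz
    n_trial = int(round(protocol.trial_duration_s * fs))
    n_total = protocol.n_trials * n_trial
    n_ch = len(CHANNELS_61)

    if onset_latencies_s is None:
        onset_latencies_s, _ = draw_onset_latencies(protocol, 0.05, seed + 1)

    depths = condition_erd_depths(effect, protocol.n_conditions, taxonomy)

    target_chs = layout.channel_neighborhoods[effect.target_channel_nb]
    ch_index = {ch: i for i, ch in enumerate(CHANNELS_61)}
    target_idx = [ch_index[ch] for ch in target_chs]
    target_freqs = layout.freqs[list(
        layout.frequency_neighborhoods[effect.target_frequency_nb])]

    eeg = np.empty((n_ch, n_total), dtype=np.float32)
    t_trial = np.arange(n_trial) / fs
    exec_cue = protocol.execute_cue_s
    relax_start = protocol.phase_onsets_s[3]

    # on the target channels, rhythms inside the planted band are the
    # condition-modulated oscillators themselves; the generic background
    # rhythm is only added there when spectrally distant
    bg_rhythms = ((10.0, 0.8), (30.0, 0.5))
    lo_t, hi_t = target_freqs.min() - 3.0, target_freqs.max() + 3.0

    for tr, (cond, _rep) in enumerate(protocol.trial_sequence()):
        x = effect.noise_sd * _pink_noise(rng, (n_ch,), n_trial, fs)
        # ongoing condition-independent alpha/beta rhythms
        for f0, amp in bg_rhythms:
            phases = rng.uniform(0, 2 * np.pi, n_ch)[:, None]
            osc = amp * np.sin(2 * np.pi * f0 * t_trial[None, :] + phases)
            if lo_t <= f0 <= hi_t:
                osc[target_idx] = 0.0
            x += osc
        # planted, condition-modulated oscillators in the target cell
        onset = exec_cue + onset_latencies_s[tr]
        g = _movement_profile(t_trial, onset, relax_start)      # (n_trial,)
        phases = rng.uniform(0, 2 * np.pi, (5, 5))
        carrier = np.sin(2 * np.pi * target_freqs[None, :, None] * t_trial
                         + phases[..., None])                   # (5, 5, T)
        # rhythm energy peaks at the band center so the apparent spectral
        # center of the effect coincides with the planted neighborhood
        band_w = np.array([0.6, 0.85, 1.0, 0.85, 0.6])
        amp = effect.osc_amplitude * band_w[None, :, None] * (
            1.0 - depths[cond - 1][:, :, None] * g[None, None, :])
        x[target_idx] += (amp * carrier).sum(axis=1)
        eeg[:, tr * n_trial:(tr + 1) * n_trial] = x

    eog = 0.3 * rng.standard_normal((3, n_total)).astype(np.float32)
    info = {"erd_depths": depths, "onset_latencies_s": onset_latencies_s,
            "target_cell": (effect.target_channel_nb, effect.target_frequency_nb)}
    return eeg, eog, info


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class EMGSpec:
    """Synergy mixing matrix and per-condition activation vectors."""

    weights: np.ndarray        # (8, S)
    activations: np.ndarray    # (n_conditions, S), non-negative
    noise_sd: float = 0.05
    rest_amp: float = 0.2


def make_default_emg_spec(n_conditions: int, seed: int,
                          n_synergies: int = 3,
                          noise_sd: float = 0.05) -> EMGSpec:
    rng = np.random.default_rng(seed)
    w = np.abs(rng.standard_normal((8, n_synergies)))
    w /= np.linalg.norm(w, axis=0, keepdims=True)
    acts = np.abs(rng.standard_normal((n_conditions, n_synergies)))
    return EMGSpec(weights=w, activations=acts, noise_sd=noise_sd)


def synthesize_emg(protocol: ProtocolSpec, synergy_weights: np.ndarray,
                   condition_activations: np.ndarray, noise_sd: float,
                   seed: int,
                   onset_latencies_s: np.ndarray | None = None,
                   rest_amp: float = 0.2) -> np.ndarray:
    """Amplitude-modulated broadband EMG.

    During execution the per-channel envelope is
    ``rest_amp + (weights @ activations[condition]) * profile(t)``; during
    the other phases it stays at the rest amplitude.  The envelope modulates
    a white-noise carrier, so a Hilbert envelope recovers it.
    """
    W = np.asarray(synergy_weights, dtype=float)
    A = np.asarray(condition_activations, dtype=float)
    if W.ndim != 2 or W.shape[0] != len(EMG_CHANNELS):
        raise ValueError(f"synergy_weights must be (8, S), got {W.shape}")
    if A.ndim != 2 or A.shape != (protocol.n_conditions, W.shape[1]):
        raise ValueError(
            f"condition_activations must be ({protocol.n_conditions}, "
            f"{W.shape[1]}), got {A.shape}")
    if (A < 0).any():
        raise ValueError("condition activations must be non-negative")

    rng = np.random.default_rng(seed)
    fs = protocol.emg_hz
    n_trial = int(round(protocol.trial_duration_s * fs))
    if onset_latencies_s is None:
        onset_latencies_s, _ = draw_onset_latencies(protocol, 0.05, seed + 1)

    t_trial = np.arange(n_trial) / fs
    exec_cue = protocol.execute_cue_s
    relax_start = protocol.phase_onsets_s[3]
    out = np.empty((len(EMG_CHANNELS), protocol.n_trials * n_trial),
                   dtype=np.float32)
    for tr, (cond, _rep) in enumerate(protocol.trial_sequence()):
        onset = exec_cue + onset_latencies_s[tr]
        prof = _movement_profile(t_trial, onset, relax_start, ramp_s=0.2)
        amp = rest_amp + np.outer(W @ A[cond - 1], prof)
        carrier = rng.standard_normal((len(EMG_CHANNELS), n_trial))
        x = amp * carrier + noise_sd * rng.standard_normal(amp.shape)
        out[:, tr * n_trial:(tr + 1) * n_trial] = x
    return out


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class KinematicsSpec:
    """Synergy basis and per-condition scores for the 19 joint angles."""

    basis: np.ndarray          # (19, 5), full column rank
    scores: np.ndarray         # (n_conditions, 5)
    noise_sd: float = 0.02
    rest_posture: np.ndarray | None = None


def make_default_kinematics_spec(n_conditions: int, seed: int,
                                 n_synergies: int = 5,
                                 noise_sd: float = 0.02) -> KinematicsSpec:
    rng = np.random.default_rng(seed)
    basis = rng.standard_normal((N_JOINTS, n_synergies))
    basis, _ = np.linalg.qr(basis)           # orthonormal, full column rank
    scores = 0.8 * rng.standard_normal((n_conditions, n_synergies))
    rest = 0.2 * rng.standard_normal(N_JOINTS)
    return KinematicsSpec(basis=basis, scores=scores, noise_sd=noise_sd,
                          rest_posture=rest)


def synthesize_kinematics(protocol: ProtocolSpec, synergy_basis: np.ndarray,
                          condition_scores: np.ndarray, noise_sd: float,
                          seed: int,
                          onset_latencies_s: np.ndarray | None = None,
                          rest_posture: np.ndarray | None = None):
    """Joint-angle traces at a variable 80-120 Hz sampling rate.

    ``joints(t) = rest + basis @ (scores[condition] * profile(t)) + noise``,
    wrapped to (-pi, pi].  Sample spacing is drawn uniformly from
    [1/120 s, 1/80 s], so the instantaneous rate stays within 80-120 Hz.

    Returns ``(timestamps, values)`` with values shaped (19, n_samples).
    """
    B = np.asarray(synergy_basis, dtype=float)
    S = np.asarray(condition_scores, dtype=float)
    if B.ndim != 2 or B.shape[0] != N_JOINTS:
        raise ValueError(f"synergy basis must be (19, S), got {B.shape}")
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise ValueError("synergy basis is rank deficient")
    if S.shape != (protocol.n_conditions, B.shape[1]):
        raise ValueError(
            f"condition_scores must be ({protocol.n_conditions}, "
            f"{B.shape[1]}), got {S.shape}")

    rng = np.random.default_rng(seed)
    lo, hi = protocol.joint_hz_range
    total = protocol.session_duration_s
    n_est = int(total * hi) + 10
    dt = rng.uniform(1.0 / hi, 1.0 / lo, n_est)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    t = t[t < total]

    if onset_latencies_s is None:
        onset_latencies_s, _ = draw_onset_latencies(protocol, 0.05, seed + 1)
    rest = np.zeros(N_JOINTS) if rest_posture is None else np.asarray(rest_posture)

    trial_dur = protocol.trial_duration_s
    trial_idx = np.minimum((t / trial_dur).astype(int), protocol.n_trials - 1)
    t_in_trial = t - trial_idx * trial_dur
    conds = np.asarray([c for c, _ in protocol.trial_sequence()])
    exec_cue = protocol.execute_cue_s
    relax_start = protocol.phase_onsets_s[3]

    onset = exec_cue + onset_latencies_s[trial_idx]   # per-sample trial onset
    prof = _movement_profile(t_in_trial, onset, relax_start)
    scores_t = S[conds[trial_idx] - 1] * prof[:, None]     # (n, S)
    values = rest[:, None] + B @ scores_t.T
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(values.shape)
    return t, wrap_angle(values)


# ---------------------------------------------------------------------------
# accelerometer
# ---------------------------------------------------------------------------
#: direction of the movement acceleration across the three axes
_ACCEL_AXES = np.array([1.0, 0.3, -0.2])


def synthesize_accelerometer(protocol: ProtocolSpec, onset_jitter_sd: float,
                             seed: int,
                             onset_latencies_s: np.ndarray | None = None,
                             noise_sd: float = 0.02,
                             step: float = 0.5, slope: float = 1.0):
    """Quiescent accelerometer with an abrupt mean-and-slope change at onset.

    From the movement onset until the end of the execution phase the signal
    follows ``step + slope * (t - onset)`` along a fixed axis direction (so
    the change is exactly piecewise linear within the one-second detection
    window), then decays during relaxation.  Returns ``(accel, truth)``
    where ``truth`` is a per-trial table of the ground-truth onsets.
    """
    rng = np.random.default_rng(seed)
    fs = protocol.accel_hz
    n_trial = int(round(protocol.trial_duration_s * fs))
    clipped = np.zeros(protocol.n_trials, dtype=bool)
    if onset_latencies_s is None:
        onset_latencies_s, clipped = draw_onset_latencies(
            protocol, onset_jitter_sd, seed + 1)

    t_trial = np.arange(n_trial) / fs
    exec_cue = protocol.execute_cue_s
    exec_end = protocol.phase_onsets_s[3]
    accel = noise_sd * rng.standard_normal(
        (3, protocol.n_trials * n_trial)).astype(np.float32)
    rows = []
    for tr in range(protocol.n_trials):
        onset_s = exec_cue + onset_latencies_s[tr]
        # first sample at/after the onset time (where the change begins)
        onset_sample = int(np.ceil(onset_s * fs - 1e-9))
        mag = np.zeros(n_trial)
        moving = (t_trial >= onset_latencies_s[tr] + exec_cue) & (t_trial < exec_end)
        mag[moving] = step + slope * (t_trial[moving] - onset_s)
        relax = (t_trial >= exec_end) & (t_trial < exec_end + 0.5)
        peak = step + slope * (exec_end - onset_s)
        mag[relax] = peak * (1.0 - (t_trial[relax] - exec_end) / 0.5)
        accel[:, tr * n_trial:(tr + 1) * n_trial] += np.outer(_ACCEL_AXES, mag)
        rows.append({"trial": tr,
                     "onset_s": tr * protocol.trial_duration_s + onset_s,
                     "onset_latency_s": float(onset_latencies_s[tr]),
                     "onset_sample": tr * n_trial + onset_sample,
                     "clipped": bool(clipped[tr])})
    return accel, rows


# ---------------------------------------------------------------------------
# bad trials
# ---------------------------------------------------------------------------
ARTIFACT_KINDS = ("movement_during_observation", "tracking_glitch")


def inject_artifact_trials(recording: MultimodalRecording,
                           bad_trial_spec, seed: int = 0
                           ) -> MultimodalRecording:
    """Return a copy of the recording with bad trials injected.

    ``movement_during_observation`` adds an accelerometer + EMG burst inside
    the observation phase; ``tracking_glitch`` injects a joint-angle
    discontinuity larger than the rejection threshold.  An empty spec
    returns the recording unchanged (bitwise); duplicated trial ids are
    collapsed with a warning.
    """
    if not bad_trial_spec:
        return recording
    rec = recording.copy()
    proto = rec.protocol
    seen = set()
    rng = np.random.default_rng(seed)
    for trial, kind in bad_trial_spec:
        if kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {kind!r}")
        if not 0 <= trial < proto.n_trials:
            raise ValueError(f"trial id {trial} outside 0..{proto.n_trials - 1}")
        if (trial, kind) in seen:
            warnings.warn(f"trial {trial} listed twice for {kind}; "
                          "injecting once")
            continue
        seen.add((trial, kind))
        t0 = proto.trial_start_s(trial)
        obs_mid = t0 + proto.phase_onsets_s[1] + 2.0
        if kind == "movement_during_observation":
            for stream, fs, scale in ((rec.accel, proto.accel_hz, 1.0),
                                      (rec.emg, proto.emg_hz, 2.0)):
                i0 = int(obs_mid * fs)
                n = int(0.5 * fs)
                burst = scale * (0.8 + 0.2 * rng.random())
                stream[:, i0:i0 + n] += burst
        else:  # tracking_glitch
            mask = (rec.joint_t >= obs_mid) & (rec.joint_t < obs_mid + 0.1)
            joint = int(rng.integers(0, N_JOINTS))
            rec.joints[joint, mask] = wrap_angle(
                rec.joints[joint, mask] + 2.5)
        rec.truth.setdefault("bad_trials", []).append(
            {"trial": int(trial), "kind": kind})
    return rec


# ---------------------------------------------------------------------------
# session / cohort orchestration
# ---------------------------------------------------------------------------
def simulate_session(protocol: ProtocolSpec, effect: EffectSpec,
                     taxonomy: Taxonomy | None = None,
                     layout: SearchlightLayout | None = None,
                     emg_spec: EMGSpec | None = None,
                     kin_spec: KinematicsSpec | None = None,
                     seed: int = 0,
                     onset_jitter_sd: float = 0.05) -> MultimodalRecording:
    """Generate one subject's full multimodal session."""
    layout = layout if layout is not None else default_layout()
    taxonomy = taxonomy if taxonomy is not None else default_taxonomy(
        protocol.n_conditions)
    if emg_spec is None:
        emg_spec = make_default_emg_spec(protocol.n_conditions, seed=9000)
    if kin_spec is None:
        kin_spec = make_default_kinematics_spec(protocol.n_conditions, seed=9001)

    latencies, clipped = draw_onset_latencies(protocol, onset_jitter_sd,
                                              seed * 7 + 1)
    eeg, eog, eeg_info = synthesize_eeg(
        protocol, effect, layout, taxonomy, seed=seed * 7 + 2,
        onset_latencies_s=latencies)
    emg = synthesize_emg(protocol, emg_spec.weights, emg_spec.activations,
                         emg_spec.noise_sd, seed * 7 + 3,
                         onset_latencies_s=latencies,
                         rest_amp=emg_spec.rest_amp)
    joint_t, joints = synthesize_kinematics(
        protocol, kin_spec.basis, kin_spec.scores, kin_spec.noise_sd,
        seed * 7 + 4, onset_latencies_s=latencies,
        rest_posture=kin_spec.rest_posture)
    accel, onset_truth = synthesize_accelerometer(
        protocol, onset_jitter_sd, seed * 7 + 5, onset_latencies_s=latencies)

    truth = {"onsets": onset_truth, "onset_latencies_s": latencies,
             "clipped_onsets": clipped, "seed": seed, **eeg_info}
    return MultimodalRecording(
        protocol=protocol, eeg=eeg, eog=eog, emg=emg,
        joint_t=joint_t, joints=joints, accel=accel,
        events=protocol.events(), truth=truth)


def simulate_cohort(n_subjects: int, protocol: ProtocolSpec,
                    effect: EffectSpec,
                    taxonomy: Taxonomy | None = None,
                    layout: SearchlightLayout | None = None,
                    seed: int = 0,
                    emg_noise_sd: float = 0.05,
                    kin_noise_sd: float = 0.02,
                    onset_jitter_sd: float = 0.05
                    ) -> list[MultimodalRecording]:
    """Generate a cohort sharing one population EMG/kinematic structure.

    The synergy weights, condition activations, kinematic basis and scores
    are drawn once from ``seed`` and shared across subjects, so group-level
    averaging recovers them; per-subject noise differs by subject seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    emg_spec = make_default_emg_spec(protocol.n_conditions, seed=seed * 131 + 11,
                                     noise_sd=emg_noise_sd)
    kin_spec = make_default_kinematics_spec(protocol.n_conditions,
                                            seed=seed * 131 + 12,
                                            noise_sd=kin_noise_sd)
    return [
        simulate_session(protocol, effect, taxonomy, layout,
                         emg_spec=emg_spec, kin_spec=kin_spec,
                         seed=seed * 131 + 1000 + s,
                         onset_jitter_sd=onset_jitter_sd)
        for s in range(n_subjects)
    ]


def make_population_patterns(model_rdm: np.ndarray, n_subjects: int,
                             n_features: int = 60, noise_sd: float = 0.5,
                             seed: int = 0):
    """Subject-level condition patterns around a known population structure.

    Used to calibrate the subject-level bootstrap: the population (infinite
    subject) pattern of condition ``c`` is a fixed linear image of the model
    embedding; each subject observes it plus Gaussian noise.

    Returns ``(patterns, population_mean)`` with shapes
    (n_subjects, n_conditions, n_features) and (n_conditions, n_features).
    """
    rng = np.random.default_rng(seed)
    X = model_embedding(np.asarray(model_rdm, dtype=float))
    P = rng.standard_normal((X.shape[1], n_features)) / np.sqrt(X.shape[1])
    mu = X @ P
    patterns = mu[None] + noise_sd * rng.standard_normal(
        (n_subjects,) + mu.shape)
    return patterns, mu
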