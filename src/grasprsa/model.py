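"""End-to-end pipeline: generation -> preprocessing -> searchlight -> RSA.

The user-facing surface follows the model/results idiom: a
:class:`GraspRSA` model is built from a :class:`PipelineConfig` (or from
already-simulated recordings), ``fit()`` executes all stages and returns a
:class:`GraspRSAResults` carrying the reference and candidate RDMs, the
searchlight RSA maps, subject-level bootstrap CIs, the second-level RDM and
a ``summary()`` table.  ``run_pipeline``/``summarize`` expose the same
functionality as plain functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from . import rsa as _rsa
from .protocol import EffectSpec, Taxonomy, default_taxonomy, generate_protocol
from .searchlight import SearchlightLayout, default_layout, extract_pattern
from .synth import MultimodalRecording, simulate_cohort

logger = logging.getLogger("grasprsa")

WINDOW_NAMES = ("pre-shaping [0, 0.5) s", "finalization [0.5, 1) s",
                "hold [1, 1.5) s")
N_WINDOWS = 3
WINDOW_LEN_S = 0.5
CANDIDATE_NAMES = ("emg", "kinematics", "categorical:grasp_type",
                   "categorical:thumb_position", "categorical:object_shape")


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable run configuration; hashed into every output."""

    n_subjects: int = 5
    n_conditions: int = 33
    n_repetitions: int = 8
    seed: int = 0
    # planted effect (left centro-parietal neighborhood, mu band)
    target_channel_nb: int = 3
    target_frequency_nb: int = 6
    effect_model: str = "object_shape"    # scheme name of the planted model
    effect_size: float = 1.0
    noise_sd: float = 2.0
    osc_amplitude: float = 1.2
    onset_jitter_sd: float = 0.05
    # preprocessing
    filter_band: tuple[float, float] = (0.1, 40.0)
    baseline_window_s: tuple[float, float] = pp.BASELINE_WINDOW_S
    observation_reject_sd: float = 5.0
    joint_jump_deg: float = 60.0
    cycles_range: tuple[float, float] = (3.0, 8.0)
    trunc_sd: float = 3.5
    # RSA
    n_boot: int = 500
    alpha: float = 0.05
    region: tuple[tuple[int, int], ...] | None = None
    n_kinematic_components: int = 5

    def effect_spec(self) -> EffectSpec:
        return EffectSpec(
            target_channel_nb=self.target_channel_nb,
            target_frequency_nb=self.target_frequency_nb,
            effect_size=self.effect_size, noise_sd=self.noise_sd,
            osc_amplitude=self.osc_amplitude,
            seed=self.seed * 977 + 13)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("filter_band", "baseline_window_s", "cycles_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("region") is not None:
            raw["region"] = tuple(tuple(c) for c in raw["region"])
        return cls(**raw)


@dataclass
class ResultBundle:
    """Everything one pipeline run produces."""

    config: PipelineConfig
    layout: SearchlightLayout
    taxonomy: Taxonomy
    reference_rdms: list[dict]          # per window: (ch_nb, fq_nb) -> RDM
    candidate_rdms: dict                # name -> list of RDM per window
    rsa_maps: dict                      # (window, candidate name) -> RSAMap
    bootstrap: dict                     # window -> (candidate, BootstrapResult)
    second_level: dict                  # window -> (matrix, labels)
    qc: pd.DataFrame
    region: tuple[tuple[int, int], ...]
    truth: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def best_candidate(self, window: int, region=None):
        """Candidate with the smallest region-mean distance in a window."""
        region = region if region is not None else self.region
        means = {name: self.rsa_maps[(window, name)].region_mean(region)
                 for name in CANDIDATE_NAMES}
        best = min(means, key=means.get)
        return best, means


# ---------------------------------------------------------------------------
# per-subject feature extraction
# ---------------------------------------------------------------------------
def _subject_features(rec: MultimodalRecording, config: PipelineConfig,
                      layout: SearchlightLayout):
    """Preprocess one subject: epochs, onsets, rejection, ERD/S, EMG and
    kinematic condition features."""
    proto = rec.protocol
    fs = 100.0
    eeg = rec.eeg
    if proto.eeg_hz != fs:
        eeg = pp.bandpass_filter(eeg, proto.eeg_hz, *config.filter_band)
        eeg = pp.downsample(eeg, proto.eeg_hz, fs)
        rec = replace_stream(rec, eeg)
    epochs = pp.epoch_trials(rec)
    if len(epochs) != proto.n_trials:
        raise RuntimeError(
            f"stage epoch: {len(epochs)} epochs from {proto.n_trials} trials")

    for ep in epochs:
        if ep.rejected:
            continue
        onset = pp.detect_movement_onset(ep.accel, proto.accel_hz,
                                         cue_s=proto.execute_cue_s)
        if onset is None:
            ep.rejected, ep.reason = True, "onset"
            continue
        ep.onset_s = onset / proto.accel_hz
        ep.onset_sample = int(round(
            (ep.onset_s - proto.execute_cue_s) * fs))

    rules = pp.RejectionRules(
        observation_sd=config.observation_reject_sd,
        joint_jump_rad=float(np.deg2rad(config.joint_jump_deg)))
    kept, report = pp.reject_trials(epochs, rules, proto)
    if len(kept) + sum(r["trial"] is not None for r in report) \
            != proto.n_trials:
        raise RuntimeError("stage reject: trial counts not conserved")
    if not kept:
        raise RuntimeError("stage reject: no trials survive")

    n_exec = int(N_WINDOWS * WINDOW_LEN_S * fs)          # 150 samples
    exec_starts = np.array(
        [int(round(ep.onset_s * fs)) for ep in kept])
    eeg_stack = np.stack([ep.eeg for ep in kept]).astype(np.float32)
    from .searchlight import FREQ_GRID
    cycles = pp.default_cycles(FREQ_GRID, *config.cycles_range)
    baseline, exec_power = pp.trial_power_features(
        eeg_stack, fs, exec_starts, n_exec, cycles=cycles,
        baseline_window_s=config.baseline_window_s,
        trunc_sd=config.trunc_sd)
    subj_baseline = baseline.mean(axis=0)                # (ch, f)
    erds = (exec_power - subj_baseline[None, :, :, None]) \
        / subj_baseline[None, :, :, None] * 100.0

    conds = np.array([ep.condition for ep in kept])
    cond_ids = np.arange(1, proto.n_conditions + 1)
    if set(cond_ids) - set(conds):
        missing = sorted(set(cond_ids) - set(conds))
        raise RuntimeError(
            f"stage features: conditions {missing} have no surviving trials")
    erds_cond = np.stack([erds[conds == c].mean(axis=0) for c in cond_ids])

    # EMG: session-level standardization + Hilbert envelope, then windows
    # locked to the detected onset (200 Hz -> 100 samples per 500-ms window)
    n_emg = int(N_WINDOWS * WINDOW_LEN_S * proto.emg_hz)
    env_session = pp.emg_envelope(rec.emg)
    n_trial_emg = int(round(proto.trial_duration_s * proto.emg_hz))
    trial_of = {cr: i for i, cr in enumerate(proto.trial_sequence())}
    emg_cond = []
    for c in cond_ids:
        reps = []
        for ep in (e for e in kept if e.condition == c):
            t0 = trial_of[(ep.condition, ep.repetition)] * n_trial_emg
            i0 = t0 + int(round(ep.onset_s * proto.emg_hz))
            reps.append(env_session[:, i0:i0 + n_emg])
        emg_cond.append(np.mean(reps, axis=0))
    emg_cond = np.stack(emg_cond)                        # (n_cond, 8, 300)

    # kinematics: circular mean across repetitions of the raw angles,
    # then projection onto the subject's synergy components
    exec_end = int(proto.phase_onsets_s[3] * fs)
    move = np.concatenate(
        [ep.joints[:, int(round(ep.onset_s * fs)):exec_end] for ep in kept],
        axis=1)
    kpca = pp.kinematic_pca(move, n_components=config.n_kinematic_components)
    kin_cond = []
    for c in cond_ids:
        reps = [ep.joints[:, int(round(ep.onset_s * fs)):
                          int(round(ep.onset_s * fs)) + n_exec]
                for ep in kept if ep.condition == c]
        avg = pp.circular_mean(np.stack(reps), axis=0)   # (19, 150)
        kin_cond.append(kpca.project(avg))               # (k, 150)
    kin_cond = np.stack(kin_cond)

    qc_rows = [{"trial": i, "condition": ep.condition,
                "repetition": ep.repetition,
                "onset_sample": ep.onset_sample,
                "rejected": ep.rejected, "reason": ep.reason or ""}
               for i, ep in enumerate(epochs)]
    return {"erds": erds_cond, "emg": emg_cond, "kin": kin_cond,
            "kin_components": kpca.components, "qc": qc_rows,
            "n_kept": len(kept), "report": report}


def replace_stream(rec: MultimodalRecording, eeg: np.ndarray
                   ) -> MultimodalRecording:
    out = rec.copy()
    out.eeg = eeg
    out.protocol = replace(out.protocol, eeg_hz=100.0)
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------
def run_pipeline(config: PipelineConfig,
                 recordings: list[MultimodalRecording] | None = None
                 ) -> ResultBundle:
    """Execute all stages and assemble the result bundle.

    With ``recordings=None`` a synthetic cohort is generated from the
    config; a stage failure aborts with the stage name in the message.
    """
    t_all = time.time()
    timings = {}
    layout = default_layout()
    layout.validate()
    taxonomy = default_taxonomy(config.n_conditions)
    if not 0 <= config.target_channel_nb < layout.n_channel_nbs or \
            not 0 <= config.target_frequency_nb < layout.n_frequency_nbs:
        raise ValueError("stage config: planted cell outside the layout")
    if recordings is None and config.n_subjects < 2:
        raise ValueError("stage config: need >= 2 subjects (the bootstrap "
                         "resamples subjects)")
    if recordings is not None and len(recordings) < 2:
        raise ValueError("stage config: need >= 2 recordings")

    if recordings is None:
        t0 = time.time()
        protocol = generate_protocol(config.n_conditions,
                                     config.n_repetitions,
                                     seed=config.seed * 31 + 7)
        recordings = simulate_cohort(
            config.n_subjects, protocol, config.effect_spec(), taxonomy,
            layout, seed=config.seed,
            onset_jitter_sd=config.onset_jitter_sd)
        timings["synth"] = time.time() - t0
        logger.info("generated %d subjects in %.1f s", len(recordings),
                    timings["synth"])

    t0 = time.time()
    feats, qc_frames = [], []
    for si, rec in enumerate(recordings):
        f = _subject_features(rec, config, layout)
        feats.append(f)
        qc = pd.DataFrame(f["qc"])
        qc.insert(0, "subject", si)
        qc_frames.append(qc)
    qc = pd.concat(qc_frames, ignore_index=True)
    timings["preprocess"] = time.time() - t0

    n_cond = config.n_conditions
    cond_ids = tuple(range(1, n_cond + 1))
    fs = 100.0
    win_len = int(WINDOW_LEN_S * fs)

    # group-level condition patterns
    t0 = time.time()
    group_erds = np.mean([f["erds"] for f in feats], axis=0)
    group_emg = np.mean([f["emg"] for f in feats], axis=0)
    ref_comp = feats[0]["kin_components"]
    kin_aligned = [feats[0]["kin"]]
    for f in feats[1:]:
        perm, signs = pp.align_components(ref_comp, f["kin_components"])
        kin_aligned.append(f["kin"][:, perm, :] * signs[None, :, None])
    group_kin = np.mean(kin_aligned, axis=0)
    timings["group_average"] = time.time() - t0

    # reference RDMs per (cell, window)
    t0 = time.time()
    channel_names = recordings[0].eeg_channels
    reference_rdms = [
        _all_cell_rdms(group_erds[..., w * win_len:(w + 1) * win_len],
                       layout, channel_names, cond_ids, window=w)
        for w in range(N_WINDOWS)]
    timings["reference_rdms"] = time.time() - t0

    # candidate RDMs
    t0 = time.time()
    candidates: dict[str, list[_rsa.RDM]] = {}
    candidates["emg"] = [
        _rsa.compute_rdm(
            group_emg[:, :, w * 2 * win_len:(w + 1) * 2 * win_len]
            .reshape(n_cond, -1),
            conditions=cond_ids, source="emg", window=w)
        for w in range(N_WINDOWS)]
    candidates["kinematics"] = [
        _rsa.compute_rdm(
            group_kin[:, :, w * win_len:(w + 1) * win_len]
            .reshape(n_cond, -1),
            conditions=cond_ids, source="kinematics", window=w)
        for w in range(N_WINDOWS)]
    for scheme in ("grasp_type", "thumb_position", "object_shape"):
        rdm = _rsa.categorical_rdm(taxonomy, scheme)
        candidates[f"categorical:{scheme}"] = [rdm] * N_WINDOWS
    timings["candidate_rdms"] = time.time() - t0

    # searchlight RSA maps
    t0 = time.time()
    region = config.region
    if region is None:
        region = tuple(
            (i, j) for i, j in layout.cell_overlaps(
                config.target_channel_nb, config.target_frequency_nb)
            if abs(i - config.target_channel_nb) <= 1
            and abs(j - config.target_frequency_nb) <= 1)
    rsa_maps = {}
    for w in range(N_WINDOWS):
        for name in CANDIDATE_NAMES:
            rsa_maps[(w, name)] = _rsa.searchlight_rsa(
                reference_rdms[w], candidates[name][w], region=region,
                window=w)
    timings["searchlight_rsa"] = time.time() - t0

    # subject-level bootstrap at the region, for the best candidate
    t0 = time.time()
    region_cells = list(region)
    bootstrap = {}
    subj_region = _subject_region_patterns(feats, layout, channel_names,
                                           region_cells, win_len)
    for w in range(N_WINDOWS):
        best, _ = _best_candidate(rsa_maps, w, region_cells)
        res = _rsa.bootstrap_effect(
            subj_region[w], candidates[best][w], n_iter=config.n_boot,
            alpha=config.alpha, seed=config.seed * 613 + 29 + w)
        bootstrap[w] = (best, res)
    timings["bootstrap"] = time.time() - t0

    # second-level RDM per window
    t0 = time.time()
    second_level = {}
    for w in range(N_WINDOWS):
        eeg_region_pats = np.concatenate(
            [np.stack([extract_pattern(group_erds[c], layout, channel_names,
                                       i, j,
                                       slice(w * win_len, (w + 1) * win_len))
                       for c in range(n_cond)])
             for i, j in region_cells], axis=1)
        reps = [_rsa.compute_rdm(eeg_region_pats, conditions=cond_ids,
                                 source="eeg:region", window=w)]
        reps += [candidates[name][w] for name in CANDIDATE_NAMES]
        second_level[w] = _rsa.second_level_rdm(reps)
    timings["second_level"] = time.time() - t0
    timings["total"] = time.time() - t_all

    truth = dict(recordings[0].truth)
    truth["target_cell"] = (config.target_channel_nb,
                            config.target_frequency_nb)
    bundle = ResultBundle(
        config=config, layout=layout, taxonomy=taxonomy,
        reference_rdms=reference_rdms, candidate_rdms=candidates,
        rsa_maps=rsa_maps, bootstrap=bootstrap, second_level=second_level,
        qc=qc, region=tuple(region_cells), truth=truth, timings=timings,
        provenance={"config_hash": config.config_hash(),
                    "seed": config.seed})
    return bundle


def _all_cell_rdms(P: np.ndarray, layout, channel_names, cond_ids,
                   window: int) -> dict:
    """Rank-scaled RDMs of every searchlight cell, batched.

    ``P`` is the windowed group ERD/S tensor (n_cond, n_ch, n_freq, n_t).
    The per-cell correlation Gram matrices are assembled from channel- and
    bin-marginal sums, which is algebraically identical to computing
    ``1 - corrcoef`` on the concatenated cell patterns (the cell features
    are exactly the (channel, bin, sample) triples of the neighborhood).
    """
    P = np.asarray(P, dtype=np.float64)
    n_cond, n_ch, n_fq, n_t = P.shape
    name_to_idx = {ch: i for i, ch in enumerate(channel_names)}
    ch_sets = np.array([[name_to_idx[ch] for ch in nb]
                        for nb in layout.channel_neighborhoods])
    fq_sets = np.array([list(nb) for nb in layout.frequency_neighborhoods])
    members = ch_sets.shape[1] * fq_sets.shape[1]
    n_feat = members * n_t

    flat = P.transpose(1, 2, 0, 3).reshape(n_ch * n_fq, n_cond, n_t)
    Q = flat @ flat.transpose(0, 2, 1)                 # (ch*fq, C, C)
    Q = Q.reshape(n_ch, n_fq, n_cond, n_cond)
    s = P.sum(-1).transpose(1, 2, 0)                   # (ch, fq, C)
    Qf = Q[:, fq_sets].sum(axis=2)                     # (ch, n_fq_nb, C, C)
    sf = s[:, fq_sets].sum(axis=2)                     # (ch, n_fq_nb, C)
    Qcf = Qf[ch_sets].sum(axis=1)                      # (n_ch_nb, n_fq_nb, C, C)
    scf = sf[ch_sets].sum(axis=1)                      # (n_ch_nb, n_fq_nb, C)

    mean = scf / n_feat
    cov = Qcf / n_feat - mean[..., :, None] * mean[..., None, :]
    var = np.einsum("...cc->...c", cov)
    if np.any(var < 1e-28):
        i, j, c = np.argwhere(var < 1e-28)[0]
        raise ValueError(f"pattern of condition {cond_ids[c]} has zero "
                         f"variance in cell ({i}, {j})")
    denom = np.sqrt(var[..., :, None] * var[..., None, :])
    raw = 1.0 - cov / denom
    ii = np.arange(n_cond)
    raw[..., ii, ii] = 0.0
    raw = (raw + raw.swapaxes(-1, -2)) / 2.0

    il, jl = np.tril_indices(n_cond, k=-1)
    tri = raw[..., il, jl].reshape(-1, il.size)        # (cells, n_pairs)
    from scipy import stats as _st
    ranks = _st.rankdata(tri, axis=1)
    lo = ranks.min(axis=1, keepdims=True)
    hi = ranks.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled_tri = (ranks - lo) / span

    out = {}
    k = 0
    for i in range(ch_sets.shape[0]):
        for j in range(fq_sets.shape[0]):
            m = np.zeros((n_cond, n_cond))
            m[il, jl] = scaled_tri[k]
            m[jl, il] = scaled_tri[k]
            out[(i, j)] = _rsa.RDM(
                matrix=m, conditions=tuple(cond_ids),
                source=f"eeg:cell({i},{j})", window=window,
                scaling="rank-scaled", raw_matrix=raw[i, j])
            k += 1
    return out


def _best_candidate(rsa_maps, window, region_cells):
    means = {name: rsa_maps[(window, name)].region_mean(region_cells)
             for name in CANDIDATE_NAMES}
    best = min(means, key=means.get)
    return best, means


def _subject_region_patterns(feats, layout, channel_names, region_cells,
                             win_len):
    """Per-window arrays (n_subjects, n_cells, n_conditions, n_features)."""
    out = []
    for w in range(N_WINDOWS):
        sl = slice(w * win_len, (w + 1) * win_len)
        per_subj = []
        for f in feats:
            cells = []
            for i, j in region_cells:
                pats = np.stack([
                    extract_pattern(f["erds"][c], layout, channel_names,
                                    i, j, sl)
                    for c in range(f["erds"].shape[0])])
                cells.append(pats)
            per_subj.append(np.stack(cells))
        out.append(np.stack(per_subj))
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------
#: a map minimum this many null standard deviations below the mean counts
#: as localized representational structure
LOCALIZATION_Z = -6.0


def summarize(bundle: ResultBundle) -> str:
    """Human-readable run report."""
    if not bundle.rsa_maps:
        raise ValueError("empty bundle")
    lines = [f"grasp-rsa run {bundle.provenance.get('config_hash', '?')} "
             f"(seed {bundle.config.seed})",
             f"subjects: {bundle.config.n_subjects}, conditions: "
             f"{bundle.config.n_conditions}, repetitions: "
             f"{bundle.config.n_repetitions}"]
    n_rej = int(bundle.qc["rejected"].sum())
    lines.append(f"trials: {len(bundle.qc)} total, {n_rej} rejected")
    target = bundle.truth.get("target_cell")
    for w in range(N_WINDOWS):
        best, means = bundle.best_candidate(w)
        cand, boot = bundle.bootstrap[w]
        amap = bundle.rsa_maps[(w, best)]
        d = amap.distances
        zmin = (d.min() - d.mean()) / d.std() if d.std() > 0 else 0.0
        localized = zmin < LOCALIZATION_Z
        ci_note = "" if boot.ci_contains_observed else \
            " (observed outside CI: small-cohort bootstrap bias)"
        lines.append(
            f"window {w} ({WINDOW_NAMES[w]}): best candidate at region = "
            f"{best} (region-mean distance {means[best]:.3f}); bootstrap "
            f"[{cand}] {boot.observed:.3f} "
            f"CI [{boot.ci_low:.3f}, {boot.ci_high:.3f}]{ci_note}")
        lines.append(
            f"  map minimum {d.min():.3f} at cell {amap.argmin_cell} "
            f"(z = {zmin:.1f}): "
            + ("localized structure" if localized
               else "no localized structure"))
        if target is not None and localized:
            hit = amap.argmin_cell in bundle.layout.cell_overlaps(*target)
            lines.append(f"  planted-effect recovery: argmin "
                         f"{'at/near' if hit else 'away from'} planted cell "
                         f"{tuple(target)}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------
class GraspRSA:
    """Searchlight RSA model of multimodal grasping recordings.

    Parameters
    ----------
    config
        Run configuration; keyword overrides are applied on top.
    recordings
        Optional pre-simulated (or loaded) cohort; when omitted, ``fit``
        generates a synthetic cohort from the config.
    """

    def __init__(self, config: PipelineConfig | None = None,
                 recordings: list[MultimodalRecording] | None = None,
                 **overrides):
        config = config or PipelineConfig()
        if overrides:
            config = replace(config, **overrides)
        self.config = config
        self.recordings = recordings

    @classmethod
    def from_config(cls, path, **overrides) -> "GraspRSA":
        return cls(PipelineConfig.from_yaml(path), **overrides)

    def fit(self) -> "GraspRSAResults":
        bundle = run_pipeline(self.config, recordings=self.recordings)
        return GraspRSAResults(self, bundle)


class GraspRSAResults:
    """Fitted searchlight-RSA results.

    Attributes of interest: ``rsa_maps`` (distance grids per window and
    candidate), ``bootstrap_`` (per-window CIs), ``second_level_``,
    ``qc_`` and ``summary()``.
    """

    def __init__(self, model: GraspRSA, bundle: ResultBundle):
        self.model = model
        self.bundle = bundle

    @property
    def rsa_maps(self):
        return self.bundle.rsa_maps

    @property
    def bootstrap_(self):
        return self.bundle.bootstrap

    @property
    def second_level_(self):
        return self.bundle.second_level

    @property
    def qc_(self) -> pd.DataFrame:
        return self.bundle.qc

    def best_candidate(self, window: int, region=None):
        return self.bundle.best_candidate(window, region)

    def argmin_cell(self, window: int, candidate: str) -> tuple[int, int]:
        return self.bundle.rsa_maps[(window, candidate)].argmin_cell

    def summary(self) -> str:
        return summarize(self.bundle)
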