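"""Experimental protocol and condition taxonomy for the grasping task.

A session consists of ``n_conditions`` grasp types presented in blocks of
``n_repetitions`` consecutive 15-s trials.  Every trial runs through four
phases: fixation (3 s), observation (4 s), execution (4 s) and relaxation
(4 s).  Conditions are additionally labelled under three categorical
schemes -- grasp type, thumb position and object shape -- which later serve
as binary model RDMs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

PHASES = ("fixation", "observation", "execution", "relaxation")
PHASE_DURATIONS = (3.0, 4.0, 4.0, 4.0)

#: labels emitted for the per-trial event markers, in phase order
EVENT_LABELS = ("trial_start", "observe", "execute", "relax")

SCHEMES = ("grasp_type", "thumb_position", "object_shape")


@dataclass(frozen=True)
class ProtocolSpec:
    """Block-randomized session layout.

    Parameters mirror the acquisition protocol: trials are 15 s long
    (3 + 4 + 4 + 4 s phases), all repetitions of a condition are consecutive
    (one block per condition), and each modality has its own sampling rate.
    """

    n_conditions: int = 33
    n_repetitions: int = 8
    phase_durations: tuple[float, float, float, float] = PHASE_DURATIONS
    block_order: tuple[int, ...] = ()
    eeg_hz: float = 100.0
    emg_hz: float = 200.0
    accel_hz: float = 50.0
    joint_hz_range: tuple[float, float] = (80.0, 120.0)

    @property
    def trial_duration_s(self) -> float:
        return float(sum(self.phase_durations))

    @property
    def n_trials(self) -> int:
        return self.n_conditions * self.n_repetitions

    @property
    def phase_onsets_s(self) -> tuple[float, ...]:
        """Phase start times within a trial, in seconds."""
        return tuple(np.concatenate([[0.0], np.cumsum(self.phase_durations)[:-1]]))

    @property
    def execute_cue_s(self) -> float:
        return self.phase_onsets_s[2]

    def trial_sequence(self) -> list[tuple[int, int]]:
        """``(condition_id, repetition_index)`` for every trial, in session order."""
        return [(c, r) for c in self.block_order for r in range(self.n_repetitions)]

    def trial_start_s(self, trial_index: int) -> float:
        return trial_index * self.trial_duration_s

    @property
    def session_duration_s(self) -> float:
        return self.n_trials * self.trial_duration_s

    def events(self):
        """Event table: one row per (trial, phase cue).

        Returns a list of dicts with keys ``time_s``, ``label``, ``condition``
        and ``repetition``; the importable :mod:`grasprsa.io` helpers turn it
        into a DataFrame / TSV.
        """
        rows = []
        for t, (cond, rep) in enumerate(self.trial_sequence()):
            t0 = self.trial_start_s(t)
            for label, onset in zip(EVENT_LABELS, self.phase_onsets_s):
                rows.append(
                    {"time_s": t0 + onset, "label": label,
                     "condition": cond, "repetition": rep}
                )
        return rows

    def __post_init__(self):
        if self.n_conditions < 2:
            raise ValueError(f"n_conditions must be >= 2, got {self.n_conditions}")
        if self.n_repetitions < 1:
            raise ValueError(f"n_repetitions must be >= 1, got {self.n_repetitions}")
        if len(self.block_order) != self.n_conditions:
            raise ValueError("block_order must list every condition exactly once")
        if sorted(self.block_order) != list(range(1, self.n_conditions + 1)):
            raise ValueError("block_order must be a permutation of 1..n_conditions")


def generate_protocol(n_conditions: int = 33, n_repetitions: int = 8,
                      seed: int = 0, **kwargs) -> ProtocolSpec:
    """Create a block-randomized :class:`ProtocolSpec`.

    The block order (which condition each block presents) is a seeded
    permutation of ``1..n_conditions``; identical seeds give identical
    protocols.
    """
    if n_conditions < 2 or n_repetitions < 1:
        raise ValueError(
            "need n_conditions >= 2 and n_repetitions >= 1, got "
            f"({n_conditions}, {n_repetitions})")
    rng = np.random.default_rng(seed)
    order = tuple(int(c) for c in rng.permutation(n_conditions) + 1)
    return ProtocolSpec(n_conditions=n_conditions, n_repetitions=n_repetitions,
                        block_order=order, **kwargs)


@dataclass(frozen=True)
class Taxonomy:
    """Categorical labels of each condition under the three schemes."""

    grasp_type: dict[int, str]
    thumb_position: dict[int, str]
    object_shape: dict[int, str]
    names: dict[int, str] = field(default_factory=dict)

    def scheme(self, name: str) -> dict[int, str]:
        if name not in SCHEMES:
            raise KeyError(f"unknown scheme {name!r}; expected one of {SCHEMES}")
        return getattr(self, name)

    @property
    def condition_ids(self) -> list[int]:
        return sorted(self.grasp_type)

    def __post_init__(self):
        ids = set(self.grasp_type)
        for s in SCHEMES:
            if set(getattr(self, s)) != ids:
                raise ValueError(f"scheme {s!r} does not label the same conditions")
        limits = {"grasp_type": 3, "thumb_position": 2, "object_shape": 7}
        for s, lim in limits.items():
            k = len(set(getattr(self, s).values()))
            if k > lim:
                raise ValueError(f"scheme {s!r} has {k} labels, at most {lim} allowed")

    def subset(self, condition_ids) -> "Taxonomy":
        ids = list(condition_ids)
        return Taxonomy(
            grasp_type={c: self.grasp_type[c] for c in ids},
            thumb_position={c: self.thumb_position[c] for c in ids},
            object_shape={c: self.object_shape[c] for c in ids},
            names={c: self.names.get(c, str(c)) for c in ids},
        )

    @classmethod
    def from_yaml(cls, path_or_stream) -> "Taxonomy":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        g, t, o, names = {}, {}, {}, {}
        for cid, entry in raw["conditions"].items():
            cid = int(cid)
            g[cid] = entry["grasp_type"]
            t[cid] = entry["thumb_position"]
            o[cid] = entry["object_shape"]
            names[cid] = entry.get("name", str(cid))
        return cls(grasp_type=g, thumb_position=t, object_shape=o, names=names)


def default_taxonomy(n_conditions: int = 33) -> Taxonomy:
    """The taxonomy shipped with the package (33 one-handed grasps).

    The labels are a plausible assignment over the standard grasp repertoire
    and are treated as configuration data, not ground truth.  For
    ``n_conditions < 33`` the first conditions are kept.
    """
    ref = importlib.resources.files("grasprsa.data") / "taxonomy33.yaml"
    with ref.open() as fh:
        tax = Taxonomy.from_yaml(fh)
    if n_conditions > len(tax.condition_ids):
        raise ValueError(
            f"default taxonomy covers {len(tax.condition_ids)} conditions, "
            f"{n_conditions} requested")
    return tax.subset(range(1, n_conditions + 1))


@dataclass(frozen=True)
class EffectSpec:
    """Where and how strongly a condition-similarity effect is planted in EEG.

    ``target_channel_nb`` / ``target_frequency_nb`` index the searchlight
    layout; the planted pattern dissimilarities follow ``model_rdm`` (a
    condition x condition dissimilarity matrix) with between-condition
    amplitude scaled by ``effect_size``.  ``effect_size = 0`` makes all
    conditions exchangeable.
    """

    # defaults: left centro-parietal channel neighborhood, mu band
    target_channel_nb: int = 3
    target_frequency_nb: int = 6
    model_rdm: np.ndarray | None = None
    effect_size: float = 1.0
    noise_sd: float = 2.0
    erd_depth: float = 0.5       # baseline suppression of target-band power
    osc_amplitude: float = 1.2   # amplitude of the planted band oscillators
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.erd_depth < 1.0:
            raise ValueError("erd_depth must lie in [0, 1)")


def replace_protocol(protocol: ProtocolSpec, **kwargs) -> ProtocolSpec:
    """Convenience wrapper around :func:`dataclasses.replace`."""
    return replace(protocol, **kwargs)
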