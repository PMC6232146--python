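"""Reading and writing sessions and results.

Synthetic sessions are stored in an HDF5 container with the layout

    /eeg      (61, T)  float32, attrs: rate_hz, channels
    /eog      (3, T)   float32
    /emg      (8, T)   float32, attrs: rate_hz
    /joints/t (n,)     float64  irregular timestamps [s]
    /joints/values (19, n) float64
    /accel    (3, T)   float32, attrs: rate_hz
    /events   structured table (time_s, label, condition, repetition)
    /truth    JSON-encoded ground truth (onsets, planted effect)

plus a TSV event sidecar.  RDMs and second-level matrices are written as
TSV with a JSON metadata sidecar; QC reports as TSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .protocol import ProtocolSpec
from .rsa import RDM
from .synth import MultimodalRecording


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def events_frame(events) -> pd.DataFrame:
    return pd.DataFrame(events, columns=["time_s", "label", "condition",
                                         "repetition"])


def save_session(recording: MultimodalRecording, path, events_tsv=None
                 ) -> None:
    """Write a session to the HDF5 container (and a TSV event sidecar)."""
    path = Path(path)
    proto = recording.protocol
    with h5py.File(path, "w") as f:
        f.attrs["trial_duration_s"] = proto.trial_duration_s
        f.attrs["n_conditions"] = proto.n_conditions
        f.attrs["n_repetitions"] = proto.n_repetitions
        f.attrs["block_order"] = list(proto.block_order)
        f.attrs["phase_durations"] = list(proto.phase_durations)
        d = f.create_dataset("eeg", data=recording.eeg.astype(np.float32))
        d.attrs["rate_hz"] = proto.eeg_hz
        d.attrs["channels"] = list(recording.eeg_channels)
        f.create_dataset("eog", data=recording.eog.astype(np.float32))
        d = f.create_dataset("emg", data=recording.emg.astype(np.float32))
        d.attrs["rate_hz"] = proto.emg_hz
        g = f.create_group("joints")
        g.create_dataset("t", data=recording.joint_t)
        g.create_dataset("values", data=recording.joints)
        d = f.create_dataset("accel", data=recording.accel.astype(np.float32))
        d.attrs["rate_hz"] = proto.accel_hz
        ev = events_frame(recording.events)
        rec = np.rec.fromarrays(
            [ev["time_s"].to_numpy(),
             ev["label"].astype("S24").to_numpy(),
             ev["condition"].to_numpy(), ev["repetition"].to_numpy()],
            names=["time_s", "label", "condition", "repetition"])
        f.create_dataset("events", data=rec)
        f.create_dataset("truth", data=json.dumps(
            recording.truth, default=_json_default))
    if events_tsv is None:
        events_tsv = path.with_suffix(".events.tsv")
    events_frame(recording.events).to_csv(events_tsv, sep="\t", index=False)


def load_session(path) -> MultimodalRecording:
    with h5py.File(path, "r") as f:
        proto = ProtocolSpec(
            n_conditions=int(f.attrs["n_conditions"]),
            n_repetitions=int(f.attrs["n_repetitions"]),
            phase_durations=tuple(f.attrs["phase_durations"]),
            block_order=tuple(int(c) for c in f.attrs["block_order"]),
            eeg_hz=float(f["eeg"].attrs["rate_hz"]),
            emg_hz=float(f["emg"].attrs["rate_hz"]),
            accel_hz=float(f["accel"].attrs["rate_hz"]))
        ev = f["events"][()]
        events = [
            {"time_s": float(r["time_s"]),
             "label": r["label"].decode(),
             "condition": int(r["condition"]),
             "repetition": int(r["repetition"])}
            for r in ev]
        return MultimodalRecording(
            protocol=proto,
            eeg=f["eeg"][()], eog=f["eog"][()], emg=f["emg"][()],
            joint_t=f["joints/t"][()], joints=f["joints/values"][()],
            accel=f["accel"][()], events=events,
            eeg_channels=tuple(c for c in f["eeg"].attrs["channels"]),
            truth=json.loads(f["truth"][()]))


def save_rdm(rdm: RDM, path) -> None:
    """TSV matrix + JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(rdm.matrix, index=rdm.conditions,
                 columns=rdm.conditions).to_csv(path, sep="\t")
    meta = {"source": rdm.source, "window": rdm.window,
            "scaling": rdm.scaling, "conditions": list(rdm.conditions),
            **rdm.meta}
    path.with_suffix(".json").write_text(
        json.dumps(meta, default=_json_default, indent=1))


def load_rdm(path) -> RDM:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text())
    return RDM(matrix=df.to_numpy(dtype=float),
               conditions=tuple(meta["conditions"]),
               source=meta.get("source", ""), window=meta.get("window"),
               scaling=meta.get("scaling", "rank-scaled"),
               meta={k: v for k, v in meta.items()
                     if k not in ("source", "window", "scaling",
                                  "conditions")})


def save_qc_report(qc: pd.DataFrame, path) -> None:
    qc.to_csv(path, sep="\t", index=False)


def save_rsa_map(rsa_map, path) -> None:
    """RSA distance grid as TSV (channel neighborhoods x frequency
    neighborhoods) + JSON sidecar."""
    path = Path(path)
    pd.DataFrame(rsa_map.distances).to_csv(path, sep="\t", index=False)
    path.with_suffix(".json").write_text(json.dumps(
        {"candidate": rsa_map.candidate, "window": rsa_map.window,
         "argmin_cell": list(rsa_map.argmin_cell),
         "region": [list(c) for c in rsa_map.region]},
        default=_json_default, indent=1))


def save_bundle(bundle, out_dir) -> None:
    """Persist the portable parts of a result bundle to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(out / "config.yaml")
    save_qc_report(bundle.qc, out / "qc.tsv")
    for (w, name), amap in bundle.rsa_maps.items():
        safe = name.replace(":", "_")
        save_rsa_map(amap, out / f"rsa_map_w{w}_{safe}.tsv")
    for name, rdms in bundle.candidate_rdms.items():
        safe = name.replace(":", "_")
        for w, rdm in enumerate(rdms):
            save_rdm(rdm, out / f"candidate_w{w}_{safe}.tsv")
    boot_rows = []
    for w, (cand, res) in bundle.bootstrap.items():
        boot_rows.append({"window": w, "candidate": cand,
                          "observed": res.observed, "ci_low": res.ci_low,
                          "ci_high": res.ci_high,
                          "n_iterations": res.n_iterations})
    pd.DataFrame(boot_rows).to_csv(out / "bootstrap.tsv", sep="\t",
                                   index=False)
    for w, (mat, labels) in bundle.second_level.items():
        pd.DataFrame(mat, index=labels, columns=labels).to_csv(
            out / f"second_level_w{w}.tsv", sep="\t")
    (out / "provenance.json").write_text(json.dumps(
        {**bundle.provenance, "timings_s": bundle.timings},
        default=_json_default, indent=1))


# -- optional raw-EEG readers (thin delegations to mne) ---------------------
def read_raw_edf(path, **kwargs):
    """Read an EDF EEG file via mne (optional dependency)."""
    import mne

    return mne.io.read_raw_edf(path, **kwargs)


def read_raw_brainvision(vhdr_path, **kwargs):
    """Read a BrainVision (.vhdr/.eeg/.vmrk) EEG file via mne."""
    import mne

    return mne.io.read_raw_brainvision(vhdr_path, **kwargs)
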