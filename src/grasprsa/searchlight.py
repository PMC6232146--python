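"""Channel-space and frequency-space searchlight neighborhoods.

The searchlight scans a grid of local neighborhoods: 31 in channel space
(five channels each: a centroid and four neighbors) crossed with 26 in
frequency space (five consecutive 0.5-Hz bins, i.e. a 2-Hz band).
Consecutive neighborhoods in either space share exactly two members, so the
channel chain advances by three channels and the frequency windows slide by
three bins (1.5 Hz).  Every (channel neighborhood x frequency neighborhood)
cell contributes one reference RDM per time window: 31 x 26 = 806 cells.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np

#: 0.5-Hz analysis grid over the 0.1-40 Hz band; bin centers start at 0.5 Hz
#: (the 0.1-Hz band edge lies below the first representable bin center).
FREQ_GRID = np.round(np.arange(0.5, 40.0 + 1e-9, 0.5), 3)  # 80 bins

N_MEMBERS = 5
N_SHARED = 2


def frequency_grid() -> np.ndarray:
    return FREQ_GRID.copy()


def build_frequency_neighborhoods(n_bins: int | None = None,
                                  members: int = N_MEMBERS,
                                  shared: int = N_SHARED) -> list[tuple[int, ...]]:
    """Sliding windows of ``members`` consecutive bins, stride ``members - shared``.

    On the 80-bin grid the defaults give 26 neighborhoods of five bins
    (2-Hz bands) with two bins in common between consecutive neighborhoods.
    """
    if n_bins is None:
        n_bins = FREQ_GRID.size
    if members <= shared:
        raise ValueError("members must exceed shared")
    if n_bins < members:
        raise ValueError(f"grid of {n_bins} bins is shorter than one window")
    stride = members - shared
    n_nb = (n_bins - members) // stride + 1
    return [tuple(range(i * stride, i * stride + members)) for i in range(n_nb)]


@dataclass(frozen=True)
class SearchlightLayout:
    """Neighborhood definitions plus ordering metadata.

    ``channel_neighborhoods`` lists, in periphery-to-midline /
    anterior-to-posterior traversal order, five channel names each (the
    centroid is the middle member).  ``frequency_neighborhoods`` lists bin
    indices into ``freqs``.
    """

    channel_neighborhoods: tuple[tuple[str, ...], ...]
    frequency_neighborhoods: tuple[tuple[int, ...], ...]
    freqs: np.ndarray = field(default_factory=frequency_grid)
    ordering: str = "periphery-to-midline, anterior-to-posterior"

    @property
    def n_channel_nbs(self) -> int:
        return len(self.channel_neighborhoods)

    @property
    def n_frequency_nbs(self) -> int:
        return len(self.frequency_neighborhoods)

    @property
    def n_cells(self) -> int:
        return self.n_channel_nbs * self.n_frequency_nbs

    @property
    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for nb in self.channel_neighborhoods:
            for ch in nb:
                seen.setdefault(ch)
        return list(seen)

    def centroid(self, ch_nb: int) -> str:
        return self.channel_neighborhoods[ch_nb][N_MEMBERS // 2]

    def band_hz(self, fq_nb: int) -> tuple[float, float]:
        bins = self.frequency_neighborhoods[fq_nb]
        return float(self.freqs[bins[0]]), float(self.freqs[bins[-1]])

    def validate(self, channel_names=None) -> None:
        """Enforce the 5-member / 2-shared invariants; raise on violation."""
        for space, nbs in (("channel", self.channel_neighborhoods),
                           ("frequency", self.frequency_neighborhoods)):
            for i, nb in enumerate(nbs):
                if len(nb) != N_MEMBERS or len(set(nb)) != N_MEMBERS:
                    raise ValueError(
                        f"{space} neighborhood {i} must have exactly "
                        f"{N_MEMBERS} distinct members, got {nb}")
            for i in range(len(nbs) - 1):
                n_common = len(set(nbs[i]) & set(nbs[i + 1]))
                if n_common != N_SHARED:
                    raise ValueError(
                        f"consecutive {space} neighborhoods {i},{i + 1} share "
                        f"{n_common} members, expected {N_SHARED}")
        for nb in self.frequency_neighborhoods:
            if min(nb) < 0 or max(nb) >= self.freqs.size:
                raise ValueError(f"frequency neighborhood {nb} outside the grid")
        if channel_names is not None:
            missing = sorted(set(self.channels) - set(channel_names))
            if missing:
                raise ValueError(f"montage is missing layout channels: {missing}")

    def cell_overlaps(self, ch_nb: int, fq_nb: int) -> list[tuple[int, int]]:
        """Cells sharing at least one channel and one frequency bin with a cell."""
        chs = set(self.channel_neighborhoods[ch_nb])
        bins = set(self.frequency_neighborhoods[fq_nb])
        ch_ids = [i for i, nb in enumerate(self.channel_neighborhoods)
                  if chs & set(nb)]
        fq_ids = [j for j, nb in enumerate(self.frequency_neighborhoods)
                  if bins & set(nb)]
        return [(i, j) for i in ch_ids for j in fq_ids]

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "ordering": self.ordering,
            "freqs_hz": [float(f) for f in self.freqs],
            "channel_neighborhoods": [list(nb) for nb in self.channel_neighborhoods],
            "frequency_neighborhoods": [list(nb) for nb in self.frequency_neighborhoods],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path_or_stream) -> "SearchlightLayout":
        if hasattr(path_or_stream, "read"):
            payload = json.load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                payload = json.load(fh)
        layout = cls(
            channel_neighborhoods=tuple(
                tuple(nb) for nb in payload["channel_neighborhoods"]),
            frequency_neighborhoods=tuple(
                tuple(int(b) for b in nb)
                for nb in payload["frequency_neighborhoods"]),
            freqs=np.asarray(payload["freqs_hz"], dtype=float),
            ordering=payload.get("ordering", ""),
        )
        layout.validate()
        return layout


def traversal_order(positions: dict[str, tuple[float, float]]) -> list[str]:
    """Order channels periphery-to-midline (left to right) and
    anterior-to-posterior within each sagittal column."""
    def key(ch):
        x, y = positions[ch]
        return (round(float(x), 3), -round(float(y), 3))
    return sorted(positions, key=key)


def build_channel_neighborhoods(positions: dict[str, tuple[float, float]],
                                n_centroids: int = 31,
                                members: int = N_MEMBERS,
                                shared: int = N_SHARED,
                                ) -> tuple[tuple[str, ...], ...]:
    """Chain neighborhoods along the 2-D montage traversal.

    Channels are ordered periphery-to-midline / anterior-to-posterior and the
    chain advances ``members - shared`` channels per neighborhood (wrapping
    around the traversal), which guarantees that consecutive neighborhoods
    share exactly ``shared`` channels.  The exact member sets of the original
    study are not recoverable; only these counting/overlap invariants are
    enforced.
    """
    order = traversal_order(positions)
    n = len(order)
    if n < members + 2:
        raise ValueError(f"montage with {n} channels is too small")
    stride = members - shared
    if n_centroids * stride > 2 * n:
        raise ValueError("too many centroids for this montage")
    nbs = []
    for i in range(n_centroids):
        nb = tuple(order[(i * stride + j) % n] for j in range(members))
        nbs.append(nb)
    return tuple(nbs)


def montage_positions_2d(channel_names,
                         montage_name: str = "standard_1005"
                         ) -> dict[str, tuple[float, float]]:
    """2-D (x, y) electrode positions from a standard montage (via mne)."""
    import mne

    montage = mne.channels.make_standard_montage(montage_name)
    pos3d = montage.get_positions()["ch_pos"]
    missing = [ch for ch in channel_names if ch not in pos3d]
    if missing:
        raise ValueError(f"montage {montage_name!r} lacks channels: {missing}")
    return {ch: (float(pos3d[ch][0]), float(pos3d[ch][1]))
            for ch in channel_names}


#: the 61 EEG channels of the 10-10 montage used throughout the package
CHANNELS_61 = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
)


def generate_default_layout() -> SearchlightLayout:
    """Regenerate the default layout from standard montage coordinates.

    Requires mne (for electrode positions).  The shipped
    ``data/layout61.json`` was produced by this function and is loaded by
    :func:`default_layout` without needing mne.
    """
    pos = montage_positions_2d(CHANNELS_61)
    layout = SearchlightLayout(
        channel_neighborhoods=build_channel_neighborhoods(pos),
        frequency_neighborhoods=tuple(build_frequency_neighborhoods()),
    )
    layout.validate(CHANNELS_61)
    return layout


def default_layout() -> SearchlightLayout:
    """The frozen 31 x 26 layout shipped with the package."""
    ref = importlib.resources.files("grasprsa.data") / "layout61.json"
    with ref.open() as fh:
        return SearchlightLayout.from_json(fh)


def extract_pattern(erds_values: np.ndarray,
                    layout: SearchlightLayout,
                    channel_names,
                    ch_nb: int, fq_nb: int,
                    window: slice | tuple[int, int]) -> np.ndarray:
    """Concatenate ERD/S values of one searchlight cell into a pattern vector.

    ``erds_values`` is (channels x frequency bins x time).  Order of
    concatenation is channel-major, then frequency, then time, so a 500-ms
    window at 100 Hz yields 5 x 5 x 50 = 1250 values.
    """
    if not isinstance(window, slice):
        window = slice(*window)
    name_to_idx = {ch: i for i, ch in enumerate(channel_names)}
    try:
        ch_idx = [name_to_idx[ch] for ch in layout.channel_neighborhoods[ch_nb]]
    except KeyError as e:
        raise ValueError(f"channel {e.args[0]!r} absent from data") from None
    bins = list(layout.frequency_neighborhoods[fq_nb])
    n_t = erds_values.shape[-1]
    stop = window.stop if window.stop is not None else n_t
    if stop > n_t:
        raise ValueError(
            f"window {window} exceeds the {n_t} available samples")
    block = erds_values[np.ix_(ch_idx, bins)][..., window]
    return np.ascontiguousarray(block).reshape(-1)
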