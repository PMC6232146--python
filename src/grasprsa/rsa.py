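"""Representational similarity analysis.

First-level RDMs use ``1 - r`` (Pearson) between condition patterns, with
the off-diagonal distances replaced by their average ranks and min-max
scaled to [0, 1].  Binary categorical models (same category -> 0, different
-> 1) serve as candidate RDMs alongside the EMG and kinematic ones.  RDMs
are compared with ``1 - Spearman rho`` over the lower-triangle entries,
which is invariant to any monotone transform of either RDM (so comparing
rank-scaled matrices is equivalent to comparing the raw distances).
Uncertainty of a region-level effect is quantified by a subject-level
bootstrap (resampling subjects with replacement) with percentile CIs, and a
second-level RDM assembles all pairwise comparisons among representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .protocol import Taxonomy


# ---------------------------------------------------------------------------
# RDM container
# ---------------------------------------------------------------------------
@dataclass
class RDM:
    """Symmetric zero-diagonal condition dissimilarity matrix."""

    matrix: np.ndarray
    conditions: tuple[int, ...]
    source: str = ""
    window: int | None = None
    scaling: str = "rank-scaled"          # "raw" | "rank-scaled"
    raw_matrix: np.ndarray | None = None  # pre-scaling distances
    meta: dict = field(default_factory=dict)

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n_conditions, k=-1)
        return self.matrix[i, j]

    def validate(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("RDM diagonal must be zero")


def rank_scale(distances: np.ndarray) -> np.ndarray:
    """Average ranks min-max scaled to [0, 1] (ties permitting).

    A degenerate all-equal input maps to all zeros.
    """
    d = np.asarray(distances, dtype=float)
    ranks = stats.rankdata(d, method="average")
    lo, hi = ranks.min(), ranks.max()
    if hi == lo:
        return np.zeros_like(d)
    return (ranks - lo) / (hi - lo)


def compute_rdm(patterns: np.ndarray, conditions=None, source: str = "",
                window: int | None = None, meta: dict | None = None) -> RDM:
    """Rank-scaled correlation-distance RDM from one pattern per condition.

    ``patterns`` is (n_conditions, n_features); the distance is
    ``1 - Pearson r`` between rows, then the 528 (for 33 conditions)
    off-diagonal entries are ranked and scaled to [0, 1].  The raw distance
    matrix is kept in ``raw_matrix``.
    """
    X = np.asarray(patterns, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 condition patterns")
    n = X.shape[0]
    if conditions is None:
        conditions = tuple(range(1, n + 1))
    conditions = tuple(conditions)
    if len(conditions) != n:
        raise ValueError("conditions must label every pattern")
    sd = X.std(axis=1)
    if np.any(sd < 1e-14):
        bad = conditions[int(np.flatnonzero(sd < 1e-14)[0])]
        raise ValueError(f"pattern of condition {bad} has zero variance")
    raw = 1.0 - np.corrcoef(X)
    np.fill_diagonal(raw, 0.0)
    raw = (raw + raw.T) / 2.0
    i, j = np.tril_indices(n, k=-1)
    scaled_tri = rank_scale(raw[i, j])
    scaled = np.zeros_like(raw)
    scaled[i, j] = scaled_tri
    scaled[j, i] = scaled_tri
    return RDM(matrix=scaled, conditions=conditions, source=source,
               window=window, scaling="rank-scaled", raw_matrix=raw,
               meta=meta or {})


def categorical_rdm(taxonomy: Taxonomy, scheme: str) -> RDM:
    """Binary model RDM: 0 for same-category pairs, 1 otherwise."""
    labels = taxonomy.scheme(scheme)
    conditions = tuple(sorted(labels))
    missing = [c for c in conditions if labels[c] is None]
    if missing:
        raise ValueError(f"conditions without a {scheme} label: {missing}")
    lab = np.asarray([labels[c] for c in conditions], dtype=object)
    m = (lab[:, None] != lab[None, :]).astype(float)
    return RDM(matrix=m, conditions=conditions, source=f"categorical:{scheme}",
               scaling="rank-scaled", raw_matrix=m.copy(),
               meta={"scheme": scheme,
                     "n_categories": len(set(labels.values()))})


def spearman_distances(triangles: np.ndarray, candidate_tri: np.ndarray
                       ) -> np.ndarray:
    """``1 - Spearman rho`` between each row of ``triangles`` and one
    candidate triangle (vectorized; average ranks, like
    :func:`compare_rdms`)."""
    A = stats.rankdata(np.atleast_2d(triangles), axis=1)
    b = stats.rankdata(np.asarray(candidate_tri, dtype=float))
    A = A - A.mean(axis=1, keepdims=True)
    b = b - b.mean()
    denom = np.sqrt((A ** 2).sum(axis=1) * (b ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (A @ b) / np.where(denom > 0, denom, 1.0),
                       0.0)
    return 1.0 - rho


def compare_rdms(reference: RDM, candidate: RDM) -> float:
    """Distance between two RDMs: ``1 - Spearman rho`` over the lower
    triangles.  Requires identical condition sets and ordering (no silent
    reindexing); the result lies in [0, 2].
    """
    if reference.conditions != candidate.conditions:
        raise ValueError(
            "RDMs are defined on different condition orderings: "
            f"{reference.conditions[:5]}... vs {candidate.conditions[:5]}...")
    a = reference.lower_triangle()
    b = candidate.lower_triangle()
    # a constant RDM (e.g. a one-category categorical model) carries no
    # rank structure; its correlation with anything is taken as zero
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 1.0
    rho = stats.spearmanr(a, b).statistic
    return float(1.0 - rho)


# ---------------------------------------------------------------------------
# searchlight-level comparison
# ---------------------------------------------------------------------------
@dataclass
class RSAMap:
    """Reference-vs-candidate distances over the searchlight grid."""

    distances: np.ndarray           # (n_channel_nbs, n_frequency_nbs)
    candidate: str
    window: int | None = None
    region: tuple[tuple[int, int], ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def argmin_cell(self) -> tuple[int, int]:
        i = int(np.argmin(self.distances))
        return tuple(int(v) for v in
                     np.unravel_index(i, self.distances.shape))

    def region_mean(self, region=None) -> float:
        cells = tuple(region) if region is not None else self.region
        if not cells:
            raise ValueError("no region of interest specified")
        return float(np.mean([self.distances[c] for c in cells]))


def searchlight_rsa(reference_rdms, candidate: RDM,
                    region=(), window: int | None = None) -> RSAMap:
    """Compare one candidate RDM against every searchlight reference RDM.

    ``reference_rdms`` is a mapping ``(ch_nb, fq_nb) -> RDM`` covering the
    full grid (806 cells for the default layout); missing cells raise with
    the absent (centroid, band) pairs listed.
    """
    cells = sorted(reference_rdms)
    n_ch = max(c for c, _ in cells) + 1
    n_fq = max(f for _, f in cells) + 1
    expected = {(i, j) for i in range(n_ch) for j in range(n_fq)}
    missing = sorted(expected - set(cells))
    if missing:
        raise ValueError(f"reference set incomplete; missing cells "
                         f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    for rdm in reference_rdms.values():
        if rdm.conditions != candidate.conditions:
            raise ValueError("RDMs are defined on different condition "
                             "orderings")
    tri = np.stack([reference_rdms[c].lower_triangle() for c in cells])
    d = spearman_distances(tri, candidate.lower_triangle())
    dist = np.empty((n_ch, n_fq))
    for c, value in zip(cells, d):
        dist[c] = value
    return RSAMap(distances=dist, candidate=candidate.source, window=window,
                  region=tuple(region))


# ---------------------------------------------------------------------------
# subject-level bootstrap
# ---------------------------------------------------------------------------
@dataclass
class BootstrapResult:
    """Observed region-mean distance with a percentile bootstrap CI."""

    observed: float
    ci_low: float
    ci_high: float
    n_iterations: int
    alpha: float
    seed: int
    replicates: np.ndarray = field(repr=False, default=None)
    ci_contains_observed: bool = True


def _region_distance(subject_patterns: np.ndarray, candidate: RDM,
                     conditions) -> float:
    """Mean over region cells of the distance between the group-level RDM
    and the candidate.  ``subject_patterns`` is
    (n_subjects, n_cells, n_conditions, n_features)."""
    group = subject_patterns.mean(axis=0)        # (n_cells, n_cond, d)
    dists = [compare_rdms(compute_rdm(group[c], conditions=conditions),
                          candidate)
             for c in range(group.shape[0])]
    return float(np.mean(dists))


def bootstrap_effect(subject_patterns: np.ndarray, candidate: RDM,
                     n_iter: int = 500, alpha: float = 0.05,
                     seed: int = 0) -> BootstrapResult:
    """Subject-level bootstrap of the region-mean RDM distance.

    ``subject_patterns`` is (n_subjects, n_cells, n_conditions,
    n_features): the per-subject condition patterns of every region cell.
    Each iteration resamples the subjects with replacement, recomputes the
    group patterns, the per-cell RDMs and the region-mean distance to the
    candidate; the CI is the (alpha/2, 1-alpha/2) percentile interval of
    the replicates.  In the typical regime the CI contains the observed
    effect; violations are flagged, not hidden.
    """
    P = np.asarray(subject_patterns, dtype=float)
    if P.ndim == 3:
        P = P[:, None]
    if P.ndim != 4:
        raise ValueError("subject_patterns must be (n_subjects, n_cells, "
                         "n_conditions, n_features)")
    n_subj = P.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    conditions = candidate.conditions
    observed = _region_distance(P, candidate, conditions)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.integers(0, n_subj, n_subj)
        reps[it] = _region_distance(P[idx], candidate, conditions)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        observed=observed, ci_low=float(lo), ci_high=float(hi),
        n_iterations=n_iter, alpha=alpha, seed=seed, replicates=reps,
        ci_contains_observed=bool(lo <= observed <= hi))


# ---------------------------------------------------------------------------
# second level
# ---------------------------------------------------------------------------
def second_level_rdm(representations: list[RDM]):
    """Dissimilarity matrix of RDMs (rank-correlation distance).

    Entry (a, b) is ``compare_rdms(RDM_a, RDM_b)``; the result is symmetric
    with a zero diagonal.  All RDMs must share one condition set.
    """
    if len(representations) < 2:
        raise ValueError("need at least 2 RDMs")
    conds = representations[0].conditions
    for r in representations[1:]:
        if r.conditions != conds:
            raise ValueError("RDMs are defined on heterogeneous condition "
                             "sets")
    K = len(representations)
    out = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            d = compare_rdms(representations[a], representations[b])
            out[a, b] = out[b, a] = d
    labels = [r.source or f"rdm{i}" for i, r in enumerate(representations)]
    return out, labels
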