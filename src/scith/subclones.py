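"""Subclonal SCNA detection and subpopulation structure.

Hierarchical (Euclidean/Ward) clustering of tumor-cell copy-number matrices,
PAM with silhouette-based choice of k, variance + PCA selection of candidate
subclonal bins, a >=1.5 Mb contiguous-event filter, and subpopulation
frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from .grid import BinGrid

__all__ = [
    "SubcloneParams",
    "SubcloneResult",
    "hierarchical_cluster",
    "pam",
    "pam_choose_k",
    "pca_candidate_bins",
    "select_large_events",
    "assign_subclones",
    "subpopulation_frequencies",
]


@dataclass
class SubcloneParams:
    min_nonzero_elements: int = 3
    variance_threshold: float = 0.5
    n_pcs: int = 6
    # a bin is "collected from" a PC iff |loading| >= loading_rel_threshold *
    # that PC's max |loading|; set loading_quantile to use a per-PC top-quantile
    # cutoff instead
    loading_rel_threshold: float = 0.5
    loading_quantile: float | None = None
    min_event_span: int = 1_500_000
    gap_tolerance_bins: int = 1
    k_min: int = 2
    k_max: int = 10

    def __post_init__(self):
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")


@dataclass
class SubcloneResult:
    labels: pd.Series  # cell -> cluster id (1-based)
    k: int
    candidate_bins: np.ndarray
    selected_bins: np.ndarray
    events: pd.DataFrame  # chrom, start, end, n_bins
    frequencies: dict  # cluster -> exact fraction
    percent: dict  # cluster -> integer-rounded percent
    silhouette: dict = field(default_factory=dict)  # k -> average width
    low_confidence: bool = False
    agreement: pd.DataFrame | None = None


def hierarchical_cluster(matrix: pd.DataFrame, k: int) -> tuple[np.ndarray, pd.Series]:
    """Ward linkage on Euclidean distances, cut into k clusters.

    Returns (linkage matrix, labels). Deterministic given row order; a
    constant matrix collapses to one cluster with a warning.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 cells")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        warnings.warn("constant matrix: single cluster", stacklevel=2)
        return linkage(X, method="ward"), pd.Series(1, index=matrix.index, name="cluster")
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Z, pd.Series(labels, index=matrix.index, name="cluster")


def pam(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Partition around medoids on a precomputed distance matrix.

    Deterministic BUILD initialization followed by SWAP until no improvement;
    ties break toward the lower index. Returns 0-based labels.
    """
    n = dist.shape[0]
    if k >= n:
        return np.arange(n)
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:  # BUILD: greedily add the best cost reducer
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds):
        return dist[:, meds].min(axis=1).sum()

    best = cost(medoids)
    for _ in range(max_iter):  # SWAP
        improved = False
        for i, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:i] + medoids[i + 1 :] + [h])
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best, improved = trial, c, True
        if not improved:
            break
    return np.argmin(dist[:, medoids], axis=1)


def pam_choose_k(
    matrix: pd.DataFrame, params: SubcloneParams | None = None
) -> tuple[int, pd.Series, dict, bool]:
    """PAM at each k in [k_min, k_max]; keep the k maximizing average
    silhouette width.

    Returns (k, labels, silhouette profile, low_confidence flag). With <= 2
    cells a degenerate single cluster is returned with a warning.
    """
    params = params or SubcloneParams()
    n = len(matrix)
    if n <= 2:
        warnings.warn("too few cells for PAM: degenerate k=1", stacklevel=2)
        return 1, pd.Series(1, index=matrix.index, name="cluster"), {}, True
    X = matrix.to_numpy(dtype=float)
    dist = squareform(pdist(X, metric="euclidean"))
    profile: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in range(params.k_min, min(params.k_max, n - 1) + 1):
        labels = pam(dist, k)
        if len(np.unique(labels)) < 2:
            continue
        widths = silhouette_samples(dist, labels, metric="precomputed")
        profile[k] = float(widths.mean())
        labelings[k] = labels
    if not profile:
        warnings.warn("no valid k produced >= 2 clusters", stacklevel=2)
        return 1, pd.Series(1, index=matrix.index, name="cluster"), {}, True
    k_best = max(profile, key=lambda k: (profile[k], -k))
    low_confidence = profile[k_best] < 0.25
    labels = pd.Series(labelings[k_best] + 1, index=matrix.index, name="cluster")
    return k_best, labels, profile, low_confidence


def pca_candidate_bins(
    matrix: pd.DataFrame, params: SubcloneParams | None = None
) -> np.ndarray:
    """Select candidate subclonal bins by variance filtering + PCA loadings.

    Drops bins with fewer than ``min_nonzero_elements`` nonzero entries, keeps
    bins whose across-cell variance exceeds ``variance_threshold``, then runs
    centered (unscaled) PCA on the retained bins; a bin is a candidate iff its
    |loading| on any of the first ``n_pcs`` components passes the loading rule
    (relative-to-max by default, per-PC top quantile if ``loading_quantile``
    is set).

    Returns positional bin indices into the input matrix columns.
    """
    params = params or SubcloneParams()
    X = matrix.to_numpy(dtype=float)
    nonzero = (X != 0).sum(axis=0)
    keep = nonzero >= params.min_nonzero_elements
    var = X.var(axis=0, ddof=1) if len(X) > 1 else np.zeros(X.shape[1])
    keep &= var > params.variance_threshold
    retained = np.flatnonzero(keep)
    if retained.size < 2:
        if retained.size < 2:
            warnings.warn("fewer than 2 bins pass the variance filter", stacklevel=2)
        return retained
    Xr = X[:, retained]
    Xc = Xr - Xr.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    n_pcs = min(params.n_pcs, (s > 1e-10).sum())
    selected = np.zeros(retained.size, dtype=bool)
    for pc in range(n_pcs):
        load = np.abs(vt[pc])
        if params.loading_quantile is not None:
            cutoff = np.quantile(load, params.loading_quantile)
        else:
            cutoff = params.loading_rel_threshold * load.max()
        selected |= load >= cutoff
    return retained[selected]


def select_large_events(
    candidate_bins: np.ndarray, grid: BinGrid, params: SubcloneParams | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep candidate runs spanning at least ``min_event_span``.

    Candidates are grouped into maximal runs of genomically adjacent bins on
    one chromosome, tolerating gaps of up to ``gap_tolerance_bins``; a run
    survives iff its genomic span (first bin start to last bin end) is
    >= min_event_span.
    """
    params = params or SubcloneParams()
    candidate_bins = np.sort(np.asarray(candidate_bins, dtype=int))
    selected: list[int] = []
    events = []
    run: list[int] = []

    def flush(run):
        if not run:
            return
        span = grid.end[run[-1]] - grid.start[run[0]]
        if span >= params.min_event_span:
            selected.extend(run)
            events.append(
                {
                    "chrom": grid.chrom[run[0]],
                    "start": int(grid.start[run[0]]),
                    "end": int(grid.end[run[-1]]),
                    "n_bins": len(run),
                }
            )

    for b in candidate_bins:
        if run and (grid.chrom[b] != grid.chrom[run[-1]] or b - run[-1] > params.gap_tolerance_bins + 1):
            flush(run)
            run = []
        run.append(int(b))
    flush(run)
    return (
        np.array(selected, dtype=int),
        pd.DataFrame(events, columns=["chrom", "start", "end", "n_bins"]),
    )


def subpopulation_frequencies(labels: pd.Series) -> tuple[dict, dict]:
    """Cluster frequencies: exact fractions and integer-rounded percentages."""
    if len(labels) == 0:
        raise ValueError("need >= 1 labeled cell")
    counts = labels.value_counts().sort_index()
    total = int(counts.sum())
    fractions = {int(c): int(n) / total for c, n in counts.items()}
    percent = {c: int(round(100.0 * f)) for c, f in fractions.items()}
    return fractions, percent


def assign_subclones(
    matrix: pd.DataFrame,
    grid: BinGrid,
    params: SubcloneParams | None = None,
    reference_labels: pd.Series | None = None,
) -> SubcloneResult:
    """Full subclonal pipeline on a tumor-cell x bin copy-number matrix.

    Runs the variance+PCA bin selection, the >= 1.5 Mb event filter, then
    clusters cells on the selected bins (Ward cut at the PAM-chosen k).
    ``reference_labels`` (e.g. large-scale CN clustering) yields an agreement
    cross-table.
    """
    params = params or SubcloneParams()
    candidates = pca_candidate_bins(matrix, params)
    selected, events = select_large_events(candidates, grid, params)
    if selected.size == 0:
        warnings.warn("no subclonal events >= min_event_span: k=1", stacklevel=2)
        labels = pd.Series(1, index=matrix.index, name="cluster")
        fr, pct = subpopulation_frequencies(labels)
        return SubcloneResult(labels, 1, candidates, selected, events, fr, pct)
    restricted = matrix.iloc[:, selected]
    k, pam_labels, profile, low_conf = pam_choose_k(restricted, params)
    if k > 1:
        _, labels = hierarchical_cluster(restricted, k)
    else:
        labels = pam_labels
    fr, pct = subpopulation_frequencies(labels)
    agreement = None
    if reference_labels is not None:
        agreement = pd.crosstab(
            reference_labels.reindex(labels.index), labels, dropna=False
        )
    return SubcloneResult(
        labels, k, candidates, selected, events, fr, pct, profile, low_conf, agreement
    )
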