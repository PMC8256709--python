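"""Statistical screening of scan profiles: PCA clustering and outlier flags.

A raster scan yields thousands of 1D curves per sample.  Before any
model-based analysis the scan is screened with a signal-classification
workflow: normalize every curve, decompose the population into its first
three principal components, cluster into a handful of subsets, and pick one
least-correlated representative (medoid) per subset.  On laterally
homogeneous tissue the representatives come out nearly identical; regions
of altered structure (e.g. a dried patch without Bragg peaks) separate into
their own subset.  A second screen compares per-sample representative
curves against a control to flag anomalous samples for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .profiles import QProfile, ScanGrid

__all__ = ["SegmentationResult", "segment_scan", "flag_outlier_samples",
           "correlation_distance"]


@dataclass
class SegmentationResult:
    """Clustering of one scan into k subsets with medoid representatives."""

    k: int
    labels: np.ndarray          # (n_rows, n_cols) subset index in [0, k)
    scores: np.ndarray          # (n_pixels, 3) PC coordinates, raster order
    representatives: list[QProfile]
    abundance: np.ndarray       # fraction of pixels per subset, sums to 1
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not np.isclose(self.abundance.sum(), 1.0):
            raise ValueError("abundance must sum to 1")


def _feature_matrix(grid: ScanGrid, modality: str, log_transform: bool | None) -> np.ndarray:
    """Per-pixel feature vectors: (log-)intensity normalized to unit total.

    SAXS curves span decades, so they are log-transformed before
    normalization by default; WAXS curves stay linear.
    """
    X = grid.intensity_matrix()
    if log_transform is None:
        log_transform = modality == "saxs"
    if log_transform:
        X = np.log10(np.maximum(X, 1e-12))
        X = X - X.min(axis=1, keepdims=True)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return X / totals


def segment_scan(
    grid: ScanGrid,
    k: int = 4,
    modality: str | None = None,
    seed: int = 0,
    log_transform: bool | None = None,
    n_components: int = 3,
) -> SegmentationResult:
    """Cluster a scan's profiles into k subsets and extract representatives.

    Pipeline: intensity normalization -> PCA (3 components) -> seeded
    k-means (20 restarts) -> medoid representative per subset (the member
    profile closest to its cluster centroid in PC space).  Deterministic
    for a fixed seed.
    """
    if modality is None:
        modality = grid.profiles[0][0].modality
    n_pixels = len(grid)
    X = _feature_matrix(grid, modality, log_transform)
    n_distinct = np.unique(np.round(X, 12), axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct profile(s)")

    n_comp = min(n_components, n_pixels, X.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    scores_raw = pca.fit_transform(X)
    scores = np.zeros((n_pixels, n_components))
    scores[:, :n_comp] = scores_raw
    evr = np.zeros(n_components)
    evr[:n_comp] = pca.explained_variance_ratio_

    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    flat_labels = km.fit_predict(scores)

    profiles_flat = [p for _, _, p in grid.pixels()]
    reps: list[QProfile] = []
    for j in range(k):
        members = np.flatnonzero(flat_labels == j)
        d = np.linalg.norm(scores[members] - km.cluster_centers_[j], axis=1)
        reps.append(profiles_flat[members[int(np.argmin(d))]])

    abundance = np.bincount(flat_labels, minlength=k) / n_pixels
    labels = flat_labels.reshape(grid.n_rows, grid.n_cols)
    return SegmentationResult(k, labels, scores, reps, abundance, evr)


def correlation_distance(a: QProfile, b: QProfile) -> float:
    """1 - Pearson correlation between two profiles on a common q grid."""
    y1 = a.intensity
    y2 = b.intensity if b.q.shape == a.q.shape and np.allclose(b.q, a.q) \
        else np.interp(a.q, b.q, b.intensity)
    s1, s2 = np.std(y1), np.std(y2)
    if s1 == 0 or s2 == 0:
        return 0.0 if np.allclose(y1, y2) else 2.0
    r = float(np.corrcoef(y1, y2)[0, 1])
    return 1.0 - r


def flag_outlier_samples(
    summaries: dict[str, QProfile],
    reference: QProfile,
    threshold: float | None = None,
    mad_factor: float = 5.0,
) -> list[str]:
    """Flag samples whose representative profile departs from a control.

    Each sample's correlation distance to the reference is computed; with no
    explicit ``threshold`` a sample is flagged when its distance exceeds the
    median across samples by more than ``mad_factor`` median absolute
    deviations (and exceeds a minimal floor, so identical populations never
    flag).
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 samples to screen")
    names = list(summaries)
    d = np.array([correlation_distance(reference, summaries[n]) for n in names])
    if threshold is None:
        med = float(np.median(d))
        mad = float(np.median(np.abs(d - med)))
        threshold = med + mad_factor * max(mad, 1e-3)
    return [n for n, di in zip(names, d) if di > threshold]
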