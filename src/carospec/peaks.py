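"""Peak detection, k-most-important peak selection and class-separation
statistics for the carotenoid standards dataset.

The characteristic peaks shared by the three carotenoid standards are found
by detecting peaks in each compound's mean spectrum, clustering the
detected centers across compounds, and ranking clusters first by how many
compounds contain the band and then by its mean normalized prominence. On
carotenoid fingerprints — where the υ2 (~1160 cm^-1) and υ1 (~1520 cm^-1)
bands are strong and common to all three compounds — the top-2 clusters are
those two bands.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .types import LabeledSpectraSet, Spectrum


@dataclass
class PeakSet:
    """Ranked characteristic peak positions.

    ``scores`` combines the ranking criteria into one non-increasing value:
    integer part = number of classes sharing the band, fractional part =
    mean normalized prominence (compressed into [0, 1)).
    """

    centers: np.ndarray
    scores: np.ndarray
    k: int
    match_tolerance: float = 5.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.centers.size != self.k or self.scores.size != self.k:
            raise ValueError("k must equal the number of peaks")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")
        sorted_centers = np.sort(self.centers)
        if np.any(np.diff(sorted_centers) <= self.match_tolerance) and self.k > 1:
            raise ValueError("peak centers must be unique within the match tolerance")


@dataclass
class SeparationStats:
    """Intra-/inter-class distances and per-class separation ratios."""

    intra: dict = field(default_factory=dict)  # class -> mean pairwise distance
    inter: dict = field(default_factory=dict)  # (class_a, class_b) -> distance of means
    ratio: dict = field(default_factory=dict)  # class -> mean inter / intra
    undefined: list = field(default_factory=list)  # classes with intra == 0


def detect_peaks(spectrum: Spectrum, min_prominence: float = 0.05):
    """Local maxima with topographic prominence >= min_prominence * range.

    Returns a list of (center wavenumber, prominence) sorted by wavenumber.
    """
    y = spectrum.intensities
    span = float(y.max() - y.min())
    if span == 0:
        return []
    idx, props = find_peaks(y, prominence=min_prominence * span)
    return [
        (float(spectrum.wavenumbers[i]), float(p))
        for i, p in zip(idx, props["prominences"])
    ]


def _cluster_centers(entries: list[tuple[float, float, str]], tolerance: float):
    """Greedy single-link clustering of (center, prominence, class) entries
    sorted by center: a peak joins the current cluster while it is within
    ``tolerance`` of the cluster's running mean center."""
    clusters: list[list[tuple[float, float, str]]] = []
    for entry in sorted(entries, key=lambda e: e[0]):
        if clusters:
            current = clusters[-1]
            mean_center = float(np.mean([e[0] for e in current]))
            if abs(entry[0] - mean_center) <= tolerance:
                current.append(entry)
                continue
        clusters.append([entry])
    return clusters


def k_most_important_peaks(
    standards: LabeledSpectraSet,
    k: int = 2,
    tolerance: float = 5.0,
    min_prominence: float = 0.05,
) -> PeakSet:
    """Select the k most important characteristic peaks of the standards.

    Peaks are detected in each class's mean spectrum; prominences are
    normalized per class (so uniform rescaling of one class changes
    nothing); centers are clustered across classes within ``tolerance``;
    each cluster is scored by (number of classes containing it, mean
    normalized prominence) and the top-k cluster centers are returned,
    snapped to the nearest grid point. Raises if fewer than k clusters
    exist.
    """
    grid = standards.shared_grid()
    entries: list[tuple[float, float, str]] = []
    for label in standards.classes:
        idx = standards.indices_of(label)
        mean = np.vstack([standards.spectra[j].intensities for j in idx]).mean(axis=0)
        peaks = detect_peaks(Spectrum(grid, mean), min_prominence)
        if not peaks:
            continue
        max_prom = max(p for _, p in peaks)
        entries.extend((center, prom / max_prom, label) for center, prom in peaks)
    clusters = _cluster_centers(entries, tolerance)
    scored = []
    for cluster in clusters:
        by_class: dict[str, float] = {}
        for center, prom, label in cluster:
            by_class[label] = max(by_class.get(label, 0.0), prom)
        share = len(by_class)
        mean_prom = float(np.mean(list(by_class.values())))
        center = float(np.mean([c for c, _, _ in cluster]))
        center = float(grid[np.argmin(np.abs(grid - center))])
        # lexicographic (share, prominence) folded into one float; prominence
        # is compressed below 1 so share count always dominates
        score = share + min(mean_prom, 1.0) * (1.0 - 1e-9)
        scored.append((score, center))
    if len(scored) < k:
        raise ValueError(f"only {len(scored)} peak clusters found, k={k} requested")
    scored.sort(key=lambda t: (-t[0], t[1]))
    top = scored[:k]
    return PeakSet(
        centers=np.array([c for _, c in top]),
        scores=np.array([s for s, _ in top]),
        k=k,
        match_tolerance=tolerance,
    )


def class_separation_stats(
    dataset: LabeledSpectraSet, normalization: str = "l2"
) -> SeparationStats:
    """Euclidean intra-/inter-class distances on (optionally unit-L2
    normalized) spectra, and per-class separation ratios.

    intra(class) = mean pairwise distance within the class;
    inter(a, b) = distance between the class mean spectra;
    ratio(class) = mean of that class's inter distances / its intra
    distance, flagged undefined when intra = 0.
    """
    if normalization not in ("l2", "none"):
        raise ValueError("normalization must be 'l2' or 'none'")
    dataset.shared_grid()
    stats = SeparationStats()
    vectors: dict[str, np.ndarray] = {}
    for label in dataset.classes:
        idx = dataset.indices_of(label)
        if idx.size < 2:
            raise ValueError(f"class {label!r} needs at least 2 spectra")
        mat = np.vstack([dataset.spectra[j].intensities for j in idx]).astype(float)
        if normalization == "l2":
            norms = np.linalg.norm(mat, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            mat = mat / norms
        vectors[label] = mat
        pair_d = [
            float(np.linalg.norm(mat[a] - mat[b]))
            for a, b in itertools.combinations(range(mat.shape[0]), 2)
        ]
        stats.intra[label] = float(np.mean(pair_d))
    labels = list(vectors)
    for a, b in itertools.combinations(labels, 2):
        dist = float(np.linalg.norm(vectors[a].mean(axis=0) - vectors[b].mean(axis=0)))
        stats.inter[(a, b)] = dist
    for label in labels:
        inters = [d for pair, d in stats.inter.items() if label in pair]
        mean_inter = float(np.mean(inters)) if inters else np.nan
        if stats.intra[label] == 0:
            stats.ratio[label] = float("nan")
            stats.undefined.append(label)
        else:
            stats.ratio[label] = mean_inter / stats.intra[label]
    return stats


def peak_intensity(spectrum: Spectrum, center: float, tolerance: float = 5.0) -> float:
    """Maximum intensity within ±tolerance of ``center`` (window-max rather
    than nearest-point lookup, tolerating small band shifts)."""
    w = spectrum.wavenumbers
    if center < w[0] or center > w[-1]:
        raise ValueError(f"center {center} outside grid span [{w[0]}, {w[-1]}]")
    mask = np.abs(w - center) <= tolerance
    if not np.any(mask):  # pragma: no cover - center in span implies a point nearby
        raise ValueError(f"no grid points within ±{tolerance} of {center}")
    return float(spectrum.intensities[mask].max())
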