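"""Knee-point triage of Raman-map spectra into informative and
non-informative groups.

Each pixel spectrum gets a score f = sum of its intensities at the
characteristic carotenoid peaks (window-max within the match tolerance,
computed on the raw, pre-baseline spectra); the scores of one map form a
vector F. Sorting F and locating the knee of the sorted curve splits the
map into a low-signal group (before and at the knee: non-informative,
discarded) and a carotenoid-bearing group (strictly after the knee). The
knee is the point of maximum perpendicular distance to the chord joining
the curve's endpoints, after normalizing both axes to [0, 1]
(Kneedle-style, deterministic, ties broken toward the larger index).

Scores are computed before baseline correction, but cosmic-ray spikes are
removed from the scored copy first (``despike_before_scoring``, on by
default): a single spike inside a scoring window otherwise stretches the
[0, 1] normalization of the sorted curve so far that the knee degenerates
to the outlier. The spectra handed on to later stages stay raw; full
preprocessing is applied downstream to the informative group only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peaks import PeakSet
from .preprocess import PreprocessParams, despike
from .types import RamanMap, Spectrum

#: Normalized-distance floor below which a sorted curve has no usable knee.
DEGENERATE_TOL = 1e-9


@dataclass
class KneeResult:
    index: int
    degenerate: bool


def knee_point(sorted_values) -> KneeResult:
    """Knee of an ascending vector: the index maximizing perpendicular
    distance from (i, v_i) to the chord joining the endpoints, both axes
    normalized to [0, 1]; ties broken toward the larger index.

    All-equal input (or a curve indistinguishable from its chord, e.g. a
    strictly linear ramp) is degenerate: the knee is placed at n-1 so that
    nothing lies after it.
    """
    v = np.asarray(sorted_values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("knee_point needs a 1-D vector of length >= 3")
    if np.any(np.diff(v) < 0):
        raise ValueError("knee_point expects an ascending vector")
    n = v.size
    span = v[-1] - v[0]
    if span == 0:
        return KneeResult(index=n - 1, degenerate=True)
    x = np.arange(n) / (n - 1)
    y = (v - v[0]) / span
    # chord runs from (0, 0) to (1, 1); perpendicular distance ∝ |y - x|
    dist = np.abs(y - x) / np.sqrt(2.0)
    idx = int(n - 1 - np.argmax(dist[::-1]))  # argmax, ties toward larger index
    if dist[idx] < DEGENERATE_TOL:
        return KneeResult(index=n - 1, degenerate=True)
    return KneeResult(index=idx, degenerate=False)


@dataclass
class InformativeScore:
    """Per-map triage record: scores, sort order and knee position."""

    f: np.ndarray  # per-pixel summed peak intensity, pixel order
    order: np.ndarray  # permutation sorting f ascending (stable)
    knee_index: int  # knee position on the sorted curve
    degenerate: bool

    @property
    def sorted_f(self) -> np.ndarray:
        return self.f[self.order]

    @property
    def informative_indices(self) -> np.ndarray:
        """Pixel indices of spectra strictly after the knee, ascending."""
        return np.sort(self.order[self.knee_index + 1 :])


def score_spectra(
    rmap: RamanMap,
    peaks: PeakSet,
    despike_before_scoring: bool = True,
    params: PreprocessParams | None = None,
) -> InformativeScore:
    """Score every pixel spectrum of a map by its summed characteristic-peak
    intensity (window-max per peak) and locate the knee of the sorted score
    curve. Scoring uses pre-baseline intensities; with
    ``despike_before_scoring`` (default) cosmic-ray spikes are removed from
    the scored copy so one spike cannot dominate the curve normalization.
    """
    w = rmap.wavenumbers
    for center in peaks.centers:
        if center < w[0] or center > w[-1]:
            raise ValueError(f"peak {center} cm^-1 outside the map's grid span")
    scored = rmap.intensities
    if despike_before_scoring:
        scored = np.vstack(
            [
                despike(Spectrum(w, row), params)[0].intensities
                for row in rmap.intensities
            ]
        )
    f = np.zeros(rmap.n_pixels)
    for center in peaks.centers:
        mask = np.abs(w - center) <= peaks.match_tolerance
        f += scored[:, mask].max(axis=1)
    order = np.argsort(f, kind="stable")
    knee = knee_point(f[order])
    return InformativeScore(f=f, order=order, knee_index=knee.index,
                            degenerate=knee.degenerate)


@dataclass
class FilterResult:
    """Outcome of triaging one map."""

    informative: list  # informative pixel spectra (raw), pixel order
    pixel_indices: np.ndarray  # their row-major pixel indices
    mask: np.ndarray  # (ny, nx) bool, True = informative
    n_noninformative: int
    score: InformativeScore


def filter_informative(
    rmap: RamanMap,
    peaks: PeakSet,
    despike_before_scoring: bool = True,
    params: PreprocessParams | None = None,
) -> FilterResult:
    """Split a map into informative and non-informative spectra by the
    knee-point rule; degenerate maps yield zero informative spectra.
    The returned informative spectra are the raw pixel spectra (triage
    precedes baseline correction and despiking of the retained group)."""
    score = score_spectra(rmap, peaks, despike_before_scoring, params)
    idx = score.informative_indices
    mask = np.zeros(rmap.n_pixels, dtype=bool)
    mask[idx] = True
    informative = [
        Spectrum(
            rmap.wavenumbers.copy(),
            rmap.intensities[i].copy(),
            {"pixel_index": int(i), "line_id": rmap.line_id},
        )
        for i in idx
    ]
    return FilterResult(
        informative=informative,
        pixel_indices=idx,
        mask=mask.reshape(rmap.ny, rmap.nx),
        n_noninformative=rmap.n_pixels - idx.size,
        score=score,
    )
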