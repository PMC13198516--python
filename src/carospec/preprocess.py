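"""Spectral preprocessing: arPLS baseline correction, modified-z-score
despiking, noisy-spectrum discard, interpolation and feature scaling.

arPLS (asymmetrically reweighted penalized least squares, Baek et al.)
estimates a smooth baseline by iteratively reweighted ridge regression with
a second-difference penalty: points far above the current baseline get
vanishing weight via a logistic of the residual, so peaks do not drag the
baseline up. Despiking follows the Whitaker-Hayes idea — cosmic rays are
narrow, so the modified z-score of the first differences isolates them —
with a confirmation step against the local non-candidate mean so that the
clean neighbours of a spike are not flagged and 2-point-wide spikes are
fully caught.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded
from sklearn.exceptions import NotFittedError
from sklearn.preprocessing import MinMaxScaler

from .types import LabeledSpectraSet, Spectrum

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Tunable preprocessing parameters (all method defaults, none are
    prescribed by the measurement itself).

    arpls_lambda
        Baseline smoothness weight λ; larger = stiffer baseline.
    arpls_ratio
        Relative change of the weight vector at which iteration stops.
    spike_z_threshold
        Modified z-score cutoff for spike candidates (6 is the reference
        value for the method).
    spike_window
        Half-width (points) of the neighbourhood used both to confirm a
        candidate and to compute the replacement mean.
    outlier_threshold
        Minimum Pearson correlation with the class mean; spectra below it
        are discarded as noisy.
    """

    arpls_lambda: float = 1e5
    arpls_ratio: float = 1e-6
    arpls_max_iter: int = 50
    spike_z_threshold: float = 6.0
    spike_window: int = 3
    outlier_method: str = "pearson_to_mean"
    outlier_threshold: float = 0.9

    def __post_init__(self) -> None:
        if min(self.arpls_lambda, self.arpls_ratio, self.spike_z_threshold) <= 0:
            raise ValueError("arPLS and despike parameters must be positive")
        if self.arpls_max_iter < 1 or self.spike_window < 1:
            raise ValueError("arpls_max_iter and spike_window must be >= 1")


def arpls_baseline(
    spectrum: Spectrum, params: PreprocessParams | None = None
) -> tuple[Spectrum, Spectrum]:
    """Estimate a smooth baseline by arPLS; returns (baseline, corrected).

    Solves (W + λ DᵀD) z = W y with D the second-difference operator and W
    the diagonal of logistic weights
    w_i = 1 / (1 + exp(2 (d_i − (2σ_d − μ_d)) / σ_d)), d = y − z,
    where μ_d, σ_d are the mean and standard deviation of the negative
    residuals; iterates until the weight vector changes by less than
    ``arpls_ratio`` (relative L2) or ``arpls_max_iter`` is reached, in which
    case the last iterate is returned with a logged warning.
    """
    params = params or PreprocessParams()
    y = spectrum.intensities
    n = y.size
    if n < 10:
        raise ValueError("arPLS needs at least 10 points")
    diff2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = (params.arpls_lambda * (diff2.T @ diff2)).tocsc()
    # symmetric pentadiagonal system solved in banded form (lower storage)
    bands = np.zeros((3, n))
    bands[0] = penalty.diagonal(0)
    bands[1, : n - 1] = penalty.diagonal(-1)
    bands[2, : n - 2] = penalty.diagonal(-2)
    w = np.ones(n)
    z = y.astype(float)
    converged = False
    for _ in range(params.arpls_max_iter):
        ab = bands.copy()
        ab[0] += w
        z = solveh_banded(ab, w * y, lower=True)
        d = y - z
        neg = d[d < 0]
        if neg.size == 0:
            converged = True
            break
        mean_neg = neg.mean()
        std_neg = neg.std()
        if std_neg == 0:
            converged = True
            break
        exponent = np.clip(2.0 * (d - (2.0 * std_neg - mean_neg)) / std_neg, -500, 500)
        w_new = 1.0 / (1.0 + np.exp(exponent))
        if np.linalg.norm(w - w_new) / np.linalg.norm(w) < params.arpls_ratio:
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        logger.warning(
            "arPLS did not converge in %d iterations; using last iterate",
            params.arpls_max_iter,
        )
    baseline = spectrum.with_intensities(z)
    corrected = spectrum.with_intensities(y - z, baseline_corrected=True)
    return baseline, corrected


def despike(
    spectrum: Spectrum, params: PreprocessParams | None = None
) -> tuple[Spectrum, np.ndarray]:
    """Remove cosmic-ray spikes; returns (clean spectrum, spike indices).

    First differences ΔI are scored with the modified z-score
    z = 0.6745 (ΔI − median ΔI) / MAD(ΔI); both endpoints of any difference
    with |z| above the threshold become candidates. Candidates are then
    confirmed as spikes only if (i) their run of consecutive candidates is
    short enough to be a cosmic ray (longer runs are steep flanks of real
    Raman bands, which also produce large difference z-scores), and (ii)
    the point deviates from the straight line joining its nearest
    non-candidate neighbours by more than the threshold on the MAD scale.
    Confirmed points are replaced by the mean of the non-spike neighbours
    within ±``spike_window`` (widened if necessary). A constant spectrum
    (MAD = 0) is returned unchanged.
    """
    params = params or PreprocessParams()
    y = spectrum.intensities
    n = y.size
    window = params.spike_window
    if n < 2 * window + 2:
        raise ValueError(f"despike needs at least {2 * window + 2} points")
    dy = np.diff(y)
    med = np.median(dy)
    mad = np.median(np.abs(dy - med))
    if mad == 0:
        return spectrum.copy(), np.array([], dtype=int)
    z = 0.6745 * (dy - med) / mad
    big = np.abs(z) > params.spike_z_threshold
    candidates: set[int] = set()
    for i in np.nonzero(big)[0]:  # diff i joins points i and i+1
        candidates.add(int(i))
        candidates.add(int(i) + 1)
    scale = mad / 0.6745
    max_run = 4 * window  # a cosmic ray spans 1-2 points plus its two edges
    spikes: list[int] = []
    run: list[int] = []
    for j in sorted(candidates) + [n + 1]:  # sentinel flushes the last run
        if run and j != run[-1] + 1:
            if len(run) <= max_run:
                for p in run:
                    left, right = p - 1, p + 1
                    while left >= 0 and left in candidates:
                        left -= 1
                    while right < n and right in candidates:
                        right += 1
                    if left < 0 and right >= n:
                        continue
                    if left < 0:
                        estimate = y[right]
                    elif right >= n:
                        estimate = y[left]
                    else:
                        frac = (p - left) / (right - left)
                        estimate = y[left] + (y[right] - y[left]) * frac
                    if abs(y[p] - estimate) > params.spike_z_threshold * scale:
                        spikes.append(p)
            run = []
        run.append(j)
    spike_idx = np.array(spikes, dtype=int)
    clean = y.copy()
    spike_set = set(spikes)
    for j in spikes:
        half = window
        while True:
            lo, hi = max(0, j - half), min(n, j + half + 1)
            neighbours = [k for k in range(lo, hi) if k not in spike_set]
            if neighbours:
                clean[j] = float(np.mean(y[neighbours]))
                break
            half += window
    return spectrum.with_intensities(clean), spike_idx


def preprocess_spectrum(
    spectrum: Spectrum, params: PreprocessParams | None = None
) -> Spectrum:
    """Full per-spectrum correction: arPLS baseline subtraction followed by
    despiking."""
    params = params or PreprocessParams()
    _, corrected = arpls_baseline(spectrum, params)
    clean, _ = despike(corrected, params)
    return clean


def discard_outliers(
    dataset: LabeledSpectraSet, params: PreprocessParams | None = None
) -> tuple[LabeledSpectraSet, list[int]]:
    """Drop spectra that deviate strongly from their class mean.

    Per class (single pass): compute the mean spectrum, then discard every
    spectrum whose Pearson correlation with that mean is below
    ``outlier_threshold``. Raises if a class would lose all its spectra.
    Returns (kept set, discarded indices into the input order).
    """
    params = params or PreprocessParams()
    dataset.shared_grid()
    discarded: list[int] = []
    for label in dataset.classes:
        idx = dataset.indices_of(label)
        if idx.size < 3:
            raise ValueError(f"class {label!r} has fewer than 3 spectra")
        mat = np.vstack([dataset.spectra[k].intensities for k in idx])
        mean = mat.mean(axis=0)
        mean_centered = mean - mean.mean()
        denom_mean = np.linalg.norm(mean_centered)
        dropped_here = 0
        for row, k in zip(mat, idx):
            centered = row - row.mean()
            denom = np.linalg.norm(centered) * denom_mean
            corr = float(centered @ mean_centered / denom) if denom > 0 else np.nan
            if not np.isfinite(corr) or corr < params.outlier_threshold:
                discarded.append(int(k))
                dropped_here += 1
        if dropped_here == idx.size:
            raise ValueError(f"outlier discard would empty class {label!r}")
    if discarded:
        logger.info("discarding %d outlier spectra: %s", len(discarded), discarded)
    keep = [k for k in range(len(dataset)) if k not in set(discarded)]
    return dataset.subset(keep), discarded


def interpolate_to_grid(spectrum: Spectrum, target_grid) -> Spectrum:
    """Linear interpolation onto ``target_grid`` (no extrapolation)."""
    target = np.asarray(target_grid, dtype=float)
    w = spectrum.wavenumbers
    if target[0] < w[0] or target[-1] > w[-1]:
        raise ValueError(
            f"target grid [{target[0]}, {target[-1]}] extends beyond the "
            f"source span [{w[0]}, {w[-1]}]"
        )
    return Spectrum(target.copy(), np.interp(target, w, spectrum.intensities),
                    dict(spectrum.meta))


def default_feature_grid(n_features: int = 412,
                         lo: float = 900.0, hi: float = 1700.0) -> np.ndarray:
    """The common wavenumber grid model inputs are interpolated onto
    (412 features over the 900-1700 cm^-1 fingerprint window)."""
    return np.linspace(lo, hi, n_features)


class FeatureScaler:
    """Per-feature min-max scaling to [0, 1], fit on training data only.

    Thin wrapper over scikit-learn's ``MinMaxScaler`` that turns
    use-before-fit into an explicit error and maps constant features to 0.
    The fitted object carries only training statistics, so applying it to a
    test split cannot leak test information.
    """

    def __init__(self) -> None:
        self._scaler = MinMaxScaler(feature_range=(0.0, 1.0), clip=False)
        self._fitted = False

    def fit(self, features: np.ndarray) -> "FeatureScaler":
        self._scaler.fit(np.asarray(features, dtype=float))
        self._fitted = True
        return self

    def _check(self) -> None:
        if not self._fitted:
            raise RuntimeError("FeatureScaler must be fit before use")

    def transform(self, features: np.ndarray) -> np.ndarray:
        self._check()
        try:
            return self._scaler.transform(np.asarray(features, dtype=float))
        except NotFittedError as exc:  # pragma: no cover - guarded above
            raise RuntimeError("FeatureScaler must be fit before use") from exc

    def fit_transform(self, features: np.ndarray) -> np.ndarray:
        return self.fit(features).transform(features)

    def inverse_transform(self, features: np.ndarray) -> np.ndarray:
        self._check()
        return self._scaler.inverse_transform(np.asarray(features, dtype=float))

    @property
    def data_min_(self) -> np.ndarray:
        self._check()
        return self._scaler.data_min_

    @property
    def data_max_(self) -> np.ndarray:
        self._check()
        return self._scaler.data_max_
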