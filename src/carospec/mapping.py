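"""Rendering carotenoid distribution images from Raman maps.

A map image assigns each pixel the intensity of the carotenoid ν(C=C)
stretch, summarized over the 1500-1560 cm^-1 spectral window (default:
window maximum of the baseline-corrected spectrum, robust to small band
shifts; alternative: trapezoidal integral over the window).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import PreprocessParams, arpls_baseline, despike
from .types import RamanMap, Spectrum

DEFAULT_WINDOW = (1500.0, 1560.0)


def render_carotenoid_map(
    rmap: RamanMap,
    window: tuple = DEFAULT_WINDOW,
    statistic: str = "max",
    baseline_correct: bool = True,
    despike_first: bool = True,
    params: PreprocessParams | None = None,
) -> np.ndarray:
    """Per-pixel intensity image (ny, nx) over a spectral window.

    ``statistic`` is ``"max"`` (window maximum) or ``"integral"``
    (trapezoidal integral over the window). With ``baseline_correct`` the
    arPLS-corrected spectrum is summarized instead of the raw one; with
    ``despike_first`` cosmic rays are removed before summarizing, so a
    single spike inside the window cannot dominate the color scale.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError(f"empty window ({lo}, {hi})")
    w = rmap.wavenumbers
    mask = (w >= lo) & (w <= hi)
    if not np.any(mask):
        raise ValueError(f"window ({lo}, {hi}) contains no grid points")
    if statistic not in ("max", "integral"):
        raise ValueError("statistic must be 'max' or 'integral'")
    values = np.empty(rmap.n_pixels)
    for idx in range(rmap.n_pixels):
        y = rmap.intensities[idx]
        if despike_first:
            clean, _ = despike(Spectrum(w, y), params)
            y = clean.intensities
        if baseline_correct:
            _, corrected = arpls_baseline(Spectrum(w, y), params)
            y = corrected.intensities
        if statistic == "max":
            values[idx] = y[mask].max()
        else:
            values[idx] = np.trapezoid(y[mask], w[mask])
    return values.reshape(rmap.ny, rmap.nx)


def export_map_image(
    image: np.ndarray, path, colormap: str = "inferno", step_um: float | None = None
) -> tuple[Path, Path]:
    """Write the rendered image as a PNG (with colorbar spanning the data
    min/max) plus a CSV of the raw pixel values; returns both paths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    fig, ax = plt.subplots(figsize=(5, 4))
    extent = None
    if step_um is not None:
        extent = (0, image.shape[1] * step_um, image.shape[0] * step_um, 0)
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
    im = ax.imshow(
        image,
        cmap=colormap,
        vmin=float(image.min()),
        vmax=float(image.max()),
        extent=extent,
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, label="Raman intensity (counts)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    np.savetxt(csv_path, image, delimiter=",", fmt="%.17g")
    return path, csv_path
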