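"""Core containers: spectra, Raman maps, label tables and labeled spectra sets.

A :class:`Spectrum` is one wavenumber-indexed intensity trace; a
:class:`RamanMap` is a rectangular grid of spectra sharing one wavenumber
grid (one spectrum per pixel); a :class:`LabelTable` holds the per-cell-line
carotenoid composition (fractions of astaxanthin, canthaxanthin and
β-carotene) used as regression targets; a :class:`LabeledSpectraSet` bundles
spectra with class labels and composition vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

#: The three carotenoid components, in fixed target-column order.
COMPONENTS = ("astaxanthin", "canthaxanthin", "betacarotene")


class SpectrumError(ValueError):
    """Raised when a spectrum violates its structural invariants."""


class MapStructureError(ValueError):
    """Raised when a Raman map is structurally inconsistent."""


class LabelTableError(ValueError):
    """Raised when a label table violates its invariants."""


@dataclass
class Spectrum:
    """One Raman spectrum: a strictly increasing wavenumber grid (cm^-1)
    with intensity counts, plus free-form acquisition metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        w, y = self.wavenumbers, self.intensities
        if w.ndim != 1 or y.ndim != 1:
            raise SpectrumError("wavenumbers and intensities must be 1-D")
        if w.shape != y.shape:
            raise SpectrumError(
                f"length mismatch: {w.size} wavenumbers vs {y.size} intensities"
            )
        if w.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not np.all(np.diff(w) > 0):
            raise SpectrumError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise SpectrumError("intensities must be finite")
        if not np.all(np.isfinite(w)):
            raise SpectrumError("wavenumbers must be finite")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), self.intensities.copy(), dict(self.meta))

    def with_intensities(self, intensities: np.ndarray, **meta) -> "Spectrum":
        """New spectrum on the same grid with replaced intensities."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float), new_meta)


@dataclass
class RamanMap:
    """Rectangular grid of spectra sharing one wavenumber grid.

    Pixels are stored row-major with x fastest: pixel (i, j) — column i,
    row j, origin top-left — lives at row ``j * nx + i`` of ``intensities``.
    ``step_um`` is the spatial step between adjacent pixels in µm.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray  # shape (nx * ny, n_points)
    nx: int
    ny: int
    step_um: float = 1.0
    line_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise MapStructureError("nx and ny must be >= 1")
        if self.intensities.ndim != 2:
            raise MapStructureError("intensities must be 2-D (pixels x points)")
        if self.intensities.shape[0] != self.nx * self.ny:
            raise MapStructureError(
                f"expected {self.nx * self.ny} pixel spectra "
                f"(nx={self.nx}, ny={self.ny}), got {self.intensities.shape[0]}"
            )
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise MapStructureError("pixel spectra do not match the wavenumber grid")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise MapStructureError("wavenumber grid must be strictly increasing")

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    def pixel_index(self, i: int, j: int) -> int:
        """Row-major index of pixel (i, j): x fastest."""
        if not (0 <= i < self.nx and 0 <= j < self.ny):
            raise IndexError(f"pixel ({i}, {j}) outside {self.nx}x{self.ny} map")
        return j * self.nx + i

    def pixel(self, i: int, j: int) -> Spectrum:
        idx = self.pixel_index(i, j)
        return Spectrum(
            self.wavenumbers.copy(),
            self.intensities[idx].copy(),
            {"pixel": (i, j), "line_id": self.line_id},
        )

    def spectra(self) -> Iterator[Spectrum]:
        for j in range(self.ny):
            for i in range(self.nx):
                yield self.pixel(i, j)

    def transpose(self) -> "RamanMap":
        """Swap x and y axes: pixel (i, j) becomes pixel (j, i)."""
        cube = self.intensities.reshape(self.ny, self.nx, -1)
        swapped = np.ascontiguousarray(np.swapaxes(cube, 0, 1))
        return RamanMap(
            self.wavenumbers.copy(),
            swapped.reshape(self.nx * self.ny, -1),
            nx=self.ny,
            ny=self.nx,
            step_um=self.step_um,
            line_id=self.line_id,
            meta=dict(self.meta),
        )


@dataclass
class LabelTable:
    """Per-cell-line carotenoid composition used as regression labels.

    One row per line: (line_id, astaxanthin, canthaxanthin, betacarotene)
    with fractions in [0, 1]. Pure standards appear as one-hot rows.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        cols = ["line_id", *COMPONENTS]
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise LabelTableError(f"label table missing columns: {missing}")
        self.frame = self.frame.loc[:, cols].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        ids = self.frame["line_id"].astype(str)
        dup = ids[ids.duplicated()].tolist()
        if dup:
            raise LabelTableError(f"duplicate line_id: {dup}")
        vals = self.frame[list(COMPONENTS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise LabelTableError("fractions must be finite")
        if np.any(vals < 0.0) or np.any(vals > 1.0):
            bad = self.frame.loc[np.any((vals < 0) | (vals > 1), axis=1), "line_id"]
            raise LabelTableError(
                f"fractions outside [0, 1] for line(s): {bad.tolist()}"
            )

    @property
    def line_ids(self) -> list[str]:
        return self.frame["line_id"].astype(str).tolist()

    def fractions_for(self, line_id: str) -> np.ndarray:
        rows = self.frame.loc[self.frame["line_id"].astype(str) == str(line_id)]
        if rows.empty:
            raise KeyError(f"line_id {line_id!r} not in label table")
        return rows[list(COMPONENTS)].to_numpy(dtype=float)[0]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class LabeledSpectraSet:
    """Spectra plus class labels and 3-component composition vectors."""

    spectra: list
    labels: list
    fractions: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        n = len(self.spectra)
        if len(self.labels) != n or self.fractions.shape != (n, 3):
            raise ValueError(
                f"inconsistent set: {n} spectra, {len(self.labels)} labels, "
                f"fractions shape {self.fractions.shape}"
            )

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def indices_of(self, label: str) -> np.ndarray:
        return np.array([k for k, lab in enumerate(self.labels) if lab == label], int)

    def subset(self, indices) -> "LabeledSpectraSet":
        indices = np.asarray(indices, int)
        return LabeledSpectraSet(
            [self.spectra[k] for k in indices],
            [self.labels[k] for k in indices],
            self.fractions[indices],
        )

    def shared_grid(self) -> np.ndarray:
        """Common wavenumber grid of all spectra; error if grids differ."""
        grid = self.spectra[0].wavenumbers
        for k, s in enumerate(self.spectra[1:], start=1):
            if s.wavenumbers.shape != grid.shape or not np.allclose(
                s.wavenumbers, grid, rtol=0, atol=1e-9
            ):
                raise ValueError(f"spectrum {k} is not on the common grid")
        return grid

    def intensity_matrix(self) -> np.ndarray:
        self.shared_grid()
        return np.vstack([s.intensities for s in self.spectra])
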