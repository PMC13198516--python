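"""Representative spectra per cell line and training-set assembly.

The informative spectra of one cell line (pooled over all its maps) are
summarized by repeated random-half averaging: ``n_rep`` times, a random
half of the N informative spectra is drawn without replacement and
averaged, yielding ``n_rep`` representative spectra per line (default 10,
so 7 lines give 70 training rows). Standards spectra contribute one-hot
composition targets; line representatives carry the line's composition
from the label table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import default_feature_grid, interpolate_to_grid
from .types import LabeledSpectraSet, LabelTable, Spectrum


@dataclass
class RepresentativeSet:
    """The representative spectra of one cell line."""

    line_id: str
    n_informative: int  # N: informative spectra pooled over the line's maps
    n_rep: int
    fraction: float
    seed: int | None
    spectra: list  # n_rep averaged spectra
    label: np.ndarray | None = None  # 3-component composition


def representative_spectra(
    informative,
    line_id: str,
    n_rep: int = 10,
    fraction: float = 0.5,
    seed=0,
    label=None,
) -> RepresentativeSet:
    """Build ``n_rep`` representative spectra by random-subsample averaging.

    Each representative is the arithmetic mean of ``ceil(fraction * N)``
    distinct informative spectra, drawn uniformly without replacement;
    draws are independent across repeats. Deterministic under ``seed``.
    """
    informative = list(informative)
    n = len(informative)
    if n < 2:
        raise ValueError(f"line {line_id!r}: need >= 2 informative spectra, got {n}")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    grid = informative[0].wavenumbers
    mat = np.vstack([s.intensities for s in informative])
    for k, s in enumerate(informative[1:], start=1):
        if s.wavenumbers.shape != grid.shape or not np.allclose(s.wavenumbers, grid):
            raise ValueError(f"line {line_id!r}: spectrum {k} not on the common grid")
    size = math.ceil(fraction * n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = []
    for r in range(n_rep):
        idx = rng.choice(n, size=size, replace=False)
        reps.append(
            Spectrum(
                grid.copy(),
                mat[idx].mean(axis=0),
                {"line_id": line_id, "replicate": r, "subsample_size": size},
            )
        )
    seed_val = int(seed) if isinstance(seed, (int, np.integer)) else None
    return RepresentativeSet(
        line_id=line_id,
        n_informative=n,
        n_rep=n_rep,
        fraction=fraction,
        seed=seed_val,
        spectra=reps,
        label=None if label is None else np.asarray(label, dtype=float),
    )


@dataclass
class Dataset:
    """Assembled model input: features, multi-output targets, row identity."""

    features: np.ndarray  # (n, n_features)
    targets: np.ndarray  # (n, 3)
    row_ids: list
    grid: np.ndarray

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if self.targets.shape[0] != n or len(self.row_ids) != n:
            raise ValueError("rows of features, targets and row_ids must align")


def assemble_dataset(
    standards: LabeledSpectraSet,
    representatives,
    labels: LabelTable,
    grid=None,
) -> Dataset:
    """Interpolate standards + representatives onto the common feature grid
    and pair them with their composition targets.

    Standards keep their one-hot composition; each representative row takes
    its line's fractions from the label table (a missing line is an error).
    """
    grid = default_feature_grid() if grid is None else np.asarray(grid, dtype=float)
    rows, targets, row_ids = [], [], []
    for spec, label, frac in zip(standards.spectra, standards.labels, standards.fractions):
        rows.append(interpolate_to_grid(spec, grid).intensities)
        targets.append(frac)
        row_ids.append(label)
    for rep_set in representatives:
        frac = labels.fractions_for(rep_set.line_id)  # KeyError if missing
        for spec in rep_set.spectra:
            rows.append(interpolate_to_grid(spec, grid).intensities)
            targets.append(frac)
            row_ids.append(rep_set.line_id)
    return Dataset(
        features=np.vstack(rows) if rows else np.empty((0, grid.size)),
        targets=np.asarray(targets, dtype=float).reshape(len(rows), 3),
        row_ids=row_ids,
        grid=grid,
    )
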