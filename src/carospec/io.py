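"""Plain-text I/O for spectra, Raman maps and label tables.

Formats
-------
Spectrum
    Two-column text (wavenumber cm^-1, intensity counts), as exported by
    confocal Raman software. Optional ``#``-prefixed header lines are
    ignored on read (``# key: value`` pairs are collected into ``meta``).
    Delimiter is auto-detected in the order tab, comma, whitespace; a
    decimal comma is accepted when the column delimiter is not a comma.
    Files written with descending wavenumbers are silently reordered
    (a common export option) with a logged notice.
Raman map
    A directory of ``pixel_%05d.txt`` spectra (row-major, x fastest,
    origin top-left) plus a ``map.yaml`` sidecar recording nx, ny,
    step_um and line_id; alternatively a single CSV with a wavenumber
    column followed by one column per pixel.
Label table
    CSV with header ``line_id,astaxanthin,canthaxanthin,betacarotene``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    COMPONENTS,
    LabelTable,
    LabelTableError,
    MapStructureError,
    RamanMap,
    Spectrum,
    SpectrumError,
)

logger = logging.getLogger(__name__)


class SpectrumParseError(ValueError):
    """A text spectrum file contained a row that could not be parsed."""


def _split_row(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        return line.split()
    return [f.strip() for f in line.split(delimiter)]

def _parse_float(field: str, decimal_comma_ok: bool) -> float:
    if decimal_comma_ok and "," in field:
        field = field.replace(",", ".")
    return float(field)


def _detect_delimiter(line: str) -> str | None:
    """First dialect (tab, comma, whitespace) whose split of `line` parses
    as two floats fixes the dialect. Returns None for whitespace."""
    for delim in ("\t", ","):
        fields = _split_row(line, delim)
        if len(fields) == 2:
            try:
                _parse_float(fields[0], delim != ",")
                _parse_float(fields[1], delim != ",")
                return delim
            except ValueError:
                pass
    fields = line.split()
    if len(fields) == 2:
        try:
            _parse_float(fields[0], True)
            _parse_float(fields[1], True)
            return None
        except ValueError:
            pass
    raise SpectrumParseError(f"cannot detect a two-column dialect from: {line!r}")


def read_spectrum_txt(path) -> Spectrum:
    """Read one spectrum from a two-column text file.

    Raises :class:`SpectrumParseError` naming the offending line on a
    malformed row, and :class:`SpectrumError` if the grid contains
    duplicate wavenumbers after sorting.
    """
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    delimiter: str | None = None
    dialect_fixed = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if not dialect_fixed:
                delimiter = _detect_delimiter(line)
                dialect_fixed = True
            fields = _split_row(line, delimiter)
            if len(fields) != 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                w = _parse_float(fields[0], delimiter != ",")
                y = _parse_float(fields[1], delimiter != ",")
            except ValueError as exc:
                raise SpectrumParseError(f"{path}: line {lineno}: {exc}") from None
            rows.append((w, y))
    if len(rows) < 2:
        raise SpectrumParseError(f"{path}: need at least 2 data rows, got {len(rows)}")
    arr = np.asarray(rows, dtype=float)
    wav, inten = arr[:, 0], arr[:, 1]
    if np.any(np.diff(wav) < 0):
        order = np.argsort(wav, kind="stable")
        wav, inten = wav[order], inten[order]
        logger.info("%s: wavenumbers not ascending; reordered", path)
    if np.any(np.diff(wav) == 0):
        raise SpectrumError(f"{path}: duplicate wavenumbers in grid")
    meta["source"] = str(path)
    return Spectrum(wav, inten, meta)


def write_spectrum_txt(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column whitespace-delimited text at full
    double precision; ``meta`` entries become ``# key: value`` headers."""
    spectrum.validate()
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in spectrum.meta.items():
            fh.write(f"# {key}: {value}\n")
        for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.17g} {y:.17g}\n")


# ---------------------------------------------------------------------------
# Raman maps

_SIDECAR_NAME = "map.yaml"
_PIXEL_FMT = "pixel_%05d.txt"


def write_map_dir(rmap: RamanMap, path) -> None:
    """Write a map as a directory of pixel spectra plus a YAML sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "nx": int(rmap.nx),
        "ny": int(rmap.ny),
        "step_um": float(rmap.step_um),
        "line_id": str(rmap.line_id),
    }
    (path / _SIDECAR_NAME).write_text(yaml.safe_dump(sidecar, sort_keys=True))
    for idx in range(rmap.n_pixels):
        spec = Spectrum(rmap.wavenumbers, rmap.intensities[idx])
        write_spectrum_txt(spec, path / (_PIXEL_FMT % idx))


def _read_map_csv(path: Path, layout) -> RamanMap:
    if layout is None:
        raise MapStructureError(f"{path}: CSV map requires an explicit (nx, ny, step) layout")
    nx, ny, step = layout
    frame = pd.read_csv(path)
    if frame.shape[1] != nx * ny + 1:
        raise MapStructureError(
            f"{path}: expected {nx * ny} pixel columns + wavenumber, got {frame.shape[1] - 1}"
        )
    wav = frame.iloc[:, 0].to_numpy(dtype=float)
    inten = frame.iloc[:, 1:].to_numpy(dtype=float).T
    return RamanMap(wav, inten, nx=int(nx), ny=int(ny), step_um=float(step))


def read_map_dir(path, layout=None) -> RamanMap:
    """Read a Raman map from a pixel-file directory (with ``map.yaml``
    sidecar) or a single multi-column CSV export.

    ``layout`` is an optional (nx, ny, step_um) triple; it overrides the
    sidecar and is required for the CSV form.
    """
    path = Path(path)
    if path.is_file():
        return _read_map_csv(path, layout)
    if not path.is_dir():
        raise FileNotFoundError(path)
    meta: dict = {}
    sidecar_path = path / _SIDECAR_NAME
    if sidecar_path.exists():
        meta = yaml.safe_load(sidecar_path.read_text()) or {}
    if layout is not None:
        meta["nx"], meta["ny"], meta["step_um"] = layout
    if "nx" not in meta or "ny" not in meta:
        raise MapStructureError(f"{path}: no map.yaml sidecar and no layout given")
    nx, ny = int(meta["nx"]), int(meta["ny"])
    step = float(meta.get("step_um", 1.0))
    line_id = str(meta.get("line_id", ""))
    files = [path / (_PIXEL_FMT % idx) for idx in range(nx * ny)]
    missing = [f.name for f in files if not f.exists()]
    if missing:
        raise MapStructureError(
            f"{path}: expected {nx * ny} pixel files, missing {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    grid = None
    rows = []
    for idx, f in enumerate(files):
        spec = read_spectrum_txt(f)
        if grid is None:
            grid = spec.wavenumbers
        elif spec.wavenumbers.shape != grid.shape or not np.array_equal(
            spec.wavenumbers, grid
        ):
            raise MapStructureError(f"{path}: pixel {idx} ({f.name}) is on a different grid")
        rows.append(spec.intensities)
    return RamanMap(grid, np.vstack(rows), nx=nx, ny=ny, step_um=step, line_id=line_id)


# ---------------------------------------------------------------------------
# Label tables


def read_label_table(path) -> LabelTable:
    """Read and validate a CSV label table
    (``line_id,astaxanthin,canthaxanthin,betacarotene``)."""
    frame = pd.read_csv(path)
    frame.columns = [str(c).strip() for c in frame.columns]
    missing = [c for c in ("line_id", *COMPONENTS) if c not in frame.columns]
    if missing:
        raise LabelTableError(f"{path}: missing columns {missing}")
    return LabelTable(frame)


def write_label_table(table: LabelTable, path) -> None:
    table.frame.to_csv(path, index=False)
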