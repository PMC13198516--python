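"""Synthetic Raman/SERS data with known ground truth.

Emulates the three ingredients of the study design: (i) SERS spectra of
carotenoid standards (astaxanthin, canthaxanthin, β-carotene) with the
fingerprint bands at their published positions, (ii) single-cell Raman maps
of tobacco BY-2 cell lines where carotenoids concentrate in vesicle-like
hotspots, and (iii) a per-line composition label table standing in for
HPLC quantification. Every stochastic operation is a pure function of its
inputs and a seed, so downstream stages (baseline correction, despiking,
knee-point triage, regression) can be tested against exact ground truth.

Band shapes are Lorentzian (the standard line shape for Raman bands); the
background is a slowly varying polynomial plus one broad Gaussian emulating
residual fluorescence; cosmic-ray spikes are 1-2 grid points wide with
amplitudes several times the signal maximum, the artifact class that
modified-z-score despiking targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import write_label_table, write_map_dir, write_spectrum_txt
from .types import COMPONENTS, LabeledSpectraSet, LabelTable, RamanMap, Spectrum


@dataclass
class PeakModel:
    """One Raman band: Lorentzian center (cm^-1), FWHM (cm^-1), relative amplitude."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def _lorentzian(grid: np.ndarray, peak: PeakModel) -> np.ndarray:
    hw = peak.fwhm / 2.0
    return peak.amplitude * hw**2 / ((grid - peak.center) ** 2 + hw**2)


# Fingerprints: the υ3 (~1009-1011), υ2 (~1160-1161, strongest band, the
# one spectra are normalised to) and υ1 (~1516-1518) modes at their
# published positions, plus one weak compound-specific minor band so that
# mixtures of the three compounds are spectroscopically identifiable.
DEFAULT_PEAK_TABLES: dict[str, tuple[PeakModel, ...]] = {
    "astaxanthin": (
        PeakModel(1009.0, 12.0, 0.35),
        PeakModel(1160.0, 12.0, 1.00),
        PeakModel(1516.0, 12.0, 0.90),
        PeakModel(1275.0, 16.0, 0.12),
    ),
    "canthaxanthin": (
        PeakModel(1011.0, 12.0, 0.30),
        PeakModel(1161.0, 12.0, 1.00),
        PeakModel(1518.0, 12.0, 0.95),
        PeakModel(1310.0, 16.0, 0.10),
    ),
    "betacarotene": (
        PeakModel(1011.0, 12.0, 0.45),
        PeakModel(1160.0, 12.0, 1.00),
        PeakModel(1518.0, 12.0, 0.88),
        PeakModel(1190.0, 16.0, 0.14),
    ),
}


def _default_grid() -> np.ndarray:
    # 1 cm^-1 spacing, generously covering the 900-1700 cm^-1 pipeline window.
    return np.linspace(850.0, 1750.0, 901)


@dataclass
class GeneratorConfig:
    """All knobs of the simulator.

    The wavenumber grid must cover at least [900, 1700] cm^-1 so that it
    contains the carotenoid fingerprint region and the default feature grid
    used for model input. ``amplitude_scale`` converts the relative band
    amplitudes to counts for a pure compound; baseline coefficients are in
    counts over the normalised coordinate u = (ν - ν_min) / span.
    """

    grid: np.ndarray = field(default_factory=_default_grid)
    peak_tables: dict = field(default_factory=lambda: dict(DEFAULT_PEAK_TABLES))
    amplitude_scale: float = 1000.0
    baseline_poly: tuple = (400.0, -150.0, 60.0, -30.0)  # c0 + c1 u + c2 u^2 + c3 u^3
    fluorescence_amplitude: float = 300.0
    fluorescence_center: float = 1250.0
    fluorescence_sigma: float = 300.0
    noise_sigma: float = 10.0
    spike_rate: float = 0.2
    spike_amplitude_range: tuple = (5.0, 20.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid[0] > 900.0 or self.grid[-1] < 1700.0:
            raise ValueError("grid must cover at least [900, 1700] cm^-1")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.noise_sigma < 0 or self.spike_rate < 0:
            raise ValueError("noise_sigma and spike_rate must be >= 0")
        if set(self.peak_tables) != set(COMPONENTS):
            raise ValueError(f"peak_tables must cover exactly {COMPONENTS}")

    def signal(self, fractions) -> np.ndarray:
        """Noise-free, baseline-free signal: linear in the mixture fractions."""
        fractions = np.asarray(fractions, dtype=float)
        if fractions.shape != (3,) or np.any(fractions < 0) or np.any(fractions > 1):
            raise ValueError("fractions must be a 3-vector in [0, 1]")
        out = np.zeros_like(self.grid)
        for frac, compound in zip(fractions, COMPONENTS):
            if frac == 0.0:
                continue
            for peak in self.peak_tables[compound]:
                out += frac * _lorentzian(self.grid, peak)
        return self.amplitude_scale * out

    def baseline(self) -> np.ndarray:
        """Fluorescence-like background: cubic polynomial + broad Gaussian."""
        u = (self.grid - self.grid[0]) / (self.grid[-1] - self.grid[0])
        base = np.polynomial.polynomial.polyval(u, self.baseline_poly)
        base = base + self.fluorescence_amplitude * np.exp(
            -0.5 * ((self.grid - self.fluorescence_center) / self.fluorescence_sigma) ** 2
        )
        return base

    def quiet(self) -> "GeneratorConfig":
        """Copy with noise, spikes and baseline switched off."""
        return replace(
            self,
            baseline_poly=(0.0,),
            fluorescence_amplitude=0.0,
            noise_sigma=0.0,
            spike_rate=0.0,
        )


@dataclass
class GroundTruth:
    """Exact generative record for one simulated spectrum."""

    fractions: np.ndarray
    baseline: np.ndarray
    spike_indices: np.ndarray
    informative: bool


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _inject_spikes(
    intensities: np.ndarray, reference: float, cfg: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Add Poisson(spike_rate) cosmic-ray spikes, 1-2 points wide; returns
    the affected indices."""
    n_spikes = rng.poisson(cfg.spike_rate)
    hit: list[int] = []
    for _ in range(n_spikes):
        pos = int(rng.integers(0, intensities.size))
        width = int(rng.integers(1, 3))
        amp = rng.uniform(*cfg.spike_amplitude_range) * reference
        for k in range(width):
            idx = pos + k
            if idx < intensities.size:
                intensities[idx] += amp
                hit.append(idx)
    return np.array(sorted(set(hit)), dtype=int)


def simulate_spectrum(fractions, cfg: GeneratorConfig | None = None, rng=None):
    """Simulate one spectrum for a mixture; returns (Spectrum, GroundTruth).

    intensities = Σ_c fraction_c * fingerprint_c + baseline + noise + spikes.
    """
    cfg = cfg or GeneratorConfig()
    rng = _as_rng(rng)
    signal = cfg.signal(fractions)
    baseline = cfg.baseline()
    intensities = signal + baseline
    if cfg.noise_sigma > 0:
        intensities = intensities + rng.normal(0.0, cfg.noise_sigma, cfg.grid.size)
    reference = float(np.max(signal + baseline))
    if reference <= 0:
        reference = 1.0
    spike_idx = _inject_spikes(intensities, reference, cfg, rng)
    fractions = np.asarray(fractions, dtype=float)
    truth = GroundTruth(
        fractions=fractions,
        baseline=baseline,
        spike_indices=spike_idx,
        informative=bool(np.any(fractions > 0)),
    )
    return Spectrum(cfg.grid.copy(), intensities), truth


def simulate_standards_dataset(
    n_per_class=(12, 11, 11), cfg: GeneratorConfig | None = None, seed=0
) -> LabeledSpectraSet:
    """Simulate the carotenoid-standards dataset: pure-compound spectra with
    one-hot composition labels.

    ``n_per_class`` is an int (same count for all three compounds) or a
    per-compound triple. The default (12, 11, 11) reproduces the size of a
    quality-filtered standards dataset of 34 spectra.
    """
    if isinstance(n_per_class, (int, np.integer)):
        counts = (int(n_per_class),) * 3
    else:
        counts = tuple(int(n) for n in n_per_class)
    if len(counts) != 3 or min(counts) < 1:
        raise ValueError("n_per_class must be a positive int or triple")
    cfg = cfg or GeneratorConfig()
    rng = _as_rng(seed)
    spectra, labels, fractions = [], [], []
    for c, (compound, count) in enumerate(zip(COMPONENTS, counts)):
        onehot = np.zeros(3)
        onehot[c] = 1.0
        for k in range(count):
            spec, _ = simulate_spectrum(onehot, cfg, rng)
            spec.meta.update({"sample_id": f"{compound}_{k:03d}", "compound": compound})
            spectra.append(spec)
            labels.append(compound)
            fractions.append(onehot)
    return LabeledSpectraSet(spectra, labels, np.asarray(fractions))


@dataclass
class MapGroundTruth:
    """Ground truth for a simulated cell map."""

    mask: np.ndarray  # (ny, nx) bool, True on carotenoid-bearing pixels
    pixel_fractions: np.ndarray  # (nx * ny, 3)
    spike_indices: dict  # pixel index -> spike grid indices
    baseline: np.ndarray  # common true baseline
    vesicle_centers: np.ndarray  # (n_vesicles, 2) as (cx, cy) in pixel units
    vesicle_radius_px: float = 0.0


def simulate_cell_map(
    line_id: str,
    nx: int = 20,
    ny: int = 20,
    n_vesicles: int = 4,
    vesicle_radius_px: float = 2.5,
    fractions=(0.1, 0.6, 0.3),
    cfg: GeneratorConfig | None = None,
    seed=0,
):
    """Simulate one single-cell Raman map with carotenoid hotspots.

    Carotenoids are deposited in ``n_vesicles`` randomly placed discs of
    radius ``vesicle_radius_px`` (vesicle-like storage structures); pixels
    inside a disc carry the mixture fingerprint with a per-pixel amplitude
    jitter, all other pixels carry only baseline and noise. Returns
    (RamanMap, MapGroundTruth).
    """
    cfg = cfg or GeneratorConfig()
    rng = _as_rng(seed)
    disc_area = np.pi * vesicle_radius_px**2
    if n_vesicles * disc_area >= nx * ny:
        raise ValueError("vesicles would cover the whole map")
    mask = np.zeros((ny, nx), dtype=bool)
    r_int = int(np.ceil(vesicle_radius_px))
    jj, ii = np.mgrid[0:ny, 0:nx]
    centers = []
    for _ in range(n_vesicles):
        cx = rng.uniform(r_int, nx - 1 - r_int) if nx - 1 > 2 * r_int else (nx - 1) / 2
        cy = rng.uniform(r_int, ny - 1 - r_int) if ny - 1 > 2 * r_int else (ny - 1) / 2
        centers.append((cx, cy))
        mask |= (ii - cx) ** 2 + (jj - cy) ** 2 <= vesicle_radius_px**2
    fractions = np.asarray(fractions, dtype=float)
    informative = bool(np.any(fractions > 0))
    if not informative or n_vesicles == 0:
        mask[:] = False

    signal = cfg.signal(fractions)
    baseline = cfg.baseline()
    reference = float(np.max(signal + baseline)) or 1.0
    n_pixels = nx * ny
    flat_mask = mask.reshape(-1)
    intensities = np.tile(baseline, (n_pixels, 1))
    pixel_fractions = np.zeros((n_pixels, 3))
    spike_map: dict[int, np.ndarray] = {}
    for idx in range(n_pixels):
        if flat_mask[idx]:
            jitter = rng.uniform(0.6, 1.4)
            intensities[idx] += jitter * signal
            pixel_fractions[idx] = fractions
        if cfg.noise_sigma > 0:
            intensities[idx] += rng.normal(0.0, cfg.noise_sigma, cfg.grid.size)
        spikes = _inject_spikes(intensities[idx], reference, cfg, rng)
        if spikes.size:
            spike_map[idx] = spikes

    rmap = RamanMap(
        cfg.grid.copy(), intensities, nx=nx, ny=ny, step_um=1.0, line_id=line_id
    )
    truth = MapGroundTruth(
        mask,
        pixel_fractions,
        spike_map,
        baseline,
        vesicle_centers=np.asarray(centers, float).reshape(-1, 2),
        vesicle_radius_px=float(vesicle_radius_px),
    )
    return rmap, truth


def default_label_table() -> LabelTable:
    """Fixture composition table for seven BY-2-style cell lines.

    Synthetic stand-in for an HPLC quantification table (the real per-line
    values are not published): wild-type lines carry trace β-carotene only,
    engineered lines mix the three compounds.
    """
    rows = [
        ("WT-D", 0.00, 0.00, 0.02),
        ("WT-L", 0.00, 0.00, 0.10),
        ("W04", 0.05, 0.15, 0.80),
        ("YW02", 0.10, 0.60, 0.30),
        ("IW09", 0.30, 0.50, 0.20),
        ("YIW6", 0.00, 0.00, 0.60),
        ("YIW135", 0.55, 0.30, 0.15),
    ]
    frame = pd.DataFrame(rows, columns=["line_id", *COMPONENTS])
    return LabelTable(frame)


_WT_CONTENT_THRESHOLD = 0.15  # total fraction below which a line is "WT-like"


def _map_geometry(total_content: float) -> tuple[int, float]:
    """Vesicle count and radius: sparse small hotspots (<5% of pixels) for
    WT-like lines, >=3 larger vesicles for transgenic-like lines."""
    if total_content < _WT_CONTENT_THRESHOLD:
        return 2, 1.5
    return 4, 2.5


@dataclass
class Benchmark:
    """In-memory benchmark bundle: standards + per-line maps + labels."""

    standards: LabeledSpectraSet
    maps: dict  # line_id -> list of (RamanMap, MapGroundTruth)
    label_table: LabelTable
    manifest: dict
    config: GeneratorConfig


def simulate_benchmark(
    label_table: LabelTable | None = None,
    maps_per_line: int = 4,
    cfg: GeneratorConfig | None = None,
    seed=0,
    out_dir=None,
    nx: int = 20,
    ny: int = 20,
    n_standards_per_class=(12, 11, 11),
) -> Benchmark:
    """Simulate the full benchmark: a standards dataset plus ``maps_per_line``
    maps for every line in the label table. Deterministic under ``seed``.

    If ``out_dir`` is given the bundle is also written to disk as a
    spectra_io tree plus ``truth.json``, ``labels.csv`` and ``config.yaml``.
    """
    label_table = label_table or default_label_table()
    cfg = cfg or GeneratorConfig()
    ss = np.random.SeedSequence(seed)
    std_ss, *map_ss = ss.spawn(1 + len(label_table) * maps_per_line)
    standards = simulate_standards_dataset(
        n_standards_per_class, cfg, np.random.default_rng(std_ss)
    )
    maps: dict[str, list] = {}
    manifest: dict = {
        "seed": int(seed),
        "maps_per_line": maps_per_line,
        "n_standards": len(standards),
        "lines": {},
    }
    k = 0
    for line_id in label_table.line_ids:
        fractions = label_table.fractions_for(line_id)
        n_vesicles, radius = _map_geometry(float(fractions.sum()))
        entries = []
        per_map = []
        for m in range(maps_per_line):
            rmap, truth = simulate_cell_map(
                line_id,
                nx=nx,
                ny=ny,
                n_vesicles=n_vesicles,
                vesicle_radius_px=radius,
                fractions=fractions,
                cfg=cfg,
                seed=np.random.default_rng(map_ss[k]),
            )
            rmap.meta["map_index"] = m
            entries.append((rmap, truth))
            per_map.append(
                {
                    "map_index": m,
                    "nx": nx,
                    "ny": ny,
                    "n_true_informative": int(truth.mask.sum()),
                }
            )
            k += 1
        maps[line_id] = entries
        manifest["lines"][line_id] = {
            "fractions": [float(v) for v in fractions],
            "n_vesicles": n_vesicles,
            "vesicle_radius_px": radius,
            "maps": per_map,
        }
    bench = Benchmark(standards, maps, label_table, manifest, cfg)
    if out_dir is not None:
        write_benchmark(bench, out_dir)
    return bench


def write_benchmark(bench: Benchmark, out_dir) -> None:
    """Write a benchmark bundle as a plain-text fixture tree."""
    out = Path(out_dir)
    (out / "standards").mkdir(parents=True, exist_ok=True)
    for k, spec in enumerate(bench.standards.spectra):
        write_spectrum_txt(spec, out / "standards" / f"standard_{k:03d}.txt")
    truth: dict = {"lines": {}}
    for line_id, entries in bench.maps.items():
        line_truth = []
        for m, (rmap, map_truth) in enumerate(entries):
            write_map_dir(rmap, out / "lines" / line_id / f"map_{m:02d}")
            line_truth.append(
                {
                    "map_index": m,
                    "mask": map_truth.mask.astype(int).tolist(),
                    "spike_indices": {
                        str(p): v.tolist() for p, v in map_truth.spike_indices.items()
                    },
                }
            )
        truth["lines"][line_id] = line_truth
    write_label_table(bench.label_table, out / "labels.csv")
    (out / "truth.json").write_text(json.dumps(truth, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(bench.manifest, sort_keys=True, indent=1))
    cfg = bench.config
    cfg_doc = {
        "amplitude_scale": cfg.amplitude_scale,
        "baseline_poly": [float(c) for c in cfg.baseline_poly],
        "fluorescence": {
            "amplitude": cfg.fluorescence_amplitude,
            "center": cfg.fluorescence_center,
            "sigma": cfg.fluorescence_sigma,
        },
        "noise_sigma": cfg.noise_sigma,
        "spike_rate": cfg.spike_rate,
        "grid": {
            "lo": float(cfg.grid[0]),
            "hi": float(cfg.grid[-1]),
            "n": int(cfg.grid.size),
        },
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg_doc, sort_keys=True))
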