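"""Core data model and I/O for dynamic-light-scattering (DLS) size spectra.

A DLS instrument reports an intensity-weighted particle size distribution:
the percentage of scattered-light intensity falling into each
hydrodynamic-diameter bin, on bins that are log-spaced over roughly
0.4 nm - 10 um.  Throughout this package a spectrum is normalized so that
its total area is 100, which makes distributions from different
measurements directly comparable and gives the divergence statistic
(:func:`phagedls.aucdelta.auc_delta`) its fixed 0-200 range.

The module provides:

* :class:`SizeGrid` -- log-spaced diameter bins shared by comparable spectra;
* :class:`DLSSpectrum` -- one measurement (grid + non-negative intensities);
* :class:`SampleRecord` -- replicate spectra for one labeled sample, with an
  optional plaque-assay titer (log10 PFU/mL);
* readers/writers for simple CSV dialects emulating Zetasizer-style exports;
* normalization, log-space resampling, replicate averaging, peak summaries,
  and the Stokes-Einstein diameter conversion.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN_J_PER_K",
    "DEFAULT_D_MIN_NM",
    "DEFAULT_D_MAX_NM",
    "DEFAULT_N_BINS",
    "NORMALIZED_AREA",
    "SizeGrid",
    "DLSSpectrum",
    "SampleRecord",
    "PeakSummary",
    "make_log_grid",
    "default_grid",
    "normalize",
    "resample",
    "average_replicates",
    "stokes_einstein_diameter",
    "peak_summary",
    "read_spectra_csv",
    "write_spectra_csv",
]

logger = logging.getLogger(__name__)

BOLTZMANN_J_PER_K = 1.380649e-23  # exact (2019 SI)

#: Default reporting range and bin count, emulating a benchtop Zetasizer
#: export (spectra in this field span ~10 nm virions to ~8,000 nm aggregates).
DEFAULT_D_MIN_NM = 0.4
DEFAULT_D_MAX_NM = 10_000.0
DEFAULT_N_BINS = 70

#: Total area of a normalized size-intensity spectrum.
NORMALIZED_AREA = 100.0

_NORMALIZED_ATOL = 1e-6  # invariant tolerance on the area of a normalized spectrum
_IMPORT_SUM_ATOL = 1e-3  # imported sums within this of 100 are flagged normalized
_IMPORT_RENORM_ATOL = 0.1  # beyond this (0.1% of 100) imports are renormalized


def _readonly(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float).copy()
    a.flags.writeable = False
    return a


@dataclasses.dataclass(frozen=True)
class SizeGrid:
    """Ordered diameter bins (nm) shared by comparable spectra.

    Parameters
    ----------
    centers
        Bin centers in nm, strictly increasing, all positive.
    edges
        Bin boundaries in nm, ``len(centers) + 1`` values; each center must
        lie within its edge pair.
    log_spaced
        True when the edge ratio is constant (generated grids); grids
        imported from instrument exports may be irregular.
    """

    centers: np.ndarray
    edges: np.ndarray
    log_spaced: bool = True

    def __post_init__(self) -> None:
        centers = _readonly(self.centers)
        edges = _readonly(self.edges)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "edges", edges)
        if centers.ndim != 1 or edges.ndim != 1 or edges.size != centers.size + 1:
            raise ValueError("edges must have exactly one more element than centers")
        if centers.size < 1:
            raise ValueError("grid needs at least one bin")
        if np.any(edges <= 0) or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be positive and strictly increasing")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        if np.any(centers < edges[:-1]) or np.any(centers > edges[1:]):
            raise ValueError("each center must lie within its edge pair")
        if self.log_spaced:
            ratios = edges[1:] / edges[:-1]
            if not np.allclose(ratios, ratios[0], rtol=1e-9):
                raise ValueError("log_spaced grid must have a constant edge ratio")

    @property
    def n_bins(self) -> int:
        return int(self.centers.size)

    @property
    def log_widths(self) -> np.ndarray:
        """Bin widths in log10(diameter) units."""
        return np.diff(np.log10(self.edges))

    @property
    def span_nm(self) -> tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])

    def same_as(self, other: "SizeGrid", rtol: float = 1e-9) -> bool:
        return self.n_bins == other.n_bins and np.allclose(
            self.edges, other.edges, rtol=rtol
        )

    @classmethod
    def from_centers(cls, centers: Sequence[float]) -> "SizeGrid":
        """Build a grid from reported bin centers (instrument exports).

        Internal edges are geometric midpoints of adjacent centers; the
        outer edges extend the first/last midpoint ratio.  The grid is
        flagged log-spaced only when the center ratio is constant.
        """
        c = np.asarray(centers, dtype=float)
        if c.size < 2:
            raise ValueError("need at least two centers to infer edges")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("centers must be positive and strictly increasing")
        inner = np.sqrt(c[:-1] * c[1:])
        first = c[0] ** 2 / inner[0]
        last = c[-1] ** 2 / inner[-1]
        edges = np.concatenate([[first], inner, [last]])
        ratios = c[1:] / c[:-1]
        log_spaced = bool(np.allclose(ratios, ratios[0], rtol=1e-9))
        return cls(centers=c, edges=edges, log_spaced=log_spaced)


def make_log_grid(d_min: float, d_max: float, n_bins: int) -> SizeGrid:
    """Geometric (log-spaced) grid of ``n_bins`` bins from ``d_min`` to ``d_max`` nm.

    Centers are the geometric means of adjacent edges.
    """
    if not (0 < d_min < d_max):
        raise ValueError(f"require 0 < d_min < d_max, got ({d_min}, {d_max})")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.geomspace(d_min, d_max, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return SizeGrid(centers=centers, edges=edges, log_spaced=True)


def default_grid() -> SizeGrid:
    """The package default: 70 geometric bins over 0.4-10,000 nm."""
    return make_log_grid(DEFAULT_D_MIN_NM, DEFAULT_D_MAX_NM, DEFAULT_N_BINS)


@dataclasses.dataclass(frozen=True)
class DLSSpectrum:
    """One DLS measurement: a grid plus per-bin relative intensity (%).

    Intensities are non-negative and finite; when ``is_normalized`` the
    values sum to 100 (within 1e-6).
    """

    grid: SizeGrid
    intensity: np.ndarray
    label: str = ""
    is_normalized: bool = False

    def __post_init__(self) -> None:
        intensity = _readonly(self.intensity)
        object.__setattr__(self, "intensity", intensity)
        if intensity.ndim != 1 or intensity.size != self.grid.n_bins:
            raise ValueError("intensity length must match the grid bin count")
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensity values must be finite")
        if np.any(intensity < 0):
            raise ValueError("intensity values must be non-negative")
        if self.is_normalized and abs(intensity.sum() - NORMALIZED_AREA) > _NORMALIZED_ATOL:
            raise ValueError("is_normalized set but area differs from 100")

    @property
    def total(self) -> float:
        return float(self.intensity.sum())

    def with_label(self, label: str) -> "DLSSpectrum":
        return dataclasses.replace(self, label=label)


@dataclasses.dataclass
class SampleRecord:
    """A labeled sample: replicate spectra plus optional plaque-assay titer."""

    phage_id: str
    condition: str = ""
    timepoint: float | None = None
    timepoint_unit: str | None = None
    replicates: list[DLSSpectrum] = dataclasses.field(default_factory=list)
    titer_log10: float | None = None
    titer_detection_limit_log10: float | None = None

    def __post_init__(self) -> None:
        if (
            self.titer_log10 is not None
            and self.titer_detection_limit_log10 is not None
            and self.titer_log10 < self.titer_detection_limit_log10
        ):
            raise ValueError("titer_log10 below the stated detection limit")

    def require_replicates(self) -> None:
        if not self.replicates:
            raise ValueError(f"sample {self.phage_id!r} has no replicate spectra")

    def mean_spectrum(self, grid: SizeGrid | None = None) -> DLSSpectrum:
        self.require_replicates()
        return average_replicates(self.replicates, grid=grid)


def normalize(spectrum: DLSSpectrum) -> DLSSpectrum:
    """Rescale intensities so the spectrum area is exactly 100.

    Idempotent and scale-invariant; the input is never modified.
    Raises on an all-zero (degenerate) spectrum.
    """
    total = spectrum.total
    if total <= 0:
        raise ValueError("degenerate spectrum: no positive intensity to normalize")
    if spectrum.is_normalized and abs(total - NORMALIZED_AREA) <= _NORMALIZED_ATOL:
        return spectrum
    return DLSSpectrum(
        grid=spectrum.grid,
        intensity=spectrum.intensity * (NORMALIZED_AREA / total),
        label=spectrum.label,
        is_normalized=True,
    )


def resample(spectrum: DLSSpectrum, target: SizeGrid) -> DLSSpectrum:
    """Re-bin a spectrum onto ``target``, conserving area 100.

    Intensities are interpreted as densities per unit log10(diameter):
    the per-bin density is linearly interpolated in log10-size onto the
    target centers, multiplied by the target bin log-widths, and
    renormalized.  Bins outside the source support get zero.
    """
    if spectrum.grid.n_bins < 2:
        raise ValueError("resampling needs a source spectrum with >= 2 bins")
    src = normalize(spectrum)
    if src.grid.same_as(target):
        return src
    density = src.intensity / src.grid.log_widths
    log_src = np.log10(src.grid.centers)
    log_tgt = np.log10(target.centers)
    dens_tgt = np.interp(log_tgt, log_src, density, left=0.0, right=0.0)
    intensity = dens_tgt * target.log_widths
    total = intensity.sum()
    if total <= 0:
        raise ValueError(
            "no overlap: target grid lies entirely outside the source support"
        )
    return DLSSpectrum(
        grid=target,
        intensity=intensity * (NORMALIZED_AREA / total),
        label=src.label,
        is_normalized=True,
    )


def _common_grid(spectra: Sequence[DLSSpectrum]) -> SizeGrid:
    first = spectra[0].grid
    if all(s.grid.same_as(first) for s in spectra[1:]):
        return first
    lo = min(s.grid.edges[0] for s in spectra)
    hi = max(s.grid.edges[-1] for s in spectra)
    return make_log_grid(lo, hi, DEFAULT_N_BINS)


def average_replicates(
    spectra: Sequence[DLSSpectrum], grid: SizeGrid | None = None
) -> DLSSpectrum:
    """Per-bin arithmetic mean of normalized replicate spectra (area 100).

    Replicates on differing grids are first resampled onto a common grid
    (``grid`` if given, else the shared grid, else a default log grid over
    the union of supports).  Order of inputs is immaterial.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot average an empty list of spectra")
    target = grid if grid is not None else _common_grid(spectra)
    aligned = [resample(s, target) if s.grid.n_bins >= 2 else normalize(s) for s in spectra]
    mean = np.mean([s.intensity for s in aligned], axis=0)
    mean *= NORMALIZED_AREA / mean.sum()
    label = spectra[0].label or ""
    return DLSSpectrum(
        grid=target,
        intensity=mean,
        label=f"mean[n={len(spectra)}]({label})" if label else f"mean[n={len(spectra)}]",
        is_normalized=True,
    )


def stokes_einstein_diameter(
    diffusion_coeff: float,
    temperature: float = 298.15,
    viscosity: float = 8.872e-4,
) -> float:
    """Hydrodynamic diameter (nm) from a translational diffusion coefficient.

    D_H = k_B * T / (3 * pi * eta * D), converted from meters to nm.

    Parameters
    ----------
    diffusion_coeff
        Translational diffusion coefficient in m^2/s.
    temperature
        Absolute temperature in K (default 25 degC, the usual DLS setting).
    viscosity
        Dynamic viscosity of the dispersant in Pa*s (default: water at 25 degC).
    """
    if diffusion_coeff <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("diffusion coefficient, temperature and viscosity must be > 0")
    d_m = BOLTZMANN_J_PER_K * temperature / (3.0 * np.pi * viscosity * diffusion_coeff)
    return float(d_m * 1e9)


@dataclasses.dataclass(frozen=True)
class PeakSummary:
    """Mode location and area split of a spectrum around an 'intact' window."""

    mode_nm: float
    fraction_below: float
    fraction_in: float
    fraction_above: float


def peak_summary(spectrum: DLSSpectrum, intact_window: tuple[float, float]) -> PeakSummary:
    """Mode of a normalized spectrum and % of area below/in/above a window.

    The window (nm, nm) marks the expected intact-virion size range; area
    below it indicates fragments, above it aggregates.  Bins are assigned
    by their centers; the three fractions sum to 100.
    """
    lo, hi = intact_window
    if not (lo < hi):
        raise ValueError("window must satisfy lo < hi")
    spec = normalize(spectrum)
    g_lo, g_hi = spec.grid.span_nm
    if lo < g_lo or hi > g_hi:
        raise ValueError(
            f"window ({lo}, {hi}) nm outside the grid span ({g_lo:.3g}, {g_hi:.3g}) nm"
        )
    c = spec.grid.centers
    i = spec.intensity
    below = float(i[c < lo].sum())
    inside = float(i[(c >= lo) & (c <= hi)].sum())
    above = float(i[c > hi].sum())
    mode = float(c[int(np.argmax(i))])
    return PeakSummary(mode_nm=mode, fraction_below=below, fraction_in=inside, fraction_above=above)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Two plain-text dialects are supported, emulating the tables DLS software
# exports.  Wide: first column is the size bin (nm), every further column one
# spectrum.  Long: columns (sample, size_nm, intensity).  Metadata rows whose
# size cell is non-numeric are skipped.  Errors name the 1-based physical
# line in the file (the header is line 1).
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ("sample", "size_nm", "intensity")


def _import_flagged(grid: SizeGrid, values: np.ndarray, label: str) -> DLSSpectrum:
    total = values.sum()
    dev = abs(total - NORMALIZED_AREA)
    if dev <= _IMPORT_SUM_ATOL:
        return DLSSpectrum(grid=grid, intensity=values, label=label, is_normalized=True)
    if dev > _IMPORT_RENORM_ATOL:
        logger.warning(
            "spectrum %r sums to %.6g (not 100); renormalizing on import", label, total
        )
        return DLSSpectrum(
            grid=grid,
            intensity=values * (NORMALIZED_AREA / total),
            label=label,
            is_normalized=True,
        )
    return DLSSpectrum(grid=grid, intensity=values, label=label, is_normalized=False)


def _check_intensities(values: np.ndarray, lines: np.ndarray, label: str) -> None:
    if np.any(~np.isfinite(values)):
        bad = int(lines[np.flatnonzero(~np.isfinite(values))[0]])
        raise ValueError(f"non-numeric intensity for {label!r} at row {bad}")
    if np.any(values < 0):
        bad = int(lines[np.flatnonzero(values < 0)[0]])
        raise ValueError(f"negative intensity for {label!r} at row {bad}")


def read_spectra_csv(path: str | Path, dialect: str = "wide") -> list[DLSSpectrum]:
    """Read spectra from a wide- or long-format CSV (sizes in nm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty spectra file: {path}") from exc
    if df.empty:
        raise ValueError(f"empty spectra file: {path}")

    if dialect == "wide":
        if df.shape[1] < 2:
            raise ValueError("wide dialect needs a size column plus >= 1 spectrum column")
        size_raw = pd.to_numeric(df.iloc[:, 0], errors="coerce")
        keep = size_raw.notna()
        if not keep.any():
            raise ValueError("no numeric size rows found")
        body = df.loc[keep]
        lines = body.index.to_numpy() + 2  # +1 header, +1 zero-based
        sizes = size_raw[keep].to_numpy(dtype=float)
        if np.any(sizes <= 0) or np.any(np.diff(sizes) <= 0):
            raise ValueError("size column must be positive and strictly increasing")
        grid = SizeGrid.from_centers(sizes)
        spectra = []
        for col in df.columns[1:]:
            vals = pd.to_numeric(body[col], errors="coerce").to_numpy(dtype=float)
            _check_intensities(vals, lines, str(col))
            spectra.append(_import_flagged(grid, vals, str(col)))
        return spectra

    if dialect == "long":
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"long dialect requires columns {_LONG_COLUMNS}, missing {missing}")
        spectra = []
        for sample in pd.unique(df["sample"]):
            sub = df[df["sample"] == sample]
            lines = sub.index.to_numpy() + 2
            sizes = pd.to_numeric(sub["size_nm"], errors="coerce").to_numpy(dtype=float)
            if np.any(~np.isfinite(sizes)) or np.any(sizes <= 0) or np.any(np.diff(sizes) <= 0):
                raise ValueError(
                    f"sizes for sample {sample!r} must be numeric, positive and strictly increasing"
                )
            vals = pd.to_numeric(sub["intensity"], errors="coerce").to_numpy(dtype=float)
            _check_intensities(vals, lines, str(sample))
            grid = SizeGrid.from_centers(sizes)
            spectra.append(_import_flagged(grid, vals, str(sample)))
        return spectra

    raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def write_spectra_csv(spectra: Iterable[DLSSpectrum], path: str | Path) -> None:
    """Write spectra as long-format CSV (full precision; round-trips exactly)."""
    frames = []
    for spec in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "sample": spec.label or "spectrum",
                    "size_nm": spec.grid.centers,
                    "intensity": spec.intensity,
                }
            )
        )
    if not frames:
        raise ValueError("no spectra to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
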