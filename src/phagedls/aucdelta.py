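"""The AUC-delta divergence statistic for DLS size spectra.

AUC-delta quantifies how far a size-intensity spectrum has drifted from a
reference: both spectra are normalized to area 100, placed on a shared
log-diameter grid, and the absolute bin-wise differences are summed,

    AUCdelta(a, b) = sum_i |a_i - b_i|.

Because each spectrum has area 100, the statistic runs from 0 (identical
spectra) to 200 (entirely non-overlapping spectra).  It is symmetric and,
on a fixed grid, an L1 metric between distributions.  Tracking AUC-delta of
a phage preparation against its baseline measurement turns spectral drift
(aggregation, fragmentation) into a scalar that can be calibrated against
lytic-titer loss.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .spectra import (
    DEFAULT_N_BINS,
    DLSSpectrum,
    SampleRecord,
    SizeGrid,
    average_replicates,
    make_log_grid,
    normalize,
    resample,
)

__all__ = ["AUCDeltaResult", "auc_delta", "baseline_divergence_series"]

AUC_DELTA_MAX = 200.0


@dataclasses.dataclass(frozen=True)
class AUCDeltaResult:
    """AUC-delta between two spectra, with the grid it was computed on."""

    value: float
    grid_used: SizeGrid
    a_label: str = ""
    b_label: str = ""
    #: SD of replicate-vs-baseline values when computed from a replicate set.
    replicate_sd: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= AUC_DELTA_MAX):
            raise ValueError(f"AUC-delta must lie in [0, 200], got {self.value}")

    def __float__(self) -> float:
        return self.value


def _union_grid(a: DLSSpectrum, b: DLSSpectrum) -> SizeGrid:
    lo = min(a.grid.edges[0], b.grid.edges[0])
    hi = max(a.grid.edges[-1], b.grid.edges[-1])
    return make_log_grid(lo, hi, DEFAULT_N_BINS)


def auc_delta(
    a: DLSSpectrum, b: DLSSpectrum, grid: SizeGrid | None = None
) -> AUCDeltaResult:
    """Sum of absolute bin-wise differences between two normalized spectra.

    Both inputs are normalized to area 100; when their grids differ (or an
    explicit ``grid`` is given) both are resampled onto the common grid
    first.  Symmetric in its arguments; values fractionally above 200 from
    floating point are clamped.
    """
    an, bn = normalize(a), normalize(b)
    if grid is None and an.grid.same_as(bn.grid):
        target = an.grid
    else:
        target = grid if grid is not None else _union_grid(an, bn)
        an = resample(an, target)
        bn = resample(bn, target)
    value = float(np.abs(an.intensity - bn.intensity).sum())
    value = min(value, AUC_DELTA_MAX)
    return AUCDeltaResult(value=value, grid_used=target, a_label=a.label, b_label=b.label)


def replicate_auc_delta(
    record: SampleRecord, baseline_mean: DLSSpectrum, grid: SizeGrid | None = None
) -> AUCDeltaResult:
    """AUC-delta of a sample's averaged replicates against an averaged baseline.

    The point value is computed on the replicate mean; the SD of the
    individual replicate-vs-baseline values is reported as spread.
    """
    record.require_replicates()
    mean = average_replicates(record.replicates, grid=grid)
    point = auc_delta(mean, baseline_mean, grid=grid)
    spread = None
    if len(record.replicates) > 1:
        per_rep = [
            auc_delta(rep, baseline_mean, grid=point.grid_used).value
            for rep in record.replicates
        ]
        spread = float(np.std(per_rep, ddof=1))
    return dataclasses.replace(point, replicate_sd=spread)


def baseline_divergence_series(
    baseline: SampleRecord,
    series: Sequence[SampleRecord],
    grid: SizeGrid | None = None,
) -> list[tuple[float | None, AUCDeltaResult]]:
    """AUC-delta of each timepoint against the averaged baseline measurement.

    Baseline replicates are averaged once; each series record's replicates
    are averaged and compared against that baseline mean.  Output is ordered
    by timepoint (records without a timepoint sort last, in input order).
    """
    baseline.require_replicates()
    for rec in series:
        if rec.phage_id != baseline.phage_id:
            raise ValueError(
                f"phage_id mismatch: series record {rec.phage_id!r} vs baseline "
                f"{baseline.phage_id!r}"
            )
        rec.require_replicates()
    base_mean = average_replicates(baseline.replicates, grid=grid)
    ordered = sorted(
        enumerate(series),
        key=lambda item: (item[1].timepoint is None, item[1].timepoint, item[0]),
    )
    return [
        (rec.timepoint, replicate_auc_delta(rec, base_mean, grid=grid))
        for _, rec in ordered
    ]
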