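"""Spectral featurization: bucket integration, resampling, normalization.

Two input families are turned into fixed-length feature vectors:

* bare chemical-shift lists (DFT- or HOSE-predictor-style output) are
  *bucketized* — the ppm axis is split into equal bins and each shift
  increments its bin by one, yielding an integer pseudo-spectrum whose
  bin sums preserve relative integration;
* dense frequency-intensity traces (experimental-style spectra) are
  resampled to a uniform high-resolution grid and then *reduced* by
  summing intensity per bin.

Both end in a length-``n_bins`` vector (500 by default over [-1, 14) ppm)
suitable as an ML feature row.  Intensity-valued spectra are min-max
normalized to [0, 1000]; integer bucket counts need no normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .chemio import DataError, ShiftList, SpectrumTrace

logger = logging.getLogger("nmrlogd")

DEFAULT_N_BINS = 500
DEFAULT_PPM_MIN = -1.0
DEFAULT_PPM_MAX = 14.0
TRACE_PPM_MIN = -1.0
TRACE_PPM_MAX = 12.0
TRACE_POINTS = 16384
NORM_MAX = 1000.0

# Common solvent/impurity windows (ppm) for experimental-style spectra.
SOLVENT_PRESET = {
    "dmso-d6": (2.45, 2.55),
    "water_dmso": (3.28, 3.40),
    "cdcl3": (7.21, 7.31),
    "water_cdcl3": (1.50, 1.62),
    "tms": (-0.05, 0.05),
}


@dataclass
class PseudoSpectrum:
    """Integer bucket counts built from a bare shift list."""

    compound_id: str
    counts: np.ndarray
    ppm_min: float = DEFAULT_PPM_MIN
    ppm_max: float = DEFAULT_PPM_MAX
    source: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise DataError(f"{self.compound_id}: negative bucket count")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_centers(self) -> np.ndarray:
        edges = np.linspace(self.ppm_min, self.ppm_max, self.n_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class ProcessedSpectrum:
    """Fixed-length real-valued spectrum (reduced and/or normalized)."""

    compound_id: str
    intensities: np.ndarray
    ppm_min: float = DEFAULT_PPM_MIN
    ppm_max: float = DEFAULT_PPM_MAX
    source: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.intensities)

    def bin_centers(self) -> np.ndarray:
        edges = np.linspace(self.ppm_min, self.ppm_max, self.n_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])


def bucketize(shifts: ShiftList, n_bins: int = DEFAULT_N_BINS,
              ppm_min: float = DEFAULT_PPM_MIN,
              ppm_max: float = DEFAULT_PPM_MAX) -> PseudoSpectrum:
    """Count shifts into equal half-open bins [left, right) over the range.

    Each in-range shift increments exactly one bucket by 1 — three methyl
    protons at the same shift give one bucket of 3, a methylene gives 2.
    Out-of-range shifts (including a value exactly at ``ppm_max``) are
    dropped with a logged count.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not ppm_min < ppm_max:
        raise ValueError("ppm_min must be < ppm_max")
    values = shifts.shifts
    in_range = (values >= ppm_min) & (values < ppm_max)
    dropped = int(len(values) - in_range.sum())
    if dropped:
        logger.info("bucketize(%s): dropped %d out-of-range shift(s)",
                    shifts.compound_id, dropped)
    counts, _ = np.histogram(values[in_range], bins=n_bins, range=(ppm_min, ppm_max))
    return PseudoSpectrum(compound_id=shifts.compound_id, counts=counts,
                          ppm_min=ppm_min, ppm_max=ppm_max, source=shifts.source)


def resample_trace(trace: SpectrumTrace, ppm_min: float = TRACE_PPM_MIN,
                   ppm_max: float = TRACE_PPM_MAX,
                   n_points: int = TRACE_POINTS) -> SpectrumTrace:
    """Linearly interpolate a trace onto a uniform grid.

    Grid points outside the support of the input axis are set to 0.  The
    input axis must be strictly monotone (either direction).
    """
    ppm, intensity = trace.ppm, trace.intensity
    if len(ppm) < 2:
        raise DataError(f"{trace.compound_id}: trace too short to resample")
    if ppm[0] > ppm[-1]:
        ppm, intensity = ppm[::-1], intensity[::-1]
    if ppm[-1] < ppm_min or ppm[0] > ppm_max:
        raise DataError(f"{trace.compound_id}: trace does not overlap target range")
    grid = np.linspace(ppm_min, ppm_max, n_points)
    out = np.interp(grid, ppm, intensity, left=0.0, right=0.0)
    out[(grid < ppm[0]) | (grid > ppm[-1])] = 0.0
    return SpectrumTrace(ppm=grid, intensity=out, compound_id=trace.compound_id)


def reduce_trace(trace: SpectrumTrace, n_bins: int = DEFAULT_N_BINS,
                 ppm_min: float = DEFAULT_PPM_MIN,
                 ppm_max: float = DEFAULT_PPM_MAX,
                 source: str = "trace_derived") -> ProcessedSpectrum:
    """Bucket-integrate a dense trace down to ``n_bins`` points.

    Each output bin is the sum of trace intensities whose ppm position
    falls inside that half-open bin; total in-range intensity is conserved
    exactly.
    """
    values = trace.ppm
    in_range = (values >= ppm_min) & (values < ppm_max)
    sums, _ = np.histogram(values[in_range], bins=n_bins, range=(ppm_min, ppm_max),
                           weights=trace.intensity[in_range])
    return ProcessedSpectrum(compound_id=trace.compound_id, intensities=sums,
                             ppm_min=ppm_min, ppm_max=ppm_max, source=source)


def normalize(spec: ProcessedSpectrum | PseudoSpectrum,
              policy: str = "minmax_0_1000") -> ProcessedSpectrum:
    """Normalize a spectrum vector.

    ``minmax_0_1000`` maps the vector minimum to 0 and maximum to 1000
    linearly (per spectrum); any non-constant vector therefore ends with
    max exactly 1000.  ``none`` passes values through unchanged — the
    right choice for integer bucket counts, which already carry their
    scale.  A constant vector under min-max collapses to all zeros, with
    a warning when it was not zero to begin with.
    """
    values = np.asarray(spec.counts if isinstance(spec, PseudoSpectrum)
                        else spec.intensities, dtype=float)
    if not np.all(np.isfinite(values)):
        raise DataError(f"{spec.compound_id}: non-finite spectrum values")
    if policy == "none":
        out = values
    elif policy == "minmax_0_1000":
        lo, hi = values.min(), values.max()
        if hi == lo:
            if hi != 0:
                logger.warning("normalize(%s): constant nonzero spectrum collapses "
                               "to zeros under min-max", spec.compound_id)
            out = np.zeros_like(values)
        else:
            # divide before scaling so the maximum maps to exactly 1000
            out = (values - lo) / (hi - lo) * NORM_MAX
    else:
        raise ValueError(f"unknown normalization policy {policy!r}")
    return ProcessedSpectrum(compound_id=spec.compound_id, intensities=out,
                             ppm_min=spec.ppm_min, ppm_max=spec.ppm_max,
                             source=spec.source)


def mask_solvent_regions(spec: ProcessedSpectrum,
                         regions: list[tuple[float, float]]) -> ProcessedSpectrum:
    """Zero every bin whose center falls inside any of the given ppm windows.

    Overlapping windows are treated as their union.  Intended for
    experimental-style spectra; generated spectra carry no solvent or
    impurity signals.
    """
    centers = spec.bin_centers()
    mask = np.zeros(spec.n_bins, dtype=bool)
    for lo, hi in regions:
        if lo > hi:
            lo, hi = hi, lo
        mask |= (centers >= lo) & (centers <= hi)
    out = spec.intensities.copy()
    out[mask] = 0.0
    return replace(spec, intensities=out)


def feature_matrix(specs: list[ProcessedSpectrum | PseudoSpectrum]) -> "pd.DataFrame":
    """Stack spectra into a (compounds × bins) DataFrame, id-indexed."""
    import pandas as pd

    if not specs:
        raise DataError("no spectra to stack")
    n = specs[0].n_bins
    rows, ids = [], []
    for s in specs:
        if s.n_bins != n:
            raise DataError(f"{s.compound_id}: bin count {s.n_bins} != {n}")
        rows.append(np.asarray(s.counts if isinstance(s, PseudoSpectrum)
                               else s.intensities, dtype=float))
        ids.append(s.compound_id)
    cols = [f"bin_{i:03d}" for i in range(n)]
    return pd.DataFrame(np.vstack(rows), index=ids, columns=cols)


def write_feature_matrix(features: "pd.DataFrame", path: str,
                         ppm_min: float = DEFAULT_PPM_MIN,
                         ppm_max: float = DEFAULT_PPM_MAX) -> None:
    """CSV export: compound_id first column, bin centers in a header comment."""
    n = features.shape[1]
    edges = np.linspace(ppm_min, ppm_max, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# bin_center_ppm: " + ",".join(f"{c:.6g}" for c in centers) + "\n")
        features.rename_axis("compound_id").to_csv(fh)


def read_feature_matrix(path: str) -> "pd.DataFrame":
    import pandas as pd

    df = pd.read_csv(path, comment="#", index_col="compound_id",
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    return df
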