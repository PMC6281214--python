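"""Depth normalization and window merging.

Raw bin counts carry three nuisance effects: between-sample differences in
data volume, local outlier bins, and a smooth dependence of depth on bin
GC content.  They are removed in a fixed four-step order —

    1. per-sample mean-scaling ("intra-run" normalization),
    2. winsorization within contiguous 15-bin windows,
    3. LOESS correction of the depth-vs-GC trend,
    4. per-sample mean-scaling again (steps 2-3 perturb the data size)

— after which every 15 consecutive bins are summed into merged windows and
per-chromosome summary statistics (mean, s.d., unscaled MAD, window count,
autosome median of chromosome means) are taken for the Z statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .depth_io import AUTOSOMES, BinGrid, DepthMatrix
from .errors import DegenerateSampleError, ParameterError

logger = logging.getLogger(__name__)

MERGE_BINS = 15


@dataclass
class ChromStats:
    """Summary of one chromosome's merged windows for one sample."""

    merged: np.ndarray  # window depths (sums of MERGE_BINS bins)
    mean: float
    sd: float  # n-1 s.d. of merged depths
    mad: float  # unscaled median absolute deviation of merged depths
    windows: int


@dataclass
class MergedProfile:
    """Per-chromosome merged-window profile of a single sample."""

    sample_id: str
    chrom_stats: dict[str, ChromStats]
    autosome_median: float  # median over autosomes of the chromosome means
    grid_fingerprint: str = ""

    def mean(self, chrom: str) -> float:
        return self.chrom_stats[chrom].mean


def _window_slices(chrom_labels: np.ndarray, k: int):
    """Consecutive non-overlapping k-bin windows per chromosome.

    Yields (chrom, start, stop) over positions in usable-bin order; the
    trailing remainder of fewer than k bins is yielded with partial=True.
    """
    for chrom in AUTOSOMES:
        idx = np.flatnonzero(chrom_labels == chrom)
        if idx.size == 0:
            continue
        lo = idx[0]
        n_full = idx.size // k
        for w in range(n_full):
            yield chrom, lo + w * k, lo + (w + 1) * k, False
        if idx.size % k:
            yield chrom, lo + n_full * k, lo + idx.size, True


def intra_run_normalize(m: DepthMatrix) -> DepthMatrix:
    """Scale each sample to mean depth 1 over usable bins.

    Removes the between-sample data-volume difference; a row of zero total
    depth has no signal to scale and is rejected.
    """
    means = m.values.mean(axis=1)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise DegenerateSampleError(
            f"zero total depth for sample(s): {[m.sample_ids[i] for i in bad]}")
    return DepthMatrix(m.values / means[:, None], list(m.sample_ids), m.grid)


def winsorize_windows(m: DepthMatrix, window_bins: int = MERGE_BINS,
                      lower_fractile: float = 0.05,
                      upper_fractile: float = 0.95) -> DepthMatrix:
    """Clamp within-window outliers to the window's fractiles.

    Windows are the same contiguous ``window_bins``-bin runs per chromosome
    later used for merging; a trailing remainder window shorter than
    ``window_bins`` is left untouched.  Quantiles interpolate linearly
    between order statistics.
    """
    if window_bins < 2:
        raise ParameterError("window_bins must be >= 2")
    if not 0 < lower_fractile < 0.5 < upper_fractile < 1:
        raise ParameterError("fractiles must satisfy 0 < lo < 0.5 < hi < 1")
    out = m.values.copy()
    chrom_labels = m.grid.usable_chrom
    for chrom, a, b, partial in _window_slices(chrom_labels, window_bins):
        if partial:
            continue
        block = out[:, a:b]
        lo = np.quantile(block, lower_fractile, axis=1, keepdims=True)
        hi = np.quantile(block, upper_fractile, axis=1, keepdims=True)
        np.clip(block, lo, hi, out=block)
    return DepthMatrix(out, list(m.sample_ids), m.grid)


def loess_gc_correct(m: DepthMatrix, span: float = 0.75,
                     delta_frac: float = 0.01) -> DepthMatrix:
    """Remove the smooth depth-vs-GC trend per sample.

    For each sample a LOESS curve of depth on bin GC is fitted and the
    fitted deviation from the sample's overall mean is subtracted, so the
    correction is additive and mean-preserving to first order.  Negative
    corrected depths are clipped to zero.  A grid whose usable bins share
    one GC value offers nothing to fit; the correction is then a logged
    no-op.  ``delta_frac`` sets the lowess interpolation distance as a
    fraction of the GC range (a standard speed/accuracy knob).
    """
    if not 0 < span <= 1:
        raise ParameterError("span must be in (0, 1]")
    gc = m.grid.usable_gc
    gc_range = float(gc.max() - gc.min()) if gc.size else 0.0
    if gc_range == 0.0:
        logger.info("all usable bins share one GC value; LOESS correction skipped")
        return DepthMatrix(m.values.copy(), list(m.sample_ids), m.grid)
    out = np.empty_like(m.values)
    for i in range(m.values.shape[0]):
        y = m.values[i]
        fitted = lowess(y, gc, frac=span, delta=delta_frac * gc_range,
                        return_sorted=False)
        out[i] = np.clip(y - (fitted - y.mean()), 0.0, None)
    return DepthMatrix(out, list(m.sample_ids), m.grid)


def merge_bins(m: DepthMatrix, k: int = MERGE_BINS) -> list[MergedProfile]:
    """Sum every k consecutive usable bins per chromosome and summarize.

    The trailing remainder of fewer than k bins on each chromosome is
    dropped.  Summary statistics per chromosome: mean, n-1 s.d., unscaled
    MAD and count of merged windows, plus the median over autosomes of the
    chromosome means (the internal reference for the within-sample Z).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    chrom_labels = m.grid.usable_chrom
    bounds: dict[str, list[tuple[int, int]]] = {}
    for c, a, b, partial in _window_slices(chrom_labels, k):
        if not partial:
            bounds.setdefault(c, []).append((a, b))
    starts = {c: np.array([a for a, _ in bs]) for c, bs in bounds.items()}
    fp = m.grid.fingerprint()
    profiles = []
    for i, sid in enumerate(m.sample_ids):
        row = m.values[i]
        stats: dict[str, ChromStats] = {}
        for chrom, bs in bounds.items():
            # windows are contiguous, so reduceat over [a0, a1, ..., blast]
            edges = np.append(starts[chrom], bs[-1][1])
            merged = np.add.reduceat(row, edges[:-1])
            if edges[-1] < row.size:  # reduceat's last slice runs to the end
                merged[-1] = row[bs[-1][0]:bs[-1][1]].sum()
            mean = float(merged.mean())
            sd = float(merged.std(ddof=1)) if merged.size > 1 else 0.0
            mad = float(np.median(np.abs(merged - np.median(merged))))
            stats[chrom] = ChromStats(merged, mean, sd, mad, merged.size)
        means = [s.mean for s in stats.values() if s.windows > 0]
        profiles.append(MergedProfile(
            sample_id=sid, chrom_stats=stats,
            autosome_median=float(np.median(means)) if means else float("nan"),
            grid_fingerprint=fp))
    return profiles


def flag_dead_bins(m: DepthMatrix) -> BinGrid:
    """Mark bins with zero depth across all given samples as unusable.

    Run on the reference panel before any normalization: dead bins carry no
    information and destabilize both the LOESS fit and the Z denominators.
    """
    alive = m.values.sum(axis=0) > 0
    n_dead = int((~alive).sum())
    if n_dead:
        logger.info("flagging %d zero-depth bins unusable", n_dead)
    return m.grid.with_usable(alive)


def normalize_pipeline(m: DepthMatrix, span: float = 0.75,
                       winsor_lo: float = 0.05, winsor_hi: float = 0.95,
                       window_bins: int = MERGE_BINS) -> list[MergedProfile]:
    """The full fixed-order pipeline from raw counts to merged profiles."""
    x = intra_run_normalize(m)
    x = winsorize_windows(x, window_bins, winsor_lo, winsor_hi)
    x = loess_gc_correct(x, span)
    x = intra_run_normalize(x)
    return merge_bins(x, window_bins)
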