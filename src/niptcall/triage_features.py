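"""QC filtering, grey-zone triage and the ten-feature classifier input.

A sample must carry at least 3,000,000 unique reads and a fetal fraction
of at least 5% to be interpretable; anything below either threshold is
"QC-filtered".  QC-pass samples are then triaged on their run Z score:

* ``N``            — Z < 1.96: called negative by the one-Z-test rule;
* ``P``            — Z > 4:    called positive;
* ``Unclassified`` — 1.96 <= Z <= 4: the grey zone, where a single Z
  cannot separate low-fetal-fraction trisomies from noisy negatives.

The classifier input is a fixed ten-feature vector: the six Z statistics
(D1-D6, already on a Z scale, never rescaled) plus fetal fraction (D7),
read-length-distribution peak (D8), maternal age (D9) and gestational
week (D10), which are min-max scaled to [0, 3] with ranges saved from the
training set and restored verbatim on test data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .depth_io import SampleRecord, TARGET_CHROMS
from .errors import ParameterError
from .zstats import ZVector

logger = logging.getLogger(__name__)

QC_MIN_READS = 3_000_000
QC_MIN_FF = 0.05
Z_LOW = 1.96
Z_HIGH = 4.0

GROUP_N = "N"
GROUP_P = "P"
GROUP_UNCLASSIFIED = "Unclassified"
GROUP_QC_FILTERED = "QC-filtered"

FEATURE_NAMES = tuple(f"D{i}" for i in range(1, 11))
#: features D7-D10 are min-max scaled to [0, 3]; the Z features are not.
SCALED_FEATURES = ("D7", "D8", "D9", "D10")


@dataclass
class FeatureVector:
    """Ordered classifier input (D1..D10) with an optional class label."""

    sample_id: str
    chrom: str
    values: tuple[float, ...]
    label: int | None = None  # -1 normal, +1 trisomy, None unknown

    def __post_init__(self) -> None:
        if len(self.values) != 10:
            raise ParameterError("a feature vector has exactly 10 entries")
        if any(not math.isfinite(v) for v in self.values[:6]):
            raise ParameterError(
                f"{self.sample_id}: Z features D1-D6 must be finite")


def qc_filter(record: SampleRecord) -> str:
    """"pass" or "QC-filtered"; comparisons are strict, equality passes."""
    ur, ff = record.unique_reads, record.fetal_fraction
    if ur is None and ff is None:
        raise ParameterError(
            f"{record.sample_id}: QC needs unique_reads or fetal_fraction")
    if (ur is not None and ur < QC_MIN_READS) or (ff is not None and ff < QC_MIN_FF):
        return GROUP_QC_FILTERED
    return "pass"


def triage(z: float, qc: str) -> str:
    """Assign the triage group from the run Z score and QC status.

    QC failure dominates; the grey zone is the closed interval
    [1.96, 4] — the one-Z-test rule only commits outside it.
    """
    if qc == GROUP_QC_FILTERED:
        return GROUP_QC_FILTERED
    if not math.isfinite(z):
        raise ValueError(f"run Z score must be finite, got {z}")
    if z < Z_LOW:
        return GROUP_N
    if z > Z_HIGH:
        return GROUP_P
    return GROUP_UNCLASSIFIED


def run_z(zv: ZVector, record: SampleRecord, chrom: str) -> float:
    """The Z used for triage: the reported upstream Z when supplied
    (supplementary-table ingestion), otherwise D1."""
    reported = record.reported_z.get(chrom)
    return float(reported) if reported is not None else zv.d1


def assemble_features(zv: ZVector, record: SampleRecord,
                      chrom: str) -> FeatureVector:
    """Build the ordered ten-feature vector for one sample x chromosome.

    Missing metadata features (D7-D10) become NaN; training refuses them,
    prediction imputes the training median (see :class:`FeatureScaler`).
    """
    if chrom not in TARGET_CHROMS:
        raise ParameterError(f"chromosome must be one of {TARGET_CHROMS}")
    if zv.chrom != chrom:
        raise ParameterError(f"Z vector is for chromosome {zv.chrom}, not {chrom}")

    def opt(v: float | None) -> float:
        return math.nan if v is None else float(v)

    values = zv.as_tuple() + (opt(record.fetal_fraction),
                              opt(record.read_length_peak),
                              opt(record.maternal_age),
                              opt(record.gestational_week))
    return FeatureVector(record.sample_id, chrom, values,
                         label=record.real_state.get(chrom))


@dataclass
class FeatureScaler:
    """Saved min-max ranges mapping D7-D10 onto [0, 3].

    ``x -> 3 * (x - min) / (max - min)`` per scaled feature; a constant
    training feature maps everything to 0; test values outside the saved
    range extrapolate linearly and may leave [0, 3].  The training median
    is kept to impute missing test values.
    """

    mins: dict[str, float]
    maxs: dict[str, float]
    medians: dict[str, float]
    target_hi: float = 3.0

    def transform(self, v: FeatureVector) -> FeatureVector:
        vals = list(v.values)
        for name in SCALED_FEATURES:
            i = FEATURE_NAMES.index(name)
            x = vals[i]
            if math.isnan(x):
                x = self.medians[name]
                logger.warning("%s %s: missing %s imputed with training median",
                               v.sample_id, v.chrom, name)
            lo, hi = self.mins[name], self.maxs[name]
            vals[i] = 0.0 if hi == lo else self.target_hi * (x - lo) / (hi - lo)
        return FeatureVector(v.sample_id, v.chrom, tuple(vals), v.label)

    def transform_all(self, vs: Sequence[FeatureVector]) -> list[FeatureVector]:
        return [self.transform(v) for v in vs]


def fit_scaler(train: Sequence[FeatureVector],
               target_hi: float = 3.0) -> FeatureScaler:
    """Learn the 0-3 ranges of D7-D10 from the training set."""
    if not train:
        raise ParameterError("cannot fit a scaler on an empty training set")
    mins, maxs, medians = {}, {}, {}
    for name in SCALED_FEATURES:
        i = FEATURE_NAMES.index(name)
        col = np.array([v.values[i] for v in train])
        if np.any(np.isnan(col)):
            bad = [v.sample_id for v, x in zip(train, col) if math.isnan(x)]
            raise ParameterError(
                f"training refuses missing {name} values (samples {bad[:5]})")
        mins[name] = float(col.min())
        maxs[name] = float(col.max())
        medians[name] = float(np.median(col))
    return FeatureScaler(mins, maxs, medians, target_hi)


def apply_scaler(scaler: FeatureScaler, v: FeatureVector) -> FeatureVector:
    return scaler.transform(v)


# -- scaler persistence (TSV: feature, min, max, median) --------------------

def write_scaler(scaler: FeatureScaler, path) -> None:
    rows = [{"feature": f, "min": scaler.mins[f], "max": scaler.maxs[f],
             "median": scaler.medians[f]} for f in SCALED_FEATURES]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_scaler(path) -> FeatureScaler:
    df = pd.read_csv(path, sep="\t")
    return FeatureScaler(
        mins=dict(zip(df["feature"], df["min"].astype(float))),
        maxs=dict(zip(df["feature"], df["max"].astype(float))),
        medians=dict(zip(df["feature"], df["median"].astype(float))))
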