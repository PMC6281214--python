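"""File formats and core containers for binned cell-free DNA depth data.

The pipeline consumes per-sample read counts on a fixed autosomal bin grid
(20 kb bins by default), per-sample metadata (unique read count, fetal
fraction, read-length peak, maternal age, gestational week) and produces
per-sample, per-chromosome screening reports.  All formats are plain TSV;
the supplementary sample table is an XLSX workbook with one sheet per
target chromosome.

Coordinates are 0-based half-open (BED convention).  Only autosomes 1-22
participate: the internal-reference Z statistic takes a median over
autosome means, and the targets are chromosomes 13, 18 and 21.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
TARGET_CHROMS: tuple[str, ...] = ("13", "18", "21")

BIN_WIDTH = 20_000

_STATE_LABELS = {"-1": -1, "1": 1, "+1": 1, "n": -1, "p": 1,
                 "neg": -1, "negative": -1, "pos": 1, "positive": 1}


def _norm_chrom(c: object) -> str:
    s = str(c).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


@dataclass
class BinGrid:
    """The autosomal bin scaffold: sorted, non-overlapping fixed-width bins.

    ``bins`` has columns chrom, start, end, gc, usable.  Bins are sorted by
    (chrom, start) with chromosomes in karyotype order 1..22; every non-tail
    bin spans exactly ``bin_width`` bp; ``gc`` is a fraction in [0, 1] and
    must be finite for usable bins.
    """

    bins: pd.DataFrame
    bin_width: int = BIN_WIDTH

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "gc", "usable"}
        missing = required - set(self.bins.columns)
        if missing:
            raise FormatError(f"bin grid missing columns: {sorted(missing)}")
        b = self.bins.copy()
        b["chrom"] = b["chrom"].map(_norm_chrom)
        unknown = set(b["chrom"]) - set(AUTOSOMES)
        if unknown:
            b = b[b["chrom"].isin(AUTOSOMES)].reset_index(drop=True)
            logger.info("dropped %d non-autosomal bins", len(self.bins) - len(b))
        order = {c: i for i, c in enumerate(AUTOSOMES)}
        b = b.sort_values(["chrom", "start"],
                          key=lambda s: s.map(order) if s.name == "chrom" else s)
        b = b.reset_index(drop=True)
        b["usable"] = b["usable"].astype(bool)
        gc = b.loc[b["usable"], "gc"].to_numpy(float)
        if gc.size and (np.any(~np.isfinite(gc)) or gc.min() < 0 or gc.max() > 1):
            raise FormatError("usable bins must have gc in [0, 1]")
        for chrom, sub in b.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if np.any(e[:-1] > s[1:]):
                raise FormatError(f"overlapping bins on chromosome {chrom}")
        object.__setattr__(self, "bins", b)

    # -- usable-bin views -------------------------------------------------
    @property
    def usable_mask(self) -> np.ndarray:
        return self.bins["usable"].to_numpy()

    @property
    def n_usable(self) -> int:
        return int(self.usable_mask.sum())

    @property
    def usable_chrom(self) -> np.ndarray:
        """Chromosome label per usable bin, in grid order."""
        return self.bins.loc[self.usable_mask, "chrom"].to_numpy()

    @property
    def usable_gc(self) -> np.ndarray:
        return self.bins.loc[self.usable_mask, "gc"].to_numpy(float)

    def with_usable(self, mask: np.ndarray) -> "BinGrid":
        """A copy of the grid with ``usable`` restricted by ``mask`` (over usable bins)."""
        b = self.bins.copy()
        idx = np.flatnonzero(self.usable_mask)
        keep = np.asarray(mask, bool)
        if keep.size != idx.size:
            raise ParameterError("mask length must equal current usable bin count")
        b.loc[idx[~keep], "usable"] = False
        return BinGrid(b, self.bin_width)

    def fingerprint(self) -> str:
        """Stable digest of usable-bin coordinates, to pair panels with grids."""
        sub = self.bins.loc[self.usable_mask, ["chrom", "start", "end"]]
        payload = "\n".join(f"{c}\t{s}\t{e}" for c, s, e in sub.itertuples(index=False))
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass
class SampleRecord:
    """Per-sample metadata carried alongside the depth profile."""

    sample_id: str
    run_id: str = ""
    unique_reads: int | None = None
    fetal_fraction: float | None = None
    read_length_peak: float | None = None
    maternal_age: float | None = None
    gestational_week: float | None = None
    # per-chromosome truth (-1 normal, +1 trisomy, None unknown)
    real_state: dict[str, int | None] = field(default_factory=dict)
    # per-chromosome Z score reported by an upstream caller, if any
    reported_z: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fetal_fraction is not None and not 0 <= self.fetal_fraction <= 1:
            raise ParameterError(
                f"{self.sample_id}: fetal_fraction must be in [0, 1], "
                f"got {self.fetal_fraction}")
        if self.unique_reads is not None and self.unique_reads < 0:
            raise ParameterError(f"{self.sample_id}: unique_reads must be >= 0")


@dataclass
class DepthMatrix:
    """samples x usable-bins raw or normalized depths, tied to a grid."""

    values: np.ndarray
    sample_ids: list[str]
    grid: BinGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ParameterError("depth matrix must be 2-D")
        if v.shape[0] != len(self.sample_ids):
            raise ParameterError("one row per sample required")
        if v.shape[1] != self.grid.n_usable:
            raise ParameterError(
                f"column count {v.shape[1]} != usable bin count {self.grid.n_usable}")
        if np.any(v < 0):
            raise ValueError("depths must be non-negative")
        self.values = v

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]


@dataclass
class ResultRow:
    """One sample x chromosome line of the screening report."""

    sample_id: str
    chrom: str
    features: tuple[float, ...]  # D1..D10; nan marks a missing metadata feature
    qc_flag: str  # "pass" | "QC-filtered"
    triage_group: str  # "N" | "P" | "Unclassified" | "QC-filtered"
    predicted_class: int | None = None
    probability_negative: float | None = None
    probability_positive: float | None = None

    def __post_init__(self) -> None:
        if len(self.features) != 10:
            raise ParameterError("a result row carries exactly D1..D10")
        pn, pp = self.probability_negative, self.probability_positive
        if pn is not None and pp is not None and abs(pn + pp - 1.0) > 1e-9:
            raise ParameterError("class probabilities must sum to 1")


# ---------------------------------------------------------------------------
# grid I/O
# ---------------------------------------------------------------------------

def write_bin_grid(grid: BinGrid, path: str | Path) -> None:
    out = grid.bins.copy()
    out["usable"] = out["usable"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bin_grid(path: str | Path) -> BinGrid:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return BinGrid(df)


# ---------------------------------------------------------------------------
# per-sample bin counts
# ---------------------------------------------------------------------------

def read_bin_counts(paths: str | Path | Sequence[str | Path],
                    grid: BinGrid) -> DepthMatrix:
    """Read one BED-like count file per sample into a depth matrix.

    Each file holds ``chrom<TAB>start<TAB>end<TAB>count`` (header optional).
    File rows are matched to the grid by (chrom, start); bins absent from
    the grid are dropped with a counted warning, and a matching start with a
    conflicting end is a format error.  Row order in the file is irrelevant.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    key_to_col: dict[tuple[str, int], tuple[int, int]] = {}
    usable_idx = np.flatnonzero(grid.usable_mask)
    sub = grid.bins.iloc[usable_idx]
    for col, (chrom, start, end) in enumerate(
            sub[["chrom", "start", "end"]].itertuples(index=False)):
        key_to_col[(chrom, int(start))] = (col, int(end))

    rows, ids = [], []
    for path in paths:
        path = Path(path)
        df = _read_counts_file(path)
        row = np.zeros(grid.n_usable)
        dropped = 0
        for chrom, start, end, count in df.itertuples(index=False):
            if count < 0:
                raise ValueError(f"{path.name}: negative count at {chrom}:{start}")
            hit = key_to_col.get((_norm_chrom(chrom), int(start)))
            if hit is None:
                dropped += 1
                continue
            col, grid_end = hit
            if int(end) != grid_end:
                raise FormatError(
                    f"{path.name}: bin end {end} != grid end {grid_end} "
                    f"at {chrom}:{start}")
            row[col] = float(count)
        if dropped:
            logger.warning("%s: %d bins not on the grid were ignored",
                           path.name, dropped)
        rows.append(row)
        ids.append(path.stem)
    return DepthMatrix(np.vstack(rows) if rows else np.empty((0, grid.n_usable)),
                       ids, grid)


def _read_counts_file(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().split("\t")
    has_header = len(first) >= 4 and not first[1].strip().isdigit()
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None,
                     dtype={0: str})
    if df.shape[1] < 4:
        raise FormatError(f"{path.name}: expected chrom/start/end/count columns")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "count"]
    return df


def write_bin_counts(row: np.ndarray, grid: BinGrid, path: str | Path) -> None:
    """Write one sample's usable-bin counts in the BED-like count format."""
    sub = grid.bins.loc[grid.usable_mask, ["chrom", "start", "end"]].copy()
    sub["count"] = np.asarray(row)
    sub.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_META_FLOAT = ("fetal_fraction", "read_length_peak", "maternal_age",
               "gestational_week")


def write_sample_metadata(records: Iterable[SampleRecord],
                          path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "sample_id": r.sample_id, "run_id": r.run_id,
            "unique_reads": r.unique_reads}
        for f in _META_FLOAT:
            row[f] = getattr(r, f)
        for c in TARGET_CHROMS:
            row[f"state{c}"] = r.real_state.get(c)
            row[f"reported_z{c}"] = r.reported_z.get(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g",
                              na_rep="")


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "run_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("metadata file must have a sample_id column")
    records = []
    for _, row in df.iterrows():
        states = {c: _parse_state(row.get(f"state{c}")) for c in TARGET_CHROMS}
        zs = {c: _opt_float(row.get(f"reported_z{c}")) for c in TARGET_CHROMS}
        ur = _opt_float(row.get("unique_reads"))
        records.append(SampleRecord(
            sample_id=str(row["sample_id"]),
            run_id="" if pd.isna(row.get("run_id")) else str(row.get("run_id")),
            unique_reads=None if ur is None else int(ur),
            fetal_fraction=_opt_float(row.get("fetal_fraction")),
            read_length_peak=_opt_float(row.get("read_length_peak")),
            maternal_age=_opt_float(row.get("maternal_age")),
            gestational_week=_opt_float(row.get("gestational_week")),
            real_state=states, reported_z=zs))
    return records


def _opt_float(v: object) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def _parse_state(v: object) -> int | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    s = str(v).strip().lower().removesuffix(".0")
    return _STATE_LABELS.get(s)


# ---------------------------------------------------------------------------
# supplementary sample table (XLSX, one sheet per target chromosome)
# ---------------------------------------------------------------------------

_Z_ALIASES = {
    "D1": ("d1", "z_baseline_vs_n"), "D2": ("d2", "z_baseline_vs_p"),
    "D3": ("d3", "z_chr_vs_n"), "D4": ("d4", "z_chr_vs_p"),
    "D5": ("d5", "z_sample_vs_n"), "D6": ("d6", "z_sample_vs_p"),
}
_AUX_ALIASES = {
    "D7": ("d7", "fetal"), "D8": ("d8", "peak", "read_length"),
    "D9": ("d9", "ma", "maternal"), "D10": ("d10", "gw", "gestational"),
}


def read_supplementary_table(path: str | Path) -> dict[str, pd.DataFrame]:
    """Load an S1-style per-sample workbook: one sheet per chromosome 13/18/21.

    Returns ``{chrom: frame}`` with standardized columns sample_id, D1..D6,
    reported_z, real_state (+1/-1/NaN), group, and D7..D10 where present.
    Column headers are matched case-insensitively against the statistic
    names (Z_baseline_vs_n, ...) or D1..D10; optional columns that are
    absent yield NaN, never failure.
    """
    sheets = pd.read_excel(path, sheet_name=None)
    out: dict[str, pd.DataFrame] = {}
    for name, df in sheets.items():
        chrom = next((c for c in TARGET_CHROMS if c in str(name)), None)
        if chrom is None or df.empty and df.columns.empty:
            continue
        out[chrom] = _standardize_sheet(df, f"sheet {name}")
    if not out:
        raise FormatError("no sheet named for chromosome 13, 18 or 21")
    return out


def _match_col(columns: Sequence[str], aliases: tuple[str, ...]) -> str | None:
    low = {str(c).strip().lower(): c for c in columns}
    for alias in aliases:
        if alias in low:
            return low[alias]
    for alias in aliases:
        for k, orig in low.items():
            if alias in k:
                return orig
    return None


def _standardize_sheet(df: pd.DataFrame, where: str) -> pd.DataFrame:
    cols = list(df.columns)
    out = pd.DataFrame(index=df.index)
    sid = _match_col(cols, ("sample_id", "sample", "id"))
    out["sample_id"] = (df[sid].astype(str) if sid is not None
                        else [f"s{i}" for i in range(len(df))])
    found_z = 0
    for feat, aliases in _Z_ALIASES.items():
        col = _match_col(cols, aliases)
        if col is not None:
            found_z += 1
        out[feat] = pd.to_numeric(df[col], errors="coerce") if col is not None else np.nan
    if found_z == 0 and len(df):
        raise FormatError(f"{where}: no recognizable Z-score column")
    for feat, aliases in _AUX_ALIASES.items():
        col = _match_col(cols, aliases)
        out[feat] = pd.to_numeric(df[col], errors="coerce") if col is not None else np.nan
    zr = _match_col(cols, ("z_run", "reported_z", "reported z score", "zrun"))
    out["reported_z"] = pd.to_numeric(df[zr], errors="coerce") if zr is not None else np.nan
    st = _match_col(cols, ("real_state", "real", "actual", "state"))
    out["real_state"] = (df[st].map(_parse_state) if st is not None else None)
    grp = _match_col(cols, ("group", "grouping"))
    out["group"] = df[grp].astype(str).str.strip() if grp is not None else ""
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

_REPORT_COLS = (["sample_id", "chrom"] + [f"D{i}" for i in range(1, 11)]
                + ["qc_flag", "triage_group", "predicted_class",
                   "probability_negative", "probability_positive"])


def write_report(rows: Sequence[ResultRow], path: str | Path) -> None:
    """Write the screening report as TSV; missing values are empty fields."""
    data = []
    for r in rows:
        rec: dict[str, object] = {"sample_id": r.sample_id, "chrom": r.chrom,
                                  "qc_flag": r.qc_flag,
                                  "triage_group": r.triage_group}
        for i, v in enumerate(r.features, start=1):
            rec[f"D{i}"] = v
        rec["predicted_class"] = r.predicted_class
        rec["probability_negative"] = r.probability_negative
        rec["probability_positive"] = r.probability_positive
        data.append(rec)
    df = pd.DataFrame(data, columns=_REPORT_COLS)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g", na_rep="")


def read_report(path: str | Path) -> list[ResultRow]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    rows = []
    for _, r in df.iterrows():
        feats = tuple(float(r[f"D{i}"]) if pd.notna(r[f"D{i}"]) else math.nan
                      for i in range(1, 11))
        pc = _opt_float(r.get("predicted_class"))
        rows.append(ResultRow(
            sample_id=r["sample_id"], chrom=str(r["chrom"]), features=feats,
            qc_flag=r["qc_flag"], triage_group=r["triage_group"],
            predicted_class=None if pc is None else int(pc),
            probability_negative=_opt_float(r.get("probability_negative")),
            probability_positive=_opt_float(r.get("probability_positive"))))
    return rows
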