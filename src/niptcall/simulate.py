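"""Synthetic NIPT cohorts with the statistical structure the caller assumes.

A cohort is drawn on a scaled-down autosome grid (bins proportional to
true chromosome lengths, ~15,000 bins of 20 kb in total) so that a full
simulate-normalize-call cycle runs in seconds while per-chromosome window
counts and per-chromosome read counts stay realistic.  Each sample's
expected bin depth is

    E[depth] ∝ gc_bias(gc_bin) × chrom_effect × (1 + ff/2 on the trisomic
    chromosome)

— the trisomy uplift is exactly half the fetal fraction, because only the
fetal share of plasma DNA carries the third copy.  Counts are negative
binomial around that expectation (low-coverage bin depth is overdispersed
relative to Poisson; an infinite dispersion recovers Poisson), and a
per-sample, per-chromosome multiplicative effect models the residual
between-sample variation in chromosome representation that widens real
reference panels beyond counting noise.

Cohort arms mirror a screening workload: a reference panel of confirmed
negatives, large negative and small trisomic training arms, a held-out
"grey-zone" arm of low-fetal-fraction samples of both states, and a
QC-failure arm (too few reads or fetal fraction below 5%).  Metadata
(maternal age, gestational week, read-length peak) is drawn from
realistic ranges but carries no class signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .depth_io import (AUTOSOMES, TARGET_CHROMS, BinGrid, DepthMatrix,
                       SampleRecord)
from .errors import ParameterError
from .normalize import normalize_pipeline
from .zstats import build_reference_panel, z_baseline

# hg19 autosome lengths (Mb), used only for proportional bin allocation
_CHROM_MB = {
    "1": 249.25, "2": 243.20, "3": 198.02, "4": 191.15, "5": 180.92,
    "6": 171.12, "7": 159.14, "8": 146.36, "9": 141.21, "10": 135.53,
    "11": 135.01, "12": 133.85, "13": 115.17, "14": 107.35, "15": 102.53,
    "16": 90.35, "17": 81.20, "18": 78.08, "19": 59.13, "20": 63.03,
    "21": 48.13, "22": 51.30,
}


@dataclass
class SimConfig:
    """Cohort layout and noise model; defaults are the study conditions."""

    # grid
    n_bins_total: int = 15_000
    bin_width: int = 20_000
    gc_alpha: float = 39.5  # Beta parameters of bin GC (mean ~0.41, sd ~0.05)
    gc_beta: float = 56.8
    # sequencing depth (binned unique reads per sample)
    reads_mean: float = 3.5e6
    reads_sd: float = 3.0e5
    # GC bias: multiplicative quadratic in (gc - gc_pivot); (0, 0) disables it
    gc_bias_linear: float = 1.0
    gc_bias_quad: float = -8.0
    gc_pivot: float = 0.41
    # noise
    dispersion: float = 100.0  # negative-binomial size; inf -> Poisson
    chrom_effect_sd: float = 0.008  # lognormal sigma of per-chromosome effect
    # cohort arms
    n_ref: int = 200
    n_train_neg: int = 500
    n_train_pos_per_chrom: int = 30  # trisomies per target chromosome
    n_grey_pos_per_chrom: int = 10
    n_grey_neg: int = 30
    n_qcfail: int = 10
    # fetal fraction by arm
    ff_neg_mean: float = 0.11
    ff_neg_sd: float = 0.035
    ff_neg_range: tuple[float, float] = (0.05, 0.25)
    ff_train_pos_range: tuple[float, float] = (0.08, 0.15)
    ff_grey_range: tuple[float, float] = (0.05, 0.08)
    # metadata (no class signal)
    maternal_age_mean: float = 31.8
    maternal_age_sd: float = 4.5
    gestational_weeks: tuple[int, int] = (12, 27)
    read_length_peak_mean: float = 145.0
    read_length_peak_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins_total <= 0:
            raise ParameterError("n_bins_total must be positive")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be positive")
        for name in ("n_ref", "n_train_neg", "n_train_pos_per_chrom",
                     "n_grey_pos_per_chrom", "n_grey_neg", "n_qcfail"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class SimCohort:
    """A simulated cohort: grid, raw counts, metadata and arm assignment."""

    grid: BinGrid
    depth: DepthMatrix
    records: dict[str, SampleRecord]
    arms: dict[str, str]  # sample_id -> reference|train|grey|qcfail
    config: SimConfig

    def arm_ids(self, arm: str) -> list[str]:
        return [s for s in self.depth.sample_ids if self.arms[s] == arm]


def _make_grid(cfg: SimConfig, rng: np.random.Generator) -> BinGrid:
    total_mb = sum(_CHROM_MB.values())
    rows = []
    for chrom in AUTOSOMES:
        n = max(int(round(cfg.n_bins_total * _CHROM_MB[chrom] / total_mb)), 30)
        gc = rng.beta(cfg.gc_alpha, cfg.gc_beta, n)
        starts = np.arange(n) * cfg.bin_width
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + cfg.bin_width,
            "gc": gc, "usable": True}))
    return BinGrid(pd.concat(rows, ignore_index=True), cfg.bin_width)


def _gc_bias(cfg: SimConfig, gc: np.ndarray) -> np.ndarray:
    d = gc - cfg.gc_pivot
    return np.clip(1.0 + cfg.gc_bias_linear * d + cfg.gc_bias_quad * d * d,
                   0.05, None)


@dataclass
class _ArmSpec:
    arm: str
    n: int
    trisomy: str | None  # affected chromosome or None
    ff_draw: str  # "negative" | "grey" | "train_pos" | "qcfail_ff"
    low_reads: bool = False


def simulate_cohort(cfg: SimConfig | None = None,
                    seed: int | None = None) -> SimCohort:
    """Draw a full cohort; identical (cfg, seed) gives identical cohorts."""
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    grid = _make_grid(cfg, rng)
    gc = grid.usable_gc
    chrom_of = grid.usable_chrom
    base_weight = _gc_bias(cfg, gc)

    specs: list[_ArmSpec] = [
        _ArmSpec("reference", cfg.n_ref, None, "negative"),
        _ArmSpec("train", cfg.n_train_neg, None, "negative"),
    ]
    for c in TARGET_CHROMS:
        specs.append(_ArmSpec("train", cfg.n_train_pos_per_chrom, c, "train_pos"))
    for c in TARGET_CHROMS:
        specs.append(_ArmSpec("grey", cfg.n_grey_pos_per_chrom, c, "grey"))
    specs.append(_ArmSpec("grey", cfg.n_grey_neg, None, "grey"))
    # QC failures: alternate low-read and low-fetal-fraction causes, with a
    # few trisomies among them so the arm is not trivially all-negative
    for j in range(cfg.n_qcfail):
        trisomy = TARGET_CHROMS[j % 3] if j < 3 else None
        specs.append(_ArmSpec("qcfail", 1, trisomy,
                              "qcfail_ff" if j % 2 else "negative",
                              low_reads=(j % 2 == 0)))

    n_total = sum(s.n for s in specs)
    if n_total == 0:
        raise ParameterError("cohort has zero samples")
    counts = np.empty((n_total, gc.size))
    records: dict[str, SampleRecord] = {}
    arms: dict[str, str] = {}
    sample_ids: list[str] = []
    i = 0
    for spec in specs:
        for _ in range(spec.n):
            sid = f"{spec.arm}_{i:04d}"
            ff = _draw_ff(cfg, rng, spec.ff_draw)
            if spec.low_reads:
                reads = rng.uniform(1.2e6, 2.9e6)
            else:
                reads = max(rng.normal(cfg.reads_mean, cfg.reads_sd), 5e5)
            w = base_weight.copy()
            if cfg.chrom_effect_sd > 0:
                eff = rng.lognormal(0.0, cfg.chrom_effect_sd, len(AUTOSOMES))
                for c, e in zip(AUTOSOMES, eff):
                    w[chrom_of == c] *= e
            if spec.trisomy is not None:
                w[chrom_of == spec.trisomy] *= 1 + ff / 2
            mu = reads * w / w.sum()
            counts[i] = _draw_counts(rng, mu, cfg.dispersion)
            states = {c: 1 if c == spec.trisomy else -1 for c in TARGET_CHROMS}
            records[sid] = SampleRecord(
                sample_id=sid, run_id="run1",
                unique_reads=int(round(reads)),
                fetal_fraction=float(ff),
                read_length_peak=float(rng.normal(cfg.read_length_peak_mean,
                                                  cfg.read_length_peak_sd)),
                maternal_age=float(np.clip(round(rng.normal(
                    cfg.maternal_age_mean, cfg.maternal_age_sd)), 18, 46)),
                gestational_week=float(rng.integers(
                    cfg.gestational_weeks[0], cfg.gestational_weeks[1] + 1)),
                real_state=states)
            arms[sid] = spec.arm
            sample_ids.append(sid)
            i += 1
    depth = DepthMatrix(counts, sample_ids, grid)
    return SimCohort(grid, depth, records, arms, cfg)


def _draw_ff(cfg: SimConfig, rng: np.random.Generator, kind: str) -> float:
    if kind == "negative":
        lo, hi = cfg.ff_neg_range
        return float(np.clip(rng.normal(cfg.ff_neg_mean, cfg.ff_neg_sd), lo, hi))
    if kind == "train_pos":
        return float(rng.uniform(*cfg.ff_train_pos_range))
    if kind == "grey":
        return float(rng.uniform(*cfg.ff_grey_range))
    if kind == "qcfail_ff":
        return float(rng.uniform(0.01, 0.049))
    raise ParameterError(f"unknown fetal-fraction arm {kind!r}")


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 dispersion: float) -> np.ndarray:
    if np.isinf(dispersion):
        return rng.poisson(mu).astype(float)
    # NB with mean mu, variance mu + mu^2/size, via gamma-Poisson mixture
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    return rng.poisson(lam).astype(float)


# ---------------------------------------------------------------------------
# end-to-end screen of a simulated cohort
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """End-to-end screening outcome of a simulated cohort."""

    rows: list  # ResultRow per analysis sample x chromosome
    models: dict
    internal_accuracy: float  # vs true state, triage-N/P training rows
    holdout_accuracy: float  # vs true state, held-out grey arm
    overall_accuracy: float  # both sets combined
    n_internal: int
    n_holdout: int
    missed_trisomies: list[tuple[str, str]]  # ff >= 5% positives called -1
    false_positives: list[tuple[str, str]]  # negative rows called +1
    errors: list  # misclassified rows (any analysis arm)


def screen_cohort(cohort: SimCohort, svm_config=None,
                  use_true_labels: bool = False) -> ScreenResult:
    """Run the full caller on a simulated cohort and score it against truth.

    The reference arm builds the panel; the train arm is the only training
    candidate pool (its triage-N/P members train the per-chromosome
    models); every non-reference sample is predicted.  Accuracy is scored
    against the simulated true states: "internal" on the rows used in
    training, "holdout" on the grey arm.
    """
    from .classify import correction_workflow
    from .triage_features import GROUP_N, GROUP_P

    profiles = normalize_pipeline(cohort.depth)
    by_id = {p.sample_id: p for p in profiles}
    panel = build_reference_panel(
        [by_id[s] for s in cohort.arm_ids("reference")])
    analysis = [by_id[s] for s in cohort.depth.sample_ids
                if cohort.arms[s] != "reference"]
    result = correction_workflow(analysis, cohort.records, panel,
                                 cfg=svm_config,
                                 train_ids=set(cohort.arm_ids("train")),
                                 use_true_labels=use_true_labels)
    n_int = n_int_ok = n_hold = n_hold_ok = 0
    missed, false_pos, errors = [], [], []
    for row in result.rows:
        rec = cohort.records[row.sample_id]
        truth = rec.real_state[row.chrom]
        ok = row.predicted_class == truth
        arm = cohort.arms[row.sample_id]
        if arm == "train" and row.triage_group in (GROUP_N, GROUP_P):
            n_int += 1
            n_int_ok += ok
        elif arm == "grey":
            n_hold += 1
            n_hold_ok += ok
        if not ok:
            errors.append(row)
            if truth == 1 and rec.fetal_fraction >= 0.05:
                missed.append((row.sample_id, row.chrom))
            elif truth == -1:
                false_pos.append((row.sample_id, row.chrom))
    return ScreenResult(
        rows=result.rows, models=result.models,
        internal_accuracy=n_int_ok / n_int if n_int else float("nan"),
        holdout_accuracy=n_hold_ok / n_hold if n_hold else float("nan"),
        overall_accuracy=((n_int_ok + n_hold_ok) / (n_int + n_hold)
                          if n_int + n_hold else float("nan")),
        n_internal=n_int, n_holdout=n_hold,
        missed_trisomies=missed, false_positives=false_pos, errors=errors)


# ---------------------------------------------------------------------------
# bootstrap study of Z separability vs fetal fraction
# ---------------------------------------------------------------------------

def bootstrap_z_study(cfg: SimConfig | None = None, n_boot: int = 10_000,
                      n_pool: int = 150, chrom: str = "21",
                      seed: int | None = None) -> pd.DataFrame:
    """Empirical run-Z distributions for three arms: negative, trisomy at
    5% fetal fraction, trisomy at 10% fetal fraction.

    A reference panel and three pools of simulated samples are drawn
    (positive pools with the uplift fixed at the arm's fetal fraction);
    each arm's Z distribution is bootstrapped by resampling its pool's
    baseline Z scores ``n_boot`` times.  The summary reports, per arm, the
    mean and s.d. of Z, the mass inside the grey zone [1.96, 4] and the
    mass beyond the legacy Z = 3 cutoff.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed + 1)

    arm_ffs = {"negative": None, "trisomy_ff5": 0.05, "trisomy_ff10": 0.10}
    pool_cfg = replace(
        cfg, n_train_neg=n_pool, n_train_pos_per_chrom=0,
        n_grey_pos_per_chrom=0, n_grey_neg=0, n_qcfail=0,
        ff_neg_mean=0.10)
    rows = []
    for arm_index, (arm, ff) in enumerate(arm_ffs.items()):
        arm_cfg = pool_cfg
        if ff is not None:
            arm_cfg = replace(pool_cfg, n_train_neg=0,
                              n_train_pos_per_chrom=n_pool,
                              ff_train_pos_range=(ff, ff))
        cohort = simulate_cohort(arm_cfg, seed=cfg.seed + 101 * (arm_index + 1))
        pool_ids = [s for s in cohort.arm_ids("train")
                    if ff is None or cohort.records[s].real_state[chrom] == 1]
        keep = cohort.arm_ids("reference") + pool_ids
        idx = [cohort.depth.sample_ids.index(s) for s in keep]
        sub = DepthMatrix(cohort.depth.values[idx], keep, cohort.grid)
        profiles = normalize_pipeline(sub)
        by_id = {p.sample_id: p for p in profiles}
        panel = build_reference_panel(
            [by_id[s] for s in cohort.arm_ids("reference")])
        zs = []
        for sid in pool_ids:
            d1, _ = z_baseline(by_id[sid].chrom_stats[chrom].mean, panel,
                               chrom, cohort.records[sid].fetal_fraction)
            zs.append(d1)
        zs = np.array(zs)
        boot = rng.choice(zs, size=n_boot, replace=True)
        rows.append({
            "arm": arm, "fetal_fraction": ff, "n_pool": zs.size,
            "n_boot": n_boot,
            "z_mean": float(boot.mean()), "z_sd": float(boot.std(ddof=1)),
            "frac_grey_zone": float(np.mean((boot >= 1.96) & (boot <= 4.0))),
            "frac_beyond_3": float(np.mean(boot > 3.0))})
    return pd.DataFrame(rows)
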