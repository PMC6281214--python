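"""Reference panel and the six trisomy Z statistics.

For a target chromosome *i* the normalized merged-depth mean ``mean_i`` of
a test sample is standardized against three baselines, each in a
"versus-negative" and a "versus-positive" form:

* **baseline** — the reference panel of confirmed-negative samples:
  ``D1 = (mean_i - mean(ref_i)) / sd(ref_i)``, and ``D2`` replaces
  ``mean(ref_i)`` by the predicted-positive baseline
  ``mean(ref_i) * (1 + ff/2)``, where ``ff`` is the fetal fraction (a
  trisomic chromosome gains half the fetal fraction in expected depth);
* **internal chromosome** — the sample's own median over autosome means
  replaces the panel mean in the numerator (``D3``/``D4``), keeping the
  panel s.d. as scale;
* **within-sample** — the numerator of ``D1``/``D2`` over a robust
  standard error of the chromosome mean,
  ``Sm * MAD_i / sqrt(window_i)`` with ``Sm = 1.4826`` rescaling the MAD
  to a normal s.d. (``D5``/``D6``).

A true trisomy therefore pushes the *_vs_n* scores up and sits near zero
on the *_vs_p* scores; a normal sample does the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .depth_io import SampleRecord, TARGET_CHROMS
from .errors import (DegeneratePanelError, DegenerateScaleError,
                     InsufficientPanelError, InsufficientWindowsError,
                     ParameterError)
from .normalize import MergedProfile

#: MAD-to-s.d. factor for normal data, 1 / Phi^-1(3/4) rounded to 4 decimals.
MAD_SCALE: float = 1.4826


@dataclass
class ReferencePanel:
    """Per-chromosome location/scale of confirmed-negative samples.

    ``ref_mean[c]`` is the mean over panel samples of their chromosome-c
    merged-depth mean; ``ref_sd[c]`` the n-1 standard deviation of those
    per-sample means.
    """

    ref_mean: dict[str, float]
    ref_sd: dict[str, float]
    n_ref: int
    grid_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.n_ref < 2:
            raise InsufficientPanelError("a reference panel needs >= 2 samples")
        for c, sd in self.ref_sd.items():
            if not sd > 0:
                raise DegeneratePanelError(
                    f"zero panel spread on chromosome {c}")


@dataclass
class ZVector:
    """The six Z statistics of one sample on one target chromosome."""

    chrom: str
    d1: float
    d2: float
    d3: float
    d4: float
    d5: float
    d6: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.d1, self.d2, self.d3, self.d4, self.d5, self.d6)


@dataclass
class ScreeningBurden:
    """Expected error counts for a population screening programme."""

    n_screened: float
    prevalence: float
    sensitivity: float
    specificity: float
    procedure_loss_rate: float
    expected_fn: int = field(init=False)
    expected_fp: int = field(init=False)
    expected_procedure_losses: int = field(init=False)

    def __post_init__(self) -> None:
        for name in ("prevalence", "sensitivity", "specificity",
                     "procedure_loss_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        n, p = self.n_screened, self.prevalence
        self.expected_fn = _round_half_away(n * p * (1 - self.sensitivity))
        self.expected_fp = _round_half_away(n * (1 - p) * (1 - self.specificity))
        self.expected_procedure_losses = _round_half_away(
            self.expected_fp * self.procedure_loss_rate)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

def build_reference_panel(profiles: Sequence[MergedProfile],
                          chroms: Iterable[str] = TARGET_CHROMS
                          ) -> ReferencePanel:
    """Per-chromosome mean and n-1 s.d. of panel samples' chromosome means."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise InsufficientPanelError(
            f"need >= 2 reference profiles, got {len(profiles)}")
    fps = {p.grid_fingerprint for p in profiles}
    if len(fps) > 1:
        raise ParameterError("reference profiles come from different grids")
    ref_mean, ref_sd = {}, {}
    for c in chroms:
        means = np.array([p.chrom_stats[c].mean for p in profiles])
        ref_mean[c] = float(means.mean())
        ref_sd[c] = float(means.std(ddof=1))
    return ReferencePanel(ref_mean, ref_sd, len(profiles),
                          grid_fingerprint=fps.pop())


# ---------------------------------------------------------------------------
# the six Z statistics
# ---------------------------------------------------------------------------

def _check_ff(fetal_fraction: float) -> float:
    if not 0 <= fetal_fraction <= 1:
        raise ParameterError(
            f"fetal_fraction must be a fraction in [0, 1], got {fetal_fraction}")
    return fetal_fraction


def z_baseline(mean_i: float, panel: ReferencePanel, chrom: str,
               fetal_fraction: float) -> tuple[float, float]:
    """Z against the reference-negative baseline and its predicted-positive
    counterpart (baseline uplifted by 1 + ff/2)."""
    ff = _check_ff(fetal_fraction)
    mu, sd = panel.ref_mean[chrom], panel.ref_sd[chrom]
    if not sd > 0:
        raise DegeneratePanelError(f"zero panel s.d. on chromosome {chrom}")
    d1 = (mean_i - mu) / sd
    d2 = (mean_i - mu * (1 + ff / 2)) / sd
    return d1, d2


def z_chr(mean_i: float, autosome_median: float, panel: ReferencePanel,
          chrom: str, fetal_fraction: float) -> tuple[float, float]:
    """Z against the sample's internal autosome-median reference."""
    ff = _check_ff(fetal_fraction)
    sd = panel.ref_sd[chrom]
    if not sd > 0:
        raise DegeneratePanelError(f"zero panel s.d. on chromosome {chrom}")
    d3 = (mean_i - autosome_median) / sd
    d4 = (mean_i - autosome_median * (1 + ff / 2)) / sd
    return d3, d4


def z_sample(mean_i: float, panel: ReferencePanel, chrom: str, mad_i: float,
             window_i: int, fetal_fraction: float,
             sem_denominator: str = "sqrt") -> tuple[float, float]:
    """Z against the panel mean scaled by the sample's own robust standard
    error, Sm * MAD_i / sqrt(window_i).

    ``sem_denominator="linear"`` divides by window_i instead of its square
    root (an alternative reading of the window-count scaling, kept as an
    explicit option).
    """
    ff = _check_ff(fetal_fraction)
    if window_i < 2:
        raise InsufficientWindowsError(
            f"chromosome {chrom}: need >= 2 merged windows, got {window_i}")
    if not mad_i > 0:
        raise DegenerateScaleError(f"chromosome {chrom}: zero MAD")
    if sem_denominator not in ("sqrt", "linear"):
        raise ParameterError("sem_denominator must be 'sqrt' or 'linear'")
    scale = np.sqrt(window_i) if sem_denominator == "sqrt" else window_i
    denom = MAD_SCALE * mad_i / scale
    mu = panel.ref_mean[chrom]
    d5 = (mean_i - mu) / denom
    d6 = (mean_i - mu * (1 + ff / 2)) / denom
    return d5, d6


def compute_z_vector(profile: MergedProfile, panel: ReferencePanel,
                     record: SampleRecord,
                     chroms: Iterable[str] = TARGET_CHROMS
                     ) -> dict[str, ZVector]:
    """All six Z statistics for each target chromosome of one sample."""
    if (profile.grid_fingerprint and panel.grid_fingerprint
            and profile.grid_fingerprint != panel.grid_fingerprint):
        raise ParameterError(
            f"{profile.sample_id}: profile and panel use different grids")
    ff = record.fetal_fraction
    if ff is None:
        raise ParameterError(f"{record.sample_id}: fetal fraction is required")
    out = {}
    for c in chroms:
        st = profile.chrom_stats[c]
        d1, d2 = z_baseline(st.mean, panel, c, ff)
        d3, d4 = z_chr(st.mean, profile.autosome_median, panel, c, ff)
        d5, d6 = z_sample(st.mean, panel, c, st.mad, st.windows, ff)
        out[c] = ZVector(c, d1, d2, d3, d4, d5, d6)
    return out


# ---------------------------------------------------------------------------
# screening-burden arithmetic
# ---------------------------------------------------------------------------

def screening_burden(n_screened: float, prevalence: float, sensitivity: float,
                     specificity: float,
                     procedure_loss_rate: float) -> ScreeningBurden:
    """Expected false calls and procedure losses of a screening programme.

    ``expected_fn = n * prevalence * (1 - sensitivity)`` and
    ``expected_fp = n * (1 - prevalence) * (1 - specificity)``, rounded
    half-away-from-zero; every false positive is referred to an invasive
    confirmation procedure, of which ``procedure_loss_rate`` end in the
    loss of an unaffected pregnancy.
    """
    return ScreeningBurden(n_screened, prevalence, sensitivity, specificity,
                           procedure_loss_rate)


# ---------------------------------------------------------------------------
# panel persistence (TSV: chrom, ref_mean, ref_sd, n_ref, fingerprint)
# ---------------------------------------------------------------------------

def write_panel(panel: ReferencePanel, path) -> None:
    import pandas as pd

    rows = [{"chrom": c, "ref_mean": panel.ref_mean[c],
             "ref_sd": panel.ref_sd[c], "n_ref": panel.n_ref,
             "fingerprint": panel.grid_fingerprint}
            for c in panel.ref_mean]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_panel(path) -> ReferencePanel:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fp = str(df["fingerprint"].iloc[0]) if "fingerprint" in df else ""
    return ReferencePanel(
        ref_mean=dict(zip(df["chrom"], df["ref_mean"].astype(float))),
        ref_sd=dict(zip(df["chrom"], df["ref_sd"].astype(float))),
        n_ref=int(df["n_ref"].iloc[0]), grid_fingerprint=fp)
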