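import numpy as np
import pandas as pd
import pytest

from niptcall import (BinGrid, DepthMatrix, SimConfig, screen_cohort,
                      simulate_cohort)


def make_grid(bins_per_chrom: dict[str, int], gc=None, seed: int = 0) -> BinGrid:
    """A hand-built grid: given bin counts per chromosome, random GC."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, n in bins_per_chrom.items():
        starts = np.arange(n) * 20_000
        g = gc if gc is not None else rng.uniform(0.3, 0.6, n)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + 20_000,
            "gc": np.broadcast_to(g, (n,)), "usable": True}))
    return BinGrid(pd.concat(rows, ignore_index=True))


@pytest.fixture
def tiny_grid() -> BinGrid:
    """45 bins on four chromosomes: enough for 3 full 15-bin windows each."""
    return make_grid({"1": 45, "13": 45, "18": 45, "21": 45})


@pytest.fixture(scope="session")
def default_cohort():
    """The seed-1 default simulated cohort (the headline study conditions)."""
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def default_screen(default_cohort):
    """Full pipeline + per-chromosome SVM correction on the default cohort."""
    return screen_cohort(default_cohort)


@pytest.fixture(scope="session")
def small_null_cohort():
    """A GC-flat, trisomy-free cohort for null-distribution checks."""
    cfg = SimConfig(n_bins_total=4000, gc_bias_linear=0.0, gc_bias_quad=0.0,
                    n_ref=80, n_train_neg=60, n_train_pos_per_chrom=0,
                    n_grey_pos_per_chrom=0, n_grey_neg=0, n_qcfail=0)
    return simulate_cohort(cfg, seed=7)
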