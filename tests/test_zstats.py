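import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from niptcall import (MAD_SCALE, ReferencePanel, build_reference_panel,
                      compute_z_vector, read_panel, screening_burden,
                      write_panel, z_baseline, z_chr, z_sample)
from niptcall.depth_io import SampleRecord
from niptcall.errors import (DegeneratePanelError, DegenerateScaleError,
                             InsufficientPanelError, InsufficientWindowsError,
                             ParameterError)
from niptcall.normalize import ChromStats, MergedProfile


def _profile(sid, means, mads=None, windows=25):
    stats = {}
    for chrom, mean in means.items():
        mad = (mads or {}).get(chrom, 0.1)
        merged = np.full(windows, mean / windows)
        stats[chrom] = ChromStats(merged, mean, 0.1, mad, windows)
    return MergedProfile(sid, stats,
                         autosome_median=float(np.median(list(means.values()))),
                         grid_fingerprint="fp")


def _panel(mean=1.0, sd=0.01):
    return ReferencePanel({c: mean for c in ("13", "18", "21")},
                          {c: sd for c in ("13", "18", "21")}, n_ref=10,
                          grid_fingerprint="fp")


class TestReferencePanel:
    def test_two_sample_arithmetic(self):
        p = build_reference_panel([
            _profile("a", {"13": 15.0, "18": 15.0, "21": 14.9}),
            _profile("b", {"13": 15.0, "18": 15.0, "21": 15.1})],
            chroms=("21",))
        assert p.ref_mean["21"] == pytest.approx(15.0)
        assert p.ref_sd["21"] == pytest.approx(0.1414, abs=1e-4)

    def test_order_invariant(self):
        profs = [_profile(f"s{i}", {"21": 15 + 0.01 * i}) for i in range(5)]
        a = build_reference_panel(profs, chroms=("21",))
        b = build_reference_panel(profs[::-1], chroms=("21",))
        assert a.ref_mean == b.ref_mean and a.ref_sd == b.ref_sd

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegeneratePanelError):
            build_reference_panel([_profile("a", {"21": 15.0}),
                                   _profile("b", {"21": 15.0})], chroms=("21",))

    def test_too_few_profiles(self):
        with pytest.raises(InsufficientPanelError):
            build_reference_panel([_profile("a", {"21": 15.0})], chroms=("21",))


class TestZFormulas:
    def test_baseline_direct_arithmetic(self):
        panel = _panel(mean=1.0, sd=0.01)
        d1, d2 = z_baseline(1.05, panel, "21", fetal_fraction=0.10)
        assert d1 == pytest.approx(5.0)
        # a true trisomy at 10% fetal fraction sits on the positive baseline
        assert d2 == pytest.approx(0.0, abs=1e-12)

    def test_baseline_identity_and_ff_collapse(self):
        panel = _panel()
        assert z_baseline(1.0, panel, "21", 0.0)[0] == 0.0
        d1, d2 = z_baseline(1.07, panel, "21", 0.0)
        assert d1 == d2

    def test_chr_direct_arithmetic(self):
        panel = _panel(sd=0.1)
        d3, d4 = z_chr(15.3, 15.0, panel, "21", fetal_fraction=0.04)
        assert d3 == pytest.approx(3.0)
        assert d4 == pytest.approx(0.0, abs=1e-9)

    def test_sample_direct_arithmetic(self):
        panel = _panel(mean=1.0)
        d5, _ = z_sample(1.02, panel, "21", mad_i=0.10, window_i=25,
                         fetal_fraction=0.0)
        denom = 1.4826 * 0.10 / 5
        assert denom == pytest.approx(0.029652)
        assert d5 == pytest.approx(0.02 / denom)
        assert d5 == pytest.approx(0.6745, abs=1e-4)

    def test_sample_degenerate_inputs(self):
        panel = _panel()
        with pytest.raises(DegenerateScaleError):
            z_sample(1.0, panel, "21", mad_i=0.0, window_i=25, fetal_fraction=0)
        with pytest.raises(InsufficientWindowsError):
            z_sample(1.0, panel, "21", mad_i=0.1, window_i=1, fetal_fraction=0)

    def test_linear_sem_option(self):
        panel = _panel()
        sqrt_d5, _ = z_sample(1.02, panel, "21", 0.1, 25, 0.0)
        lin_d5, _ = z_sample(1.02, panel, "21", 0.1, 25, 0.0,
                             sem_denominator="linear")
        assert lin_d5 == pytest.approx(sqrt_d5 * 5)

    def test_invalid_fetal_fraction(self):
        with pytest.raises(ParameterError):
            z_baseline(1.0, _panel(), "21", fetal_fraction=5.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(mean_i=st.floats(0.5, 2.0), ff=st.floats(1e-6, 0.5),
           median=st.floats(0.5, 2.0))
    def test_positive_baseline_orders_below_negative(self, mean_i, ff, median):
        """D2 < D1, D4 < D3 and D6 < D5 whenever ff > 0: the predicted-positive
        baseline subtracts a strictly larger (positive) location."""
        panel = _panel(mean=1.0, sd=0.02)
        d1, d2 = z_baseline(mean_i, panel, "21", ff)
        d3, d4 = z_chr(mean_i, median, panel, "21", ff)
        d5, d6 = z_sample(mean_i, panel, "21", 0.05, 16, ff)
        assert d2 < d1 and d4 < d3 and d6 < d5


class TestComputeZVector:
    def _record(self, ff=0.1):
        return SampleRecord("s", fetal_fraction=ff,
                            real_state={c: None for c in ("13", "18", "21")})

    def test_matches_per_formula_recomputation(self):
        """Aggregated Z vectors equal brute-force per-formula recomputation
        from the merged profile, exactly."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            means = {c: rng.uniform(10, 20)
                     for c in [str(i) for i in range(1, 23)]}
            mads = {c: rng.uniform(0.05, 0.5) for c in means}
            prof = _profile("s", means, mads, windows=int(rng.integers(5, 40)))
            panel = ReferencePanel(
                {c: rng.uniform(10, 20) for c in ("13", "18", "21")},
                {c: rng.uniform(0.05, 0.5) for c in ("13", "18", "21")},
                n_ref=10, grid_fingerprint="fp")
            ff = rng.uniform(0, 0.3)
            zv = compute_z_vector(prof, panel, self._record(ff))
            med = float(np.median([means[c] for c in means]))
            for c in ("13", "18", "21"):
                st_ = prof.chrom_stats[c]
                denom = 1.4826 * st_.mad / math.sqrt(st_.windows)
                expect = (
                    (st_.mean - panel.ref_mean[c]) / panel.ref_sd[c],
                    (st_.mean - panel.ref_mean[c] * (1 + ff / 2)) / panel.ref_sd[c],
                    (st_.mean - med) / panel.ref_sd[c],
                    (st_.mean - med * (1 + ff / 2)) / panel.ref_sd[c],
                    (st_.mean - panel.ref_mean[c]) / denom,
                    (st_.mean - panel.ref_mean[c] * (1 + ff / 2)) / denom)
                np.testing.assert_allclose(zv[c].as_tuple(), expect, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        prof = _profile("s", {c: 15.0 for c in ("13", "18", "21")})
        panel = ReferencePanel({c: 15.0 for c in ("13", "18", "21")},
                               {c: 0.1 for c in ("13", "18", "21")}, 10,
                               grid_fingerprint="other")
        with pytest.raises(ParameterError):
            compute_z_vector(prof, panel, self._record())

    def test_missing_fetal_fraction_rejected(self):
        prof = _profile("s", {c: 15.0 for c in ("13", "18", "21")})
        with pytest.raises(ParameterError):
            compute_z_vector(prof, _panel(15.0, 0.1), self._record(ff=None))


class TestMadScale:
    def test_constant_is_inverse_upper_quartile(self):
        assert round(1 / norm.ppf(0.75), 4) == MAD_SCALE == 1.4826

    def test_scaled_mad_estimates_normal_sd(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(10_000)
        mad = np.median(np.abs(x - np.median(x)))
        assert MAD_SCALE * mad == pytest.approx(1.0, rel=0.02)


class TestScreeningBurden:
    def test_population_screening_arithmetic(self):
        b = screening_burden(1e6, 0.01, 0.979, 0.997, 1 / 250)
        assert b.expected_fn == 210
        assert b.expected_fp == 2970
        assert b.expected_procedure_losses == 12  # 2970/250 = 11.88 rounds up

    def test_perfect_test(self):
        b = screening_burden(1e6, 0.01, 1.0, 1.0, 1 / 250)
        assert (b.expected_fn, b.expected_fp,
                b.expected_procedure_losses) == (0, 0, 0)

    def test_zero_prevalence(self):
        b = screening_burden(1000, 0.0, 0.5, 0.99, 0.0)
        assert b.expected_fn == 0
        assert b.expected_fp == 10

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            screening_burden(1e6, 1.5, 0.9, 0.9, 0.0)


def test_panel_roundtrip(tmp_path):
    panel = _panel(mean=15.0, sd=0.12)
    write_panel(panel, tmp_path / "panel.tsv")
    back = read_panel(tmp_path / "panel.tsv")
    assert back.ref_mean == panel.ref_mean
    assert back.ref_sd == panel.ref_sd
    assert back.n_ref == panel.n_ref
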