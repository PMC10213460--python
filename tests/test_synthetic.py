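"""Ground-truth generators: mass conservation, closed-form mixtures,
determinism and cohort construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ctfrac.electropherogram import LMW_REGION, MONO_REGION, integrate_region, \
    mono_nucleosomal_ratio
from ctfrac.synthetic import (
    CNVSimParams,
    FragmentomicsParams,
    MethylomeSimParams,
    SimTruth,
    expected_depth_per_bin,
    simulate_cohort,
    simulate_depth,
    simulate_methylome,
    simulate_trace,
)


def analytic_ratio(params: FragmentomicsParams) -> float:
    """Independent oracle: integrate the Gaussian ladder via the normal CDF."""
    f, s = params.tumor_fraction, params.peak_sigma

    def mass(center, weight, lo, hi):
        return weight * (norm.cdf((hi - center) / s) - norm.cdf((lo - center) / s))

    mono = total = 0.0
    for k in range(1, max(params.n_tumor_peaks, params.n_normal_peaks) + 1):
        c = k * params.nucleosome_unit
        w = 0.0
        if k <= params.n_tumor_peaks:
            w += f * params.tumor_peak_decay ** (k - 1)
        if k <= params.n_normal_peaks:
            w += (1 - f) * params.normal_peak_growth ** (k - 1)
        mono += mass(c, w, *MONO_REGION)
        total += mass(c, w, *LMW_REGION)
    return mono / total


class TestTrace:
    @pytest.mark.parametrize("f", [0.0, 0.3, 0.7, 1.0])
    def test_in_window_mass_conservation(self, f):
        params = FragmentomicsParams(tumor_fraction=f, total_mass=24.2)
        tr = simulate_trace(params)
        area = integrate_region(tr, *LMW_REGION).area
        assert area == pytest.approx(24.2, rel=0.005)

    def test_pure_normal_ratio_below_cutoff_and_matches_erf_oracle(self):
        params = FragmentomicsParams(tumor_fraction=0.0, normal_peak_growth=1.3)
        observed = mono_nucleosomal_ratio(simulate_trace(params)).ratio
        assert observed < 0.1
        assert observed == pytest.approx(analytic_ratio(params), abs=1e-3)

    @pytest.mark.parametrize("f", [0.2, 0.6])
    def test_mixture_ratio_matches_erf_oracle(self, f):
        params = FragmentomicsParams(tumor_fraction=f)
        observed = mono_nucleosomal_ratio(simulate_trace(params)).ratio
        assert observed == pytest.approx(analytic_ratio(params), abs=1e-3)

    def test_ratio_monotone_in_tumor_fraction(self):
        ratios = [mono_nucleosomal_ratio(
            simulate_trace(FragmentomicsParams(tumor_fraction=f))).ratio
            for f in np.arange(0.0, 1.01, 0.1)]
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))

    def test_deterministic_under_fixed_seed(self):
        params = FragmentomicsParams(tumor_fraction=0.5, baseline_noise_sd=0.05,
                                     seed=9)
        a = simulate_trace(params)
        b = simulate_trace(params)
        assert np.array_equal(a.fluorescence, b.fluorescence)
        c = simulate_trace(FragmentomicsParams(tumor_fraction=0.5,
                                               baseline_noise_sd=0.05, seed=10))
        assert not np.array_equal(a.fluorescence, c.fluorescence)

    def test_high_mw_material_stays_outside_analysis_window(self):
        with_hmw = simulate_trace(FragmentomicsParams(tumor_fraction=0.3,
                                                      high_mw_mass=800.0))
        without = simulate_trace(FragmentomicsParams(tumor_fraction=0.3))
        a = integrate_region(with_hmw, *LMW_REGION).area
        b = integrate_region(without, *LMW_REGION).area
        assert a == pytest.approx(b, rel=0.005)

    @pytest.mark.parametrize("bad", [{"tumor_fraction": 1.2},
                                     {"tumor_fraction": -0.1},
                                     {"peak_sigma": 0.0},
                                     {"total_mass": -1.0},
                                     {"tumor_peak_decay": 1.5}])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            FragmentomicsParams(**bad)


class TestMethylome:
    def test_pure_normal_mean_matches_beta_normal(self):
        params = MethylomeSimParams(tumor_fraction=0.0, block_spans=(),
                                    deep_spans=(), n_chroms=2,
                                    bins_per_chrom=100, seed=4)
        calls = simulate_methylome(params)
        pooled = calls["methylated"].sum() / calls["total"].sum()
        se = np.sqrt(0.85 * 0.15 / calls["total"].sum())
        assert abs(pooled - 0.85) < 3 * se

    def test_mixture_mean_identity_in_block(self):
        # closed form: 0.5*0.85 + 0.5*0.15 = 0.5 when the block sits on
        # normally fully-methylated background
        params = MethylomeSimParams(tumor_fraction=0.5, n_chroms=1,
                                    bins_per_chrom=200, cpgs_per_bin=10.0,
                                    block_spans=(("chr1", 0, 200),),
                                    beta_normal_block=0.85, deep_spans=(),
                                    seed=5)
        calls = simulate_methylome(params)
        assert calls["total"].sum() > 10_000
        pooled = calls["methylated"].sum() / calls["total"].sum()
        se = np.sqrt(0.5 * 0.5 / calls["total"].sum())
        assert abs(pooled - 0.5) < 3 * se

    def test_pure_tumor_block_sites_at_block_level(self):
        params = MethylomeSimParams(tumor_fraction=1.0, n_chroms=1,
                                    bins_per_chrom=50, cpgs_per_bin=10.0,
                                    block_spans=(("chr1", 0, 50),),
                                    deep_spans=(), seed=6)
        calls = simulate_methylome(params)
        pooled = calls["methylated"].sum() / calls["total"].sum()
        se = np.sqrt(0.15 * 0.85 / calls["total"].sum())
        assert abs(pooled - 0.15) < 3 * se

    def test_deterministic_under_fixed_seed(self):
        params = MethylomeSimParams(seed=11)
        pd.testing.assert_frame_equal(simulate_methylome(params),
                                      simulate_methylome(params))

    @pytest.mark.parametrize("bad", [{"beta_normal": 1.2},
                                     {"beta_tumor_block": -0.1},
                                     {"coverage_mean": 0.0},
                                     {"block_spans": (("chr99", 0, 10),)},
                                     {"block_spans": (("chr1", 0, 999),)}])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            MethylomeSimParams(**bad)


class TestDepth:
    def test_expected_log2_closed_forms(self):
        # f=1, CN=4 -> log2(4/2) = 1;  f=0.5, CN=1 -> log2(1.5/2) = -0.415
        p1 = CNVSimParams(segment_table=(("chr1", 0, 50, 4),), tumor_fraction=1.0)
        e1 = expected_depth_per_bin(p1)
        assert np.log2(e1["chr1"][0] / p1.mean_depth) == pytest.approx(1.0)
        p2 = CNVSimParams(segment_table=(("chr1", 0, 50, 1),), tumor_fraction=0.5)
        e2 = expected_depth_per_bin(p2)
        assert np.log2(e2["chr1"][0] / p2.mean_depth) == pytest.approx(-0.415, abs=1e-3)
        p3 = CNVSimParams(segment_table=(("chr1", 0, 50, 7),), tumor_fraction=0.0)
        e3 = expected_depth_per_bin(p3)
        assert np.log2(e3["chr1"][0] / p3.mean_depth) == pytest.approx(0.0)

    def test_empirical_depth_matches_expectation(self):
        params = CNVSimParams(segment_table=(("chr11", 30, 100, 1),),
                              tumor_fraction=0.5, seed=2)
        depth = simulate_depth(params)
        ev = depth.loc[(depth.chrom == "chr11")
                       & (depth.start >= 30_000_000)
                       & (depth.start < 100_000_000), "depth"]
        expected = params.mean_depth * 0.75
        se = np.sqrt(params.overdispersion * expected / len(ev))
        assert abs(ev.mean() - expected) < 3 * se

    def test_deterministic_under_fixed_seed(self):
        params = CNVSimParams(seed=3)
        pd.testing.assert_frame_equal(simulate_depth(params),
                                      simulate_depth(params))

    @pytest.mark.parametrize("bad", [
        {"mean_depth": 0.0},
        {"overdispersion": 0.5},
        {"segment_table": (("chr1", 0, 10, -1),)},
        {"segment_table": (("chr1", 0, 10, 3), ("chr1", 5, 20, 1))},
        {"segment_table": (("chrZ", 0, 10, 3),)},
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            CNVSimParams(**bad)


class TestCohort:
    def test_diagnosis_has_more_mono_nucleosomal_mass(self):
        fixture = simulate_cohort(10, 10, seed=21, noise_free_traces=True)
        mono = {"diagnosis": [], "relapse": []}
        for s in fixture.samples:
            area = integrate_region(s.trace, *MONO_REGION).area
            mono[s.truth.timepoint].append(area)
        assert np.mean(mono["diagnosis"]) > np.mean(mono["relapse"])

    def test_fixture_files_byte_identical_for_fixed_seed(self, tmp_path):
        a = simulate_cohort(3, 3, seed=8).write(tmp_path / "a")
        b = simulate_cohort(3, 3, seed=8).write(tmp_path / "b")
        files_a = sorted(p.name for p in a.iterdir())
        assert files_a == sorted(p.name for p in b.iterdir())
        for name in files_a:
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_paired_patients_share_ids_across_timepoints(self):
        fixture = simulate_cohort(5, 3, seed=1)
        tt = fixture.truth_table
        diag = set(tt.loc[tt.timepoint == "diagnosis", "patient_id"])
        rel = set(tt.loc[tt.timepoint == "relapse", "patient_id"])
        assert len(diag & rel) == 3
        assert len(tt) == 8

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(0, 5)

    def test_inverted_f_distributions_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(5, 5, f_distributions={"diagnosis": (0.0, 0.2),
                                                   "relapse": (0.5, 0.9)})

    def test_truth_label_consistency_enforced(self):
        with pytest.raises(ValueError):
            SimTruth(sample_id="s", patient_id="p", timepoint="diagnosis",
                     tumor_fraction=0.5, true_label="normal", events=())
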