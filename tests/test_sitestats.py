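import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_stepup, fisher_two_sided_enum, fst_nei
from chronoscan.sitestats import (
    afd,
    bh_adjust,
    contrast_from_summary,
    fisher_site,
    fst_site,
    pool_allele_frequency,
    site_scan,
    z_contrast,
)
from chronoscan.simdata import SimConfig, simulate_pool_counts, simulate_site_frequencies


class TestAlleleFrequency:
    def test_direct_ratio(self):
        assert pool_allele_frequency(((30, 10), (10, 30)), 0) == 0.75
        assert pool_allele_frequency(((30, 10), (10, 30)), 1) == 0.25

    def test_fixed_allele(self):
        assert pool_allele_frequency(((12, 0), (5, 5)), 0) == 1.0

    def test_zero_coverage_is_an_error(self):
        with pytest.raises(ValueError, match="zero coverage"):
            pool_allele_frequency(((0, 0), (5, 5)), 0)

    def test_recovers_planted_frequency_through_both_sampling_stages(self):
        import pandas as pd

        from chronoscan.simdata import SimTruth

        q = 0.25
        sites = pd.DataFrame(
            {"scaffold": "scaffold_1", "position": np.arange(1, 501), "q_anc": q}
        )
        sites["q_pool0"] = q
        sites["q_pool1"] = q
        sites["planted"] = False
        cfg = SimConfig(error_rate=0.0, depth_mean=30.0, seed=12)
        records = simulate_pool_counts(SimTruth(sites=sites), cfg)
        freqs = []
        for rec in records:
            counts = rec.counts[0, :4]
            if counts.sum():
                freqs.append(1 - counts["ATCG".index(rec.ref_base)] / counts.sum())
        freqs = np.asarray(freqs)
        assert abs(freqs.mean() - q) < 3 * freqs.std(ddof=1) / np.sqrt(len(freqs))


class TestAfd:
    @pytest.mark.parametrize(
        "f1, f2, expected", [(0.75, 0.25, 0.5), (0.4, 0.4, 0.0), (1.0, 0.0, 1.0)]
    )
    def test_absolute_difference(self, f1, f2, expected):
        assert afd(f1, f2) == expected


class TestFst:
    def test_hand_evaluated_symmetric_table(self):
        # f = (0.75, 0.25): H_S = 0.375, H_T = 0.5; corrections cancel
        # because both coverages exceed Z so c_1 = c_2 = c_T = 18
        assert fst_site(((30, 10), (10, 30)), 18, 18, corrected=True) == pytest.approx(0.25)
        assert fst_site(((30, 10), (10, 30)), corrected=False) == pytest.approx(0.25)

    def test_identical_pools_give_zero(self):
        assert fst_site(((15, 5), (15, 5))) == pytest.approx(0.0)

    def test_fixed_difference_gives_one(self):
        assert fst_site(((40, 0), (0, 40))) == pytest.approx(1.0)

    def test_monomorphic_site_undefined(self):
        assert np.isnan(fst_site(((20, 0), (20, 0))))

    def test_tiny_coverage_undefined_in_corrected_mode(self):
        assert np.isnan(fst_site(((1, 0), (3, 3)), corrected=True))
        assert not np.isnan(fst_site(((1, 1), (3, 3)), corrected=False))

    def test_monotone_towards_fixed_difference(self):
        values = [
            fst_site(((k, 40 - k), (40 - k, k))) for k in range(20, 41)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(0.0) and values[-1] == pytest.approx(1.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.tuples(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)))
    def test_corrected_equals_nei_when_effective_sizes_coincide(self, counts):
        # both coverages >= Z forces c_1 = c_2 = c_T = Z: the finite-sample
        # corrections cancel algebraically
        a, b, c, d = counts
        if a + b < 18 or c + d < 18:
            return
        got = fst_site(((a, b), (c, d)), 18, 18, corrected=True)
        expected = fst_nei(((a, b), (c, d)))
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.tuples(st.integers(0, 57), st.integers(0, 57), st.integers(0, 57), st.integers(0, 57)))
    def test_bounded_in_unit_interval(self, counts):
        a, b, c, d = counts
        if a + b == 0 or c + d == 0:
            return
        value = fst_site(((a, b), (c, d)))
        assert np.isnan(value) or -1e-12 <= value <= 1 + 1e-12


class TestFisher:
    def test_no_association(self):
        assert fisher_site(((5, 5), (5, 5))) == 1.0

    def test_enumeration_value(self):
        assert fisher_site(((2, 8), (8, 2))) == pytest.approx(0.023014137565, rel=1e-9)

    def test_transpose_symmetry(self):
        assert fisher_site(((3, 9), (11, 2))) == pytest.approx(
            fisher_site(((3, 11), (9, 2)))
        )

    def test_zero_margin_convention(self):
        assert fisher_site(((0, 0), (5, 5))) == 1.0
        assert fisher_site(((5, 0), (7, 0))) == 1.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.tuples(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)))
    def test_matches_exhaustive_enumeration(self, counts):
        a, b, c, d = counts
        assert fisher_site(((a, b), (c, d))) == pytest.approx(
            fisher_two_sided_enum(a, b, c, d), rel=1e-8, abs=1e-12
        )


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.001, 0.004, 0.03, 0.8]), [0.004, 0.008, 0.04, 0.8]
        )

    def test_degenerate_inputs(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([]).size == 0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
    def test_matches_direct_rule_and_invariants(self, p_values):
        q = bh_adjust(p_values)
        np.testing.assert_allclose(q, bh_stepup(p_values), rtol=1e-12)
        assert (q >= np.asarray(p_values) - 1e-15).all() and (q <= 1.0).all()
        # permutation invariance
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p_values))
        np.testing.assert_allclose(np.asarray(q)[perm], bh_adjust(np.asarray(p_values)[perm]))
        # monotone in rank order of p
        order = np.argsort(p_values, kind="mergesort")
        assert (np.diff(np.asarray(q)[order]) >= -1e-15).all()


class TestZContrast:
    def test_null_is_zero(self):
        summary = contrast_from_summary(0.5, 0.1, 100, 0.5, 0.1, 100)
        assert summary.z == 0.0 and summary.p_two_sided == 1.0
        assert summary.ci95_low < 0 < summary.ci95_high

    def test_antisymmetry_and_sqrt_n_scaling(self):
        forward = contrast_from_summary(0.11, 0.1, 1000, 0.10, 0.12, 1000)
        backward = contrast_from_summary(0.10, 0.12, 1000, 0.11, 0.1, 1000)
        assert forward.z == pytest.approx(-backward.z)
        doubled = contrast_from_summary(0.11, 0.1, 2000, 0.10, 0.12, 2000)
        assert doubled.z == pytest.approx(forward.z * np.sqrt(2))

    def test_zero_variance_equal_means(self):
        summary = contrast_from_summary(0.3, 0.0, 50, 0.3, 0.0, 50)
        assert summary.z == 0.0 and summary.p_two_sided == 1.0

    def test_sign_matches_mean_difference(self):
        assert contrast_from_summary(0.2, 0.1, 100, 0.1, 0.1, 100).z > 0

    def test_vector_form_uses_sample_sd(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.3, 0.05, 200)
        b = rng.normal(0.28, 0.05, 300)
        summary = z_contrast(a, b)
        assert summary.sd_a == pytest.approx(a.std(ddof=1))
        assert summary.n_a == 200 and summary.n_b == 300
        expected_z = (a.mean() - b.mean()) / np.sqrt(
            a.var(ddof=1) / 200 + b.var(ddof=1) / 300
        )
        assert summary.z == pytest.approx(expected_z)

    def test_small_samples_refused(self):
        with pytest.raises(ValueError, match=">= 30"):
            z_contrast(np.ones(10), np.ones(100))


class TestSiteScan:
    def test_planted_sites_show_elevated_statistics(self, planted_config, planted_records):
        truth, records = planted_records
        stats = site_scan(records)
        assert (stats["q_value"] >= stats["p_fisher"] - 1e-15).all()
        assert stats["position"].is_monotonic_increasing
        planted_pos = set(truth.sites.loc[truth.sites["planted"], "position"])
        planted_mask = stats["position"].isin(planted_pos)
        assert stats.loc[planted_mask, "afd"].mean() > 3 * stats.loc[~planted_mask, "afd"].mean()
        assert np.nanmean(stats.loc[planted_mask, "fst"]) > 5 * np.nanmean(
            stats.loc[~planted_mask, "fst"]
        )

    def test_empty_input(self):
        assert len(site_scan([])) == 0
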