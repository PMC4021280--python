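"""Contingency tables, Mantel-Haenszel, windows and the permutation test."""

import math

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import StratifiedTable

from foldcons.association import (
    ContingencyTable,
    constrained_permutation_test,
    gene_table,
    mantel_haenszel,
    regional_correlation_test,
    run_species_analysis,
    sliding_windows,
    stratified_analysis,
    windowed_analysis,
)
from foldcons.seqio import FourfoldSiteRecord

from oracles import mh_chi2_textbook


def _site(gene, pos, nt="A", ew=0.0, sens=0.0):
    return FourfoldSiteRecord(gene_id=gene, cds_pos=pos, aln_col=pos - 1,
                              ref_nt=nt, E_w=ew, sensitivity=sens)


class TestGeneTable:
    def test_example_counts_recovered(self):
        # 3 sensitive&conserved, 10 sensitive&variable, 4 conserved only,
        # 57 neither — the canonical single-gene table
        sites = (
            [_site("g", i, ew=0.1, sens=0.5) for i in range(1, 4)]
            + [_site("g", i, ew=1.2, sens=0.5) for i in range(4, 14)]
            + [_site("g", i, ew=0.1, sens=0.01) for i in range(14, 18)]
            + [_site("g", i, ew=1.2, sens=0.01) for i in range(18, 75)]
        )
        t = gene_table(sites)
        assert (t.a, t.b, t.c, t.d) == (3, 10, 4, 57)

    def test_all_conserved_sensitive(self):
        sites = [_site("g", i, ew=0.0, sens=0.9) for i in range(1, 6)]
        t = gene_table(sites)
        assert (t.a, t.b, t.c, t.d) == (5, 0, 0, 0)

    def test_boundary_values_are_strictly_classified(self):
        """E_w == 0.5 is non-conserved; sensitivity == 0.1 is non-sensitive."""
        t = gene_table([_site("g", 3, ew=0.5, sens=0.1)])
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 1)

    def test_undefined_sites_skipped(self):
        t = gene_table([_site("g", 3, ew=float("nan"), sens=0.2),
                        _site("g", 6, ew=0.2, sens=0.2)])
        assert t.s == 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestMantelHaenszel:
    def test_single_stratum_is_cross_product_ratio(self):
        r = mantel_haenszel([ContingencyTable(3, 10, 4, 57)])
        assert r.or_mh == pytest.approx(171 / 40)
        assert r.or_mh == pytest.approx(4.275)

    def test_duplicated_strata_leave_or_unchanged(self):
        t = ContingencyTable(3, 10, 4, 57)
        assert mantel_haenszel([t, t]).or_mh == pytest.approx(
            mantel_haenszel([t]).or_mh
        )

    def test_empty_sensitive_row_stratum_is_neutral(self):
        t = ContingencyTable(3, 10, 4, 57)
        empty = ContingencyTable(0, 0, 12, 30)
        assert mantel_haenszel([t, empty]).or_mh == pytest.approx(
            mantel_haenszel([t]).or_mh
        )

    def test_chi2_matches_textbook_formula_on_random_strata(self, rng):
        for _ in range(1000):
            k = int(rng.integers(1, 6))
            tables = [ContingencyTable(*map(int, rng.integers(1, 25, 4)))
                      for _ in range(k)]
            r = mantel_haenszel(tables)
            ref = mh_chi2_textbook([(t.a, t.b, t.c, t.d) for t in tables])
            assert r.chi2 == pytest.approx(ref, abs=1e-10)

    def test_pooled_or_matches_statsmodels(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 8))
            tables = [ContingencyTable(*map(int, rng.integers(1, 30, 4)))
                      for _ in range(k)]
            r = mantel_haenszel(tables)
            st = StratifiedTable(
                np.dstack([np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
                           for t in tables])
            )
            assert r.or_mh == pytest.approx(st.oddsratio_pooled, rel=1e-12)

    def test_ci_brackets_the_estimate(self, rng):
        tables = [ContingencyTable(*map(int, rng.integers(1, 30, 4)))
                  for _ in range(5)]
        r = mantel_haenszel(tables)
        assert r.ci95[0] <= r.or_mh <= r.ci95[1]

    def test_zero_denominator_reports_infinite_or(self):
        r = mantel_haenszel([ContingencyTable(5, 0, 0, 5)])
        assert math.isinf(r.or_mh)
        assert 0.0 <= r.p_two_sided <= 1.0

    def test_degenerate_strata_skipped_and_counted(self):
        r = mantel_haenszel([ContingencyTable(3, 10, 4, 57),
                             ContingencyTable(1, 0, 0, 0)])
        assert r.n_strata_used == 1 and r.n_strata_skipped == 1

    def test_no_usable_strata_rejected(self):
        with pytest.raises(ValueError):
            mantel_haenszel([ContingencyTable(1, 0, 0, 0)])


class TestSlidingWindows:
    def test_default_scheme_has_ten_windows(self):
        w = sliding_windows(36, 12, 109)
        assert len(w) == 10
        assert w[0] == (1, 36) and w[-1] == (109, 144)

    def test_alternate_scheme_has_nine_windows(self):
        w = sliding_windows(45, 15, 121)
        assert len(w) == 9
        assert w[0] == (1, 45) and w[-1] == (121, 165)

    def test_single_window(self):
        assert sliding_windows(36, 12, 1) == [(1, 36)]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sliding_windows(0, 12, 109)

    def test_site_membership_in_overlapping_windows(self):
        windows = sliding_windows(36, 12, 109)
        containing = [w for w in windows if w[0] <= 36 <= w[1]]
        assert containing == [(1, 36), (13, 48), (25, 60)]


class TestWindowedAnalysis:
    def test_windows_collect_only_their_sites(self):
        sites = {"g1": [_site("g1", p, ew=e, sens=s)
                        for p, e, s in [(6, 0.1, 0.5), (42, 1.0, 0.01),
                                        (120, 0.2, 0.3), (150, 0.9, 0.0)]]}
        res = windowed_analysis(sites, [(1, 36), (109, 144)])
        assert res[0]["n_sites"] == 1
        assert res[1]["n_sites"] == 1

    def test_window_without_sensitive_sites_reports_missing_or(self):
        sites = {"g1": [_site("g1", 6, ew=0.1, sens=0.0),
                        _site("g1", 9, ew=0.9, sens=0.0)]}
        res = windowed_analysis(sites, [(1, 36)])
        assert math.isnan(res[0]["or_mh"])
        assert res[0]["sensitive_fraction"] == 0.0


class TestStratifiedAnalysis:
    def test_one_gene_half_degenerates_to_single_stratum(self, small_planted):
        _, sites_by_gene, _ = small_planted
        two = {g: sites_by_gene[g] for g in list(sites_by_gene)[:2]}
        cov = {g: float(i) for i, g in enumerate(two)}
        out = stratified_analysis(two, cov)
        assert out["top"].n_strata_used == 1
        assert out["bottom"].n_strata_used == 1

    def test_missing_covariate_excludes_gene_only(self, small_planted):
        _, sites_by_gene, _ = small_planted
        cov = {g: float(i) for i, g in enumerate(sites_by_gene)}
        dropped = list(sites_by_gene)[0]
        del cov[dropped]
        out = stratified_analysis(sites_by_gene, cov)
        assert out["excluded"] == [dropped]
        assert dropped not in out["top_ids"] + out["bottom_ids"]

    def test_enc_orientation_puts_lowest_values_on_top(self, small_planted):
        _, sites_by_gene, _ = small_planted
        cov = {g: float(i) for i, g in enumerate(sorted(sites_by_gene))}
        out = stratified_analysis(sites_by_gene, cov, higher_is_top=False)
        top_vals = [cov[g] for g in out["top_ids"]]
        bottom_vals = [cov[g] for g in out["bottom_ids"]]
        assert max(top_vals) < min(bottom_vals)


class TestPermutationTest:
    def test_p_value_uses_add_one_estimator(self, small_planted):
        _, sites_by_gene, _ = small_planted
        res = constrained_permutation_test(sites_by_gene, n_perm=99, seed=1)
        assert res.p_left >= 1 / 100
        assert res.p_left <= 1.0

    def test_deterministic_given_seed(self, small_planted):
        _, sites_by_gene, _ = small_planted
        r1 = constrained_permutation_test(sites_by_gene, n_perm=50, seed=7)
        r2 = constrained_permutation_test(sites_by_gene, n_perm=50, seed=7)
        assert r1.p_left == r2.p_left
        assert np.array_equal(r1.null_means, r2.null_means)

    def test_singleton_nucleotide_classes_are_fixed_points(self):
        """With every nucleotide class below size 2 nothing can move, so the
        gene contributes identically to every permutation replicate."""
        sites = {"g": [_site("g", 3 * i, nt=nt, ew=e, sens=s)
                       for i, (nt, e, s) in enumerate(
                           [("A", 0.1, 0.5), ("C", 0.9, 0.1),
                            ("G", 0.4, 0.3), ("T", 1.5, 0.0)], 1)]}
        res = constrained_permutation_test(sites, n_perm=200, seed=0)
        assert np.allclose(res.null_means, res.mean_r)
        assert res.p_left == 1.0

    def test_permutation_preserves_nucleotide_classes(self):
        """Reshuffles must keep E_w multisets within each nucleotide class."""
        rng = np.random.default_rng(5)
        sites = {"g": [_site("g", 3 * (i + 1), nt=nt, ew=float(rng.random()),
                             sens=float(rng.random()))
                       for i, nt in enumerate("AACCGGTTAACC")]}
        res = constrained_permutation_test(sites, n_perm=100, seed=3)
        # run with the same seed but nucleotide classes merged: the null
        # distribution must differ, proving the constraint binds
        merged = {"g": [_site("g", s.cds_pos, nt="A", ew=s.E_w,
                              sens=s.sensitivity) for s in sites["g"]]}
        res2 = constrained_permutation_test(merged, n_perm=100, seed=3)
        assert not np.array_equal(res.null_means, res2.null_means)

    def test_too_few_usable_genes_rejected(self):
        sites = {"g": [_site("g", 3, ew=0.5, sens=0.5)]}
        with pytest.raises(ValueError):
            constrained_permutation_test(sites)

    def test_zero_variance_genes_excluded_and_counted(self, small_planted):
        _, sites_by_gene, _ = small_planted
        flat = {"flat": [_site("flat", 3 * i, ew=0.5, sens=0.5)
                         for i in range(1, 6)]}
        res = constrained_permutation_test({**sites_by_gene, **flat},
                                           n_perm=20, seed=0)
        assert res.n_genes_excluded == 1
        assert res.n_genes_used == len(sites_by_gene)


class TestRegionalTest:
    def test_full_length_region_equals_whole_test(self, small_planted):
        _, sites_by_gene, _ = small_planted
        whole = constrained_permutation_test(sites_by_gene, n_perm=50, seed=2)
        region = regional_correlation_test(sites_by_gene, (1, 10**6),
                                           n_perm=50, seed=2)
        assert region.mean_r == pytest.approx(whole.mean_r)
        assert region.p_left == whole.p_left

    def test_region_without_sites_rejected(self, small_planted):
        _, sites_by_gene, _ = small_planted
        with pytest.raises(ValueError):
            regional_correlation_test(sites_by_gene, (10**6, 2 * 10**6))

    def test_invalid_region_rejected(self, small_planted):
        _, sites_by_gene, _ = small_planted
        with pytest.raises(ValueError):
            regional_correlation_test(sites_by_gene, (60, 1))


class TestSpeciesAnalysis:
    def test_planted_effect_gives_or_above_one(self, small_planted):
        _, sites_by_gene, _ = small_planted
        result, tables, sens_frac = run_species_analysis(sites_by_gene)
        assert result.or_mh > 1.0
        assert set(tables) == set(sites_by_gene)
        assert all(0.0 <= f <= 1.0 for f in sens_frac.values())

    def test_sensitive_fraction_mostly_below_quarter(self, small_planted):
        """Default cutoff keeps most genes below 25% sensitive sites."""
        _, sites_by_gene, _ = small_planted
        _, _, sens_frac = run_species_analysis(sites_by_gene)
        below = sum(1 for f in sens_frac.values() if f < 0.25)
        assert below / len(sens_frac) > 0.5
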