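"""Enrichment, contrasts, loop/expression concordance, Bliss synergy."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest

from epilink.integrate import (
    bliss_synergy,
    epi_enrichment,
    expression_contrast,
    gene_epi_scores,
    gene_loop_counts,
    hichip_gene_log2fc,
    interaction_expression_concordance,
    normalize_viability,
    peak_dependency_overlap,
    _spearman_exact_p,
)
from epilink.intervals import GenomicInterval
from epilink.io import Interaction


def hypergeom_fisher_p(a, b, c, d) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    p_obs = pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


class TestEpiEnrichment:
    def test_cross_product_odds_ratio(self):
        pos = {f"a{i}": i < 8 for i in range(10)} | {f"b{i}": i < 1 for i in range(10)}
        res = epi_enrichment([f"a{i}" for i in range(10)],
                             [f"b{i}" for i in range(10)], pos)
        assert res.odds_ratio == pytest.approx(36.0)
        assert res.fraction_a == 0.8 and res.fraction_b == 0.1
        assert res.p_two_sided == pytest.approx(hypergeom_fisher_p(8, 2, 1, 9))

    def test_identical_composition_is_null(self):
        pos = {f"a{i}": i < 5 for i in range(10)} | {f"b{i}": i < 5 for i in range(10)}
        res = epi_enrichment([f"a{i}" for i in range(10)],
                             [f"b{i}" for i in range(10)], pos)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        pos = {"a1": True, "a2": True, "b1": False, "b2": False}
        res = epi_enrichment(["a1", "a2"], ["b1", "b2"], pos)
        assert math.isfinite(res.odds_ratio) and res.odds_ratio > 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="gene_set_a"):
            epi_enrichment([], ["b"], {"b": True})

    def test_fisher_matches_enumeration_on_random_tables(self):
        rng = random.Random(17)
        for _ in range(150):
            n = rng.randrange(4, 200)
            na = rng.randrange(1, n)
            genes_a = [f"a{i}" for i in range(na)]
            genes_b = [f"b{i}" for i in range(n - na)] or ["b0"]
            pos = {g: rng.random() < 0.4 for g in genes_a + genes_b}
            res = epi_enrichment(genes_a, genes_b, pos)
            expected = hypergeom_fisher_p(
                res.a_positive, res.a_negative, res.b_positive, res.b_negative
            )
            assert res.p_two_sided == pytest.approx(expected, abs=1e-9)

    def test_planted_sensitivity_fractions_recovered(
        self, default_bundle, default_results
    ):
        res = default_results["integrate"].enrichment_by_epi
        # planted: 70% of EPI+ genes drug-sensitive vs 20% of the rest
        assert abs(res.fraction_a - 0.7) < 0.15
        assert abs(res.fraction_b - 0.2) < 0.15
        assert res.p_two_sided < 1e-6


class TestExpressionContrast:
    def test_identical_sets_null(self):
        res = expression_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.mean_diff == 0.0

    def test_constant_sets_flagged_degenerate(self):
        res = expression_contrast([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.p_two_sided == 1.0

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(21)
        rejections = 0
        for _ in range(50):
            a = rng.normal(1.0, 1.0, 50)
            b = rng.normal(0.0, 1.0, 50)
            if expression_contrast(a, b).p_two_sided < 0.05:
                rejections += 1
        assert rejections >= 49  # closed-form power at d=1, n=50 is > 0.99

    def test_paired_mode_exact_mean_difference(self):
        x = np.array([1.0, 5.0, 9.0])
        res = expression_contrast(x + 2.5, x, paired=True)
        assert res.mean_diff == pytest.approx(2.5)
        assert res.degenerate  # zero variance of differences

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            expression_contrast([1.0], [1.0, 2.0])


class TestGeneEpiScores:
    def _epi(self, gene, score, j):
        it = Interaction(GenomicInterval("chr1", 0, 100),
                         GenomicInterval("chr1", 1000 + j * 100, 1050 + j * 100),
                         sample="s", score=score,
                         end_roles=("bait", "other_end"))
        it.regulatory_class = "EPI"

        class Ann:
            overlapping_gene_ids = frozenset({gene})
            overlaps_peak = True
            is_promoter = True

        it.ann1 = Ann()
        it.ann2 = Ann()
        return it

    def test_mean_sum_count(self):
        df = gene_epi_scores([self._epi("gA", 5.0, 0), self._epi("gA", 7.0, 1)])
        assert df.loc["gA", "epi_score_mean"] == 6.0
        assert df.loc["gA", "epi_score_sum"] == 12.0
        assert df.loc["gA", "epi_count"] == 2

    def test_gene_without_epi_absent(self):
        it = self._epi("gA", 5.0, 0)
        it.regulatory_class = "PPI"
        assert gene_epi_scores([it]).empty

    def test_removing_an_epi_lowers_mean_or_count(self):
        before = gene_epi_scores([self._epi("gA", 5.0, 0), self._epi("gA", 7.0, 1)])
        after = gene_epi_scores([self._epi("gA", 5.0, 0)])
        assert (after.loc["gA", "epi_count"] < before.loc["gA", "epi_count"])
        assert after.loc["gA", "epi_score_mean"] <= before.loc["gA", "epi_score_mean"]


class TestHichipLog2fc:
    def test_closed_forms(self):
        counts = pd.DataFrame({"a1": [4], "a2": [4], "b1": [1], "b2": [1]},
                              index=["g"])
        lfc = hichip_gene_log2fc(counts, ["a1", "a2"], ["b1", "b2"], pseudocount=0)
        assert lfc["g"] == pytest.approx(2.0)
        lfc_eq = hichip_gene_log2fc(counts, ["a1", "a2"], ["a1", "a2"])
        assert lfc_eq["g"] == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(0, 20, size=(30, 4)),
                              columns=["a1", "a2", "b1", "b2"])
        fwd = hichip_gene_log2fc(counts, ["a1", "a2"], ["b1", "b2"])
        rev = hichip_gene_log2fc(counts, ["b1", "b2"], ["a1", "a2"])
        assert np.allclose(fwd, -rev)

    def test_loop_counts_by_promoter_overlap(self):
        win = {"gA": [GenomicInterval("chr1", 1000, 3000)],
               "gB": [GenomicInterval("chr1", 9000, 11000)]}
        loops = [
            Interaction(GenomicInterval("chr1", 1500, 1600),
                        GenomicInterval("chr1", 5000, 5100), sample="s1"),
            Interaction(GenomicInterval("chr1", 5000, 5100),
                        GenomicInterval("chr1", 10000, 10100), sample="s1"),
            Interaction(GenomicInterval("chr1", 1500, 1600),
                        GenomicInterval("chr1", 10000, 10100), sample="s1"),
        ]
        counts = gene_loop_counts({"s1": loops}, win)
        assert counts.loc["gA", "s1"] == 2 and counts.loc["gB", "s1"] == 2


class TestConcordance:
    def test_perfect_monotone(self):
        x = pd.Series(np.arange(12, dtype=float), index=[f"g{i}" for i in range(12)])
        rho, p, n = interaction_expression_concordance(x, x**3)
        assert rho == pytest.approx(1.0) and n == 12

    def test_independent_permutations_give_small_rho(self):
        rng = np.random.default_rng(33)
        idx = [f"g{i}" for i in range(200)]
        rhos = []
        for _ in range(30):
            a = pd.Series(rng.normal(size=200), index=idx)
            b = pd.Series(rng.normal(size=200), index=idx)
            rho, _, _ = interaction_expression_concordance(a, b)
            rhos.append(abs(rho))
        assert np.mean(rhos) < 0.12

    def test_tied_ranks_match_midrank_oracle(self):
        x = pd.Series([1.0, 1.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0, 6.0, 7.0],
                      index=[f"g{i}" for i in range(10)])
        y = pd.Series([2.0, 1.0, 2.0, 2.0, 5.0, 4.0, 4.0, 6.0, 8.0, 8.0],
                      index=x.index)
        from scipy.stats import rankdata

        rho, _, _ = interaction_expression_concordance(x, y)
        rx, ry = rankdata(x), rankdata(y)  # midranks by definition
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_exact_permutation_p_consistent_at_tiny_n(self):
        # the enumeration path doubles as an oracle for the t approximation
        rng = np.random.default_rng(7)
        x = rng.normal(size=7)
        y = x + rng.normal(0, 0.5, size=7)
        exact = _spearman_exact_p(x, y)
        from scipy.stats import spearmanr

        _, p_approx = spearmanr(x, y)
        assert abs(exact - p_approx) < 0.12

    def test_requires_ten_shared_genes(self):
        x = pd.Series([1.0] * 5, index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            interaction_expression_concordance(x, x)

    def test_planted_concordance_positive(self, default_results):
        rho, p, n = default_results["integrate"].concordance
        assert rho > 0.3 and p < 0.01 and n >= 10


class TestPeakDependencyOverlap:
    def test_fractions_and_union(self):
        pondown = [GenomicInterval("chr1", i * 1000, i * 1000 + 100)
                   for i in range(4)]
        tf = {
            "TF1": [GenomicInterval("chr1", 0, 50)],
            "TF2": [GenomicInterval("chr1", 1000, 1100),
                    GenomicInterval("chr1", 2000, 2100)],
            "TF3": [GenomicInterval("chr2", 0, 50)],
        }
        out = peak_dependency_overlap(pondown, tf)
        assert out.loc["TF1", "fraction"] == 0.25
        assert out.loc["TF2", "fraction"] == 0.5
        assert out.loc["TF3", "fraction"] == 0.0
        assert out.loc["union", "fraction"] == 0.75
        assert (out.loc["union", "fraction"] >=
                out.drop("union")["fraction"]).all()

    def test_empty_pondown_rejected(self):
        with pytest.raises(ValueError):
            peak_dependency_overlap([], {"TF1": []})


class TestBliss:
    def _grid(self, combo):
        return pd.DataFrame(
            {0.0: [1.0, 0.5], 10.0: [0.6, combo]},
            index=[0.0, 1.0],
        )

    def test_bliss_identity_cell(self):
        # yA=0.5, yB=0.4, observed combo inhibition 0.9 -> excess +20
        res = bliss_synergy(self._grid(combo=0.1))
        assert res.excess.loc[1.0, 10.0] == pytest.approx(20.0)

    def test_additive_grid_scores_zero(self):
        # observed equals expectation everywhere
        expected_v = (1 - 0.5) * (1 - 0.4)
        res = bliss_synergy(self._grid(combo=expected_v))
        assert res.mean_score == pytest.approx(0.0)
        assert res.call == "additive"

    def test_call_boundary_strict_at_ten(self):
        # margins 0.5/0.5 -> expected inhibition 0.75, all exactly representable
        def grid(combo_viability):
            return pd.DataFrame({0.0: [1.0, 0.5], 10.0: [0.5, combo_viability]},
                                index=[0.0, 1.0])

        at_ten = bliss_synergy(grid(0.25 - 0.125))   # y_obs=0.875, excess 12.5
        assert at_ten.mean_score == pytest.approx(12.5)
        assert at_ten.call == "synergistic"
        exactly_ten = bliss_synergy(grid(0.15))      # y_obs=0.85, excess 10
        assert exactly_ten.mean_score == pytest.approx(10.0)
        assert exactly_ten.call == "additive"        # -10..10 is additive
        antagonistic = bliss_synergy(grid(0.40))     # y_obs=0.60, excess -15
        assert antagonistic.call == "antagonistic"

    def test_expected_inhibition_symmetric_and_bounded(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            ya, yb = rng.uniform(0, 1, 2)
            e = ya + yb - ya * yb
            assert 0.0 <= e <= 1.0
            assert e == pytest.approx(yb + ya - yb * ya)

    def test_margins_required_and_range_checked(self):
        bad = pd.DataFrame({10.0: [0.5]}, index=[1.0])
        with pytest.raises(ValueError, match="zero-dose"):
            bliss_synergy(bad)
        out_of_range = self._grid(combo=1.5)
        with pytest.raises(ValueError, match="viability"):
            bliss_synergy(out_of_range)

    def test_planted_synergy_recovered(self, default_bundle, default_results):
        synergy = default_results["integrate"].synergy
        assert synergy["combo_synergistic"].call == "synergistic"
        assert synergy["combo_additive"].call == "additive"
        planted = default_bundle.truth.planted_bliss["combo_synergistic"]
        assert abs(synergy["combo_synergistic"].mean_score - planted) < 5.0


class TestNormalizeViability:
    def test_reference_wells_map_to_unit_mean(self):
        raw = pd.DataFrame({0.0: [5000.0, 2500.0], 10.0: [3000.0, 1000.0]},
                           index=[0.0, 1.0])
        norm = normalize_viability(raw, [(0.0, 0.0)])
        assert norm.loc[0.0, 0.0] == 1.0

    def test_scale_invariance(self):
        raw = pd.DataFrame({0.0: [5000.0, 2500.0], 10.0: [3000.0, 1000.0]},
                           index=[0.0, 1.0])
        ref = [(0.0, 0.0), (1.0, 0.0)]
        a = normalize_viability(raw, ref)
        b = normalize_viability(raw * 7.3, ref)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_or_zero_reference_rejected(self):
        raw = pd.DataFrame({0.0: [0.0]}, index=[0.0])
        with pytest.raises(ValueError):
            normalize_viability(raw, [])
        with pytest.raises(ValueError):
            normalize_viability(raw, [(0.0, 0.0)])
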