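"""End annotation, interaction and promoter classification, normalization."""

import random

import numpy as np
import pandas as pd
import pytest

from epilink.classify import (
    annotate_ends,
    classify_interaction,
    classify_interactions,
    classify_promoters,
    deduplicate_interactions,
    normalize_per_10M,
)
from epilink.intervals import GenomicInterval, make_promoter_windows, overlaps
from epilink.io import Interaction

from conftest import random_intervals


def _iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def _pchic(end1, end2, sample="s", score=6.0, raw=None):
    return Interaction(end1, end2, sample=sample, score=score, raw_count=raw,
                       end_roles=("bait", "other_end"))


@pytest.fixture
def setting():
    """One gene gA at chr1 TSS 5000, one at gB TSS 20000; a distal peak."""
    promoters = make_promoter_windows(
        [("chr1", 5000, 8000, "+", "gA"), ("chr1", 20000, 25000, "+", "gB")]
    )
    peaks = [_iv("chr1", 4500, 5500), _iv("chr1", 19500, 20500),
             _iv("chr1", 50000, 50600)]
    return promoters, peaks


class TestAnnotateEnds:
    def test_peak_and_promoter_flags(self, setting):
        promoters, peaks = setting
        its = [
            _pchic(_iv("chr1", 4000, 6000), _iv("chr1", 50000, 50600)),  # peak only
            _pchic(_iv("chr1", 4000, 6000), _iv("chr1", 20500, 21000)),  # promoter only
        ]
        annotate_ends(its, peaks, promoters)
        assert its[0].ann2.overlaps_peak and not its[0].ann2.is_promoter
        assert not its[1].ann2.overlaps_peak and its[1].ann2.is_promoter
        assert its[1].ann2.overlapping_gene_ids == frozenset({"gB"})

    def test_matches_all_pairs_oracle(self, setting):
        promoters, peaks = setting
        rng = random.Random(2)
        ends = random_intervals(rng, 200, chroms=("chr1",), span=60000, max_len=800)
        its = [_pchic(a, b) for a, b in zip(ends[::2], ends[1::2])]
        annotate_ends(its, peaks, promoters)
        for it in its:
            for end, ann in ((it.end1, it.ann1), (it.end2, it.ann2)):
                assert ann.overlaps_peak == any(overlaps(end, p) for p in peaks)
                expected = {
                    p.gene_id for p in promoters if overlaps(end, p.window)
                }
                assert set(ann.overlapping_gene_ids) == expected


class TestClassifyInteraction:
    def test_pchic_epi_ppi_none(self, setting):
        promoters, peaks = setting
        epi = _pchic(_iv("chr1", 4000, 6000), _iv("chr1", 50000, 50600))
        ppi = _pchic(_iv("chr1", 4000, 6000), _iv("chr1", 19500, 20500))
        dead = _pchic(_iv("chr1", 4000, 6000), _iv("chr1", 30000, 30500))
        annotate_ends([epi, ppi, dead], peaks, promoters)
        classify_interactions([epi, ppi, dead], mode="pchic")
        assert (epi.regulatory_class, epi.activity_class) == ("EPI", "AP-AO")
        assert (ppi.regulatory_class, ppi.activity_class) == ("PPI", "AP-AO")
        assert (dead.regulatory_class, dead.activity_class) == ("none", "AP-IO")

    def test_pchic_inactive_promoter_classes(self, setting):
        promoters, peaks = setting
        # remove gA's promoter peak: bait becomes inactive
        it = _pchic(_iv("chr1", 4000, 6000), _iv("chr1", 50000, 50600))
        annotate_ends([it], [_iv("chr1", 50000, 50600)], promoters)
        classify_interaction(it, mode="pchic")
        assert it.activity_class == "IP-AO" and it.regulatory_class == "none"

    def test_pchic_requires_roles(self, setting):
        promoters, peaks = setting
        it = Interaction(_iv("chr1", 4000, 6000), _iv("chr1", 50000, 50600),
                         sample="s", score=6.0)
        annotate_ends([it], peaks, promoters)
        with pytest.raises(ValueError, match="role"):
            classify_interaction(it, mode="pchic")

    def test_hichip_types_and_swap_invariance(self, setting):
        promoters, peaks = setting
        pairs = [
            (_iv("chr1", 4000, 6000), _iv("chr1", 19500, 20500), "PPI"),
            (_iv("chr1", 4000, 6000), _iv("chr1", 50000, 50600), "EPI"),
            (_iv("chr1", 30000, 30500), _iv("chr1", 50000, 50600), "EEI"),
        ]
        for e1, e2, expected in pairs:
            fwd = Interaction(e1, e2, sample="s")
            rev = Interaction(e2, e1, sample="s")
            annotate_ends([fwd, rev], peaks, promoters)
            classify_interactions([fwd, rev], mode="hichip")
            assert fwd.regulatory_class == expected == rev.regulatory_class
            assert fwd.activity_class is None

    def test_unknown_mode_rejected(self, setting):
        promoters, peaks = setting
        it = _pchic(_iv("chr1", 4000, 6000), _iv("chr1", 50000, 50600))
        annotate_ends([it], peaks, promoters)
        with pytest.raises(ValueError):
            classify_interaction(it, mode="loop")


class TestClassifyPromoters:
    def _classify(self, promoters, peaks, its, expression=None, **kw):
        annotate_ends(its, peaks, promoters)
        classify_interactions(its, mode="pchic")
        if expression is None:
            genes = sorted({p.gene_id for p in promoters})
            expression = pd.DataFrame({"dmso_1": [100.0] * len(genes)},
                                      index=pd.Index(genes, name="gene_id"))
        return classify_promoters(its, promoters, peaks, expression, **kw)

    def test_epi_and_ppi_combination(self, setting):
        promoters, peaks = setting
        its = [
            _pchic(_iv("chr1", 4000, 6000), _iv("chr1", 50000, 50600)),  # EPI
            _pchic(_iv("chr1", 4000, 6000), _iv("chr1", 19500, 20500)),  # PPI
        ]
        out = self._classify(promoters, peaks, its)
        assert out["gA"].promoter_class == "EPI_AND_PPI"
        assert (out["gA"].n_epi, out["gA"].n_ppi) == (1, 1)

    def test_inactive_oe_only_is_no_active_oe(self, setting):
        promoters, peaks = setting
        its = [_pchic(_iv("chr1", 4000, 6000), _iv("chr1", 30000, 30500))]
        out = self._classify(promoters, peaks, its)
        assert out["gA"].promoter_class == "NO_ACTIVE_OE"
        assert out["gA"].has_any_interaction
        assert out["gB"].promoter_class == "NO_ACTIVE_OE"
        assert not out["gB"].has_any_interaction

    def test_expression_threshold_gates_activity(self, setting):
        promoters, peaks = setting
        expression = pd.DataFrame(
            {"dmso_1": [9.0, 100.0]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        its = [_pchic(_iv("chr1", 4000, 6000), _iv("chr1", 50000, 50600))]
        out = self._classify(promoters, peaks, its, expression=expression)
        assert "gA" not in out and "gB" in out  # gA below count threshold

    def test_threshold_is_inclusive_at_10(self, setting):
        promoters, peaks = setting
        expression = pd.DataFrame(
            {"dmso_1": [10.0, 9.999]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        out = self._classify(promoters, peaks, [
            _pchic(_iv("chr1", 4000, 6000), _iv("chr1", 50000, 50600))
        ], expression=expression)
        assert "gA" in out and "gB" not in out

    def test_missing_expression_warns_and_is_inactive(self, setting):
        promoters, peaks = setting
        expression = pd.DataFrame({"dmso_1": [100.0]},
                                  index=pd.Index(["gA"], name="gene_id"))
        its = [_pchic(_iv("chr1", 4000, 6000), _iv("chr1", 50000, 50600))]
        annotate_ends(its, peaks, promoters)
        classify_interactions(its, mode="pchic")
        with pytest.warns(UserWarning, match="absent"):
            out = classify_promoters(its, promoters, peaks, expression)
        assert "gB" not in out

    def test_ambiguous_oe_both_counts_ppi_toward_epi(self, setting):
        promoters, peaks = setting
        its = [_pchic(_iv("chr1", 4000, 6000), _iv("chr1", 19500, 20500))]
        strict = self._classify(promoters, peaks, its)
        assert strict["gA"].promoter_class == "PPI_ONLY"
        its2 = [_pchic(_iv("chr1", 4000, 6000), _iv("chr1", 19500, 20500))]
        both = self._classify(promoters, peaks, its2, ambiguous_oe="both")
        assert both["gA"].promoter_class == "EPI_AND_PPI"

    def test_planted_bundle_recovery_is_exact(self, default_bundle, default_results):
        summaries = default_results["classify"].summaries
        truth = default_bundle.truth.gene_class
        assert summaries, "no active genes classified"
        assert all(s.promoter_class == truth[g] for g, s in summaries.items())

    def test_labels_partition_active_genes(self, default_results):
        c = default_results["classify"]
        assert int(c.class_counts.sum()) == len(c.active_genes)

    def test_epi_genes_higher_expressed_than_no_active_oe(
        self, default_bundle, default_results
    ):
        # planted expression boost for EPI+ genes must be visible downstream
        summaries = default_results["classify"].summaries
        expr = default_bundle.expression[
            [c for c in default_bundle.expression.columns if c.startswith("dmso")]
        ].mean(axis=1)
        epi = [g for g, s in summaries.items()
               if s.promoter_class in ("EPI_ONLY", "EPI_AND_PPI")]
        none = [g for g, s in summaries.items()
                if s.promoter_class == "NO_ACTIVE_OE"]
        assert expr.loc[epi].mean() > expr.loc[none].mean()


class TestJitterDegradation:
    def test_recovery_degrades_monotonically_with_jitter(self):
        from epilink.pipeline import classify_stage
        from epilink.simulate import SyntheticConfig, generate

        rates = []
        for jitter in (0.0, 2000.0, 6000.0):
            bundle = generate(SyntheticConfig(seed=11, jitter_sd=jitter))
            summaries = classify_stage(bundle).summaries
            truth = bundle.truth.gene_class
            ok = sum(s.promoter_class == truth[g] for g, s in summaries.items())
            rates.append(ok / max(len(summaries), 1))
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[2] < 1.0


class TestNormalizePer10M:
    def test_closed_form_and_zero(self):
        its = [Interaction(_iv("chr1", 0, 10), _iv("chr1", 20, 30), sample="s",
                           raw_count=5),
               Interaction(_iv("chr1", 0, 10), _iv("chr1", 40, 50), sample="s",
                           raw_count=0)]
        normalize_per_10M(its, library_size=5_000_000)
        assert its[0].score == 10.0 and its[1].score == 0.0

    def test_sum_identity(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=50)
        its = [Interaction(_iv("chr1", i * 10, i * 10 + 5),
                           _iv("chr2", i * 10, i * 10 + 5), sample="s",
                           raw_count=int(c)) for i, c in enumerate(counts)]
        lib = 3_456_789
        normalize_per_10M(its, lib)
        assert np.isclose(sum(it.score for it in its),
                          1e7 * counts.sum() / lib)

    def test_invalid_library_size(self):
        it = Interaction(_iv("chr1", 0, 10), _iv("chr1", 20, 30), sample="s",
                         raw_count=5)
        with pytest.raises(ValueError):
            normalize_per_10M([it], 0)


class TestDeduplicate:
    def test_exact_and_swapped_duplicates_collapse(self):
        a = Interaction(_iv("chr1", 0, 10), _iv("chr1", 20, 30), sample="s",
                        raw_count=3)
        b = Interaction(_iv("chr1", 20, 30), _iv("chr1", 0, 10), sample="s",
                        raw_count=9)
        c = Interaction(_iv("chr1", 0, 10), _iv("chr1", 20, 31), sample="s",
                        raw_count=1)
        out = deduplicate_interactions([a, b, c])
        assert len(out) == 2
        assert out[0].raw_count == 9  # max count wins

    def test_distinct_samples_kept(self):
        a = Interaction(_iv("chr1", 0, 10), _iv("chr1", 20, 30), sample="s1")
        b = Interaction(_iv("chr1", 0, 10), _iv("chr1", 20, 30), sample="s2")
        assert len(deduplicate_interactions([a, b])) == 2
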