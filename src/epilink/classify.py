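"""Annotation and classification of chromatin interactions.

Ends of promoter-capture Hi-C and HiChIP contacts are annotated with H3K27ac
peak overlap and promoter-window membership, then classified:

* per interaction — the four activity classes (active/inactive promoter bait
  x active/inactive other end) and the regulatory classes EPI (active promoter
  to H3K27ac+ non-promoter), PPI (two active promoters) and, for HiChIP only,
  EEI (neither end a promoter);
* per gene — the four-way promoter classification EPI_ONLY / PPI_ONLY /
  EPI_AND_PPI / NO_ACTIVE_OE over active genes (H3K27ac+ promoter and
  normalized expression at or above a threshold, default 10).

HiChIP raw loop counts are normalized to reads per 10 million library reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, PromoterRecord
from .io import Interaction

__all__ = [
    "EndAnnotation",
    "PromoterSummary",
    "annotate_ends",
    "classify_interaction",
    "classify_interactions",
    "classify_promoters",
    "normalize_per_10M",
    "deduplicate_interactions",
    "PROMOTER_CLASSES",
]

PROMOTER_CLASSES = ("EPI_ONLY", "PPI_ONLY", "EPI_AND_PPI", "NO_ACTIVE_OE")


@dataclass(frozen=True)
class EndAnnotation:
    """H3K27ac and promoter status of one interaction end."""

    overlaps_peak: bool
    overlapping_gene_ids: frozenset[str]

    @property
    def is_promoter(self) -> bool:
        return bool(self.overlapping_gene_ids)


@dataclass
class PromoterSummary:
    """Per-gene aggregate of interaction regulatory classes."""

    gene_id: str
    promoter_class: str
    n_epi: int
    n_ppi: int
    has_any_interaction: bool


def _build_trees(
    intervals: Iterable[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _annotate_one(
    end: GenomicInterval,
    peak_trees: Mapping[str, IntervalTree],
    prom_trees: Mapping[str, IntervalTree],
) -> EndAnnotation:
    peak_hit = bool(
        end.chrom in peak_trees and peak_trees[end.chrom].overlap(end.start, end.end)
    )
    genes: set[str] = set()
    if end.chrom in prom_trees:
        for hit in prom_trees[end.chrom].overlap(end.start, end.end):
            genes.add(hit.data)
    return EndAnnotation(overlaps_peak=peak_hit, overlapping_gene_ids=frozenset(genes))


def annotate_ends(
    interactions: Sequence[Interaction],
    peaks: Iterable[GenomicInterval],
    promoters: Sequence[PromoterRecord],
) -> Sequence[Interaction]:
    """Attach peak-overlap and promoter gene-id annotations to both ends.

    Overlap is >= 1 bp under half-open semantics; an end touching several
    promoter windows collects every overlapped gene id.
    """
    peak_trees = _build_trees(peaks)
    prom_trees: dict[str, IntervalTree] = {}
    for rec in promoters:
        prom_trees.setdefault(rec.window.chrom, IntervalTree()).addi(
            rec.window.start, rec.window.end, rec.gene_id
        )
    for it in interactions:
        it.ann1 = _annotate_one(it.end1, peak_trees, prom_trees)
        it.ann2 = _annotate_one(it.end2, peak_trees, prom_trees)
    return interactions


def classify_interaction(interaction: Interaction, mode: str) -> Interaction:
    """Assign activity and regulatory classes to one annotated interaction.

    ``mode='pchic'``: the bait is a captured promoter fragment; the activity
    class crosses bait/other-end H3K27ac status (AP-AO .. IP-IO). The
    regulatory class is EPI when an active-promoter bait contacts an H3K27ac+
    non-promoter other end, PPI when the other end is itself an H3K27ac+
    promoter (promoter identity takes precedence over the peak), otherwise
    ``none``. ``mode='hichip'``: ends are symmetric — PPI when both ends lie
    in promoter windows, EEI when neither does, EPI otherwise; no activity
    class is emitted.
    """
    if interaction.ann1 is None or interaction.ann2 is None:
        raise ValueError("interaction ends must be annotated before classification")
    a1: EndAnnotation = interaction.ann1
    a2: EndAnnotation = interaction.ann2
    if mode == "pchic":
        if interaction.end_roles is None:
            raise ValueError(
                f"pchic classification needs bait/other_end roles on "
                f"interaction {interaction.id}"
            )
        bait_ann = a1 if interaction.end_roles[0] == "bait" else a2
        oe_ann = a2 if interaction.end_roles[0] == "bait" else a1
        bait_active = bait_ann.overlaps_peak
        oe_active = oe_ann.overlaps_peak
        interaction.activity_class = (
            f"{'AP' if bait_active else 'IP'}-{'AO' if oe_active else 'IO'}"
        )
        if bait_active and bait_ann.is_promoter and oe_active:
            interaction.regulatory_class = "PPI" if oe_ann.is_promoter else "EPI"
        else:
            interaction.regulatory_class = "none"
    elif mode == "hichip":
        interaction.activity_class = None
        if a1.is_promoter and a2.is_promoter:
            interaction.regulatory_class = "PPI"
        elif not a1.is_promoter and not a2.is_promoter:
            interaction.regulatory_class = "EEI"
        else:
            interaction.regulatory_class = "EPI"
    else:
        raise ValueError(f"unknown classification mode {mode!r}")
    return interaction


def classify_interactions(
    interactions: Sequence[Interaction], mode: str
) -> Sequence[Interaction]:
    for it in interactions:
        classify_interaction(it, mode)
    return interactions


def classify_promoters(
    interactions: Sequence[Interaction],
    promoters: Sequence[PromoterRecord],
    peaks: Iterable[GenomicInterval],
    expression: pd.DataFrame,
    active_count_min: float = 10.0,
    reference_samples: Sequence[str] | None = None,
    ambiguous_oe: str = "ppi",
) -> dict[str, PromoterSummary]:
    """Four-way classification of active genes by their interactions.

    A gene is *active* when its promoter window overlaps an H3K27ac peak and
    its mean normalized count over the reference-condition samples is at or
    above ``active_count_min``. Each active gene is then labelled by the
    regulatory classes of the classified interactions whose bait maps to it:
    EPI_ONLY, PPI_ONLY, EPI_AND_PPI, or NO_ACTIVE_OE (no H3K27ac+ other end;
    ``has_any_interaction`` separates genes with only inactive contacts from
    genes with no significant contacts at all). The four labels partition the
    active-gene set — asserted on every run.

    ``ambiguous_oe='both'`` additionally counts a PPI whose other end also
    carries a peak toward the gene's EPI tally (the default keeps promoter
    precedence strict).
    """
    if ambiguous_oe not in ("ppi", "both"):
        raise ValueError("ambiguous_oe must be 'ppi' or 'both'")
    cols = list(reference_samples) if reference_samples else list(expression.columns)
    mean_expr = expression[cols].mean(axis=1)

    peak_trees = _build_trees(peaks)
    gene_windows: dict[str, list[GenomicInterval]] = {}
    for rec in promoters:
        gene_windows.setdefault(rec.gene_id, []).append(rec.window)
        w = rec.window
        rec.active = bool(
            w.chrom in peak_trees and peak_trees[w.chrom].overlap(w.start, w.end)
        )
    gene_peak_positive = {
        g: any(
            w.chrom in peak_trees and peak_trees[w.chrom].overlap(w.start, w.end)
            for w in wins
        )
        for g, wins in gene_windows.items()
    }

    missing = [g for g in gene_windows if g not in mean_expr.index]
    if missing:
        warnings.warn(
            f"{len(missing)} promoter genes absent from expression table; "
            "treated as count 0",
            stacklevel=2,
        )
    active_genes = {
        g
        for g in gene_windows
        if gene_peak_positive[g] and float(mean_expr.get(g, 0.0)) >= active_count_min
    }

    n_epi: dict[str, int] = {g: 0 for g in gene_windows}
    n_ppi: dict[str, int] = {g: 0 for g in gene_windows}
    touched: dict[str, bool] = {g: False for g in gene_windows}
    for it in interactions:
        if it.regulatory_class is None:
            raise ValueError("interactions must be classified before gene aggregation")
        if it.end_roles is not None:
            bait_ann = it.ann1 if it.end_roles[0] == "bait" else it.ann2
            oe_ann = it.ann2 if it.end_roles[0] == "bait" else it.ann1
            gene_sets = [bait_ann.overlapping_gene_ids]
            oe_anns = [oe_ann]
        else:
            # symmetric loops: each promoter-overlapping end claims the gene
            gene_sets = [it.ann1.overlapping_gene_ids, it.ann2.overlapping_gene_ids]
            oe_anns = [it.ann2, it.ann1]
        for genes, oe in zip(gene_sets, oe_anns):
            for g in genes:
                if g not in touched:
                    continue
                touched[g] = True
                if it.regulatory_class == "EPI":
                    n_epi[g] += 1
                elif it.regulatory_class == "PPI":
                    n_ppi[g] += 1
                    if ambiguous_oe == "both" and oe.is_promoter and oe.overlaps_peak:
                        n_epi[g] += 1

    out: dict[str, PromoterSummary] = {}
    for g in sorted(active_genes):
        if n_epi[g] and n_ppi[g]:
            label = "EPI_AND_PPI"
        elif n_epi[g]:
            label = "EPI_ONLY"
        elif n_ppi[g]:
            label = "PPI_ONLY"
        else:
            label = "NO_ACTIVE_OE"
        out[g] = PromoterSummary(
            gene_id=g,
            promoter_class=label,
            n_epi=n_epi[g],
            n_ppi=n_ppi[g],
            has_any_interaction=touched[g],
        )
    counts = pd.Series([s.promoter_class for s in out.values()]).value_counts()
    assert counts.sum() == len(active_genes), "promoter classes must partition"
    return out


def normalize_per_10M(
    interactions: Sequence[Interaction], library_size: float
) -> Sequence[Interaction]:
    """Set score = raw_count x 1e7 / library_size for every interaction."""
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    for it in interactions:
        if it.raw_count is None:
            raise ValueError(f"interaction {it.id} lacks a raw_count")
        it.score = it.raw_count * 1e7 / library_size
    return interactions


def deduplicate_interactions(
    interactions: Sequence[Interaction],
) -> list[Interaction]:
    """Keep one record per (sample, canonical id).

    Among duplicates the record with the highest raw_count wins; ties (and
    records without counts) resolve to the first occurrence, so the operation
    is deterministic and order-stable.
    """
    best: dict[tuple[str, str], Interaction] = {}
    order: list[tuple[str, str]] = []
    for it in interactions:
        key = (it.sample, it.id)
        if key not in best:
            best[key] = it
            order.append(key)
        else:
            cur = best[key]
            if (it.raw_count or 0) > (cur.raw_count or 0):
                best[key] = it
    return [best[k] for k in order]
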