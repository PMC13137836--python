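"""Gene-level integration: enrichment, expression contrasts, loop/expression
concordance, regulatory-region dependency overlap, and Bliss drug synergy.

The statistics are deliberately plain: Fisher's exact test on 2x2 membership
tables, Welch (or paired) t for group means, Spearman rank correlation for
loop-change vs expression-change concordance, and the Bliss independence
model for two-drug combinations with the conventional +/-10 call thresholds
on the x100 excess scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, _OverlapLookup
from .io import Interaction

__all__ = [
    "EnrichmentResult",
    "epi_enrichment",
    "ContrastResult",
    "expression_contrast",
    "gene_epi_scores",
    "gene_loop_counts",
    "hichip_gene_log2fc",
    "interaction_expression_concordance",
    "peak_dependency_overlap",
    "SynergyResult",
    "bliss_synergy",
    "normalize_viability",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 membership comparison of a dichotomy between two gene sets."""

    a_positive: int
    a_negative: int
    b_positive: int
    b_negative: int
    fraction_a: float
    fraction_b: float
    odds_ratio: float
    p_two_sided: float


def epi_enrichment(
    gene_set_a: Iterable[str],
    gene_set_b: Iterable[str],
    epi_positive: Mapping[str, bool],
) -> EnrichmentResult:
    """Compare the EPI-positive fraction between two gene sets.

    ``epi_positive`` must cover the union of both sets (typically derived
    from the promoter classification: EPI_ONLY or EPI_AND_PPI). The p-value
    is Fisher's exact two-sided; the odds ratio uses the cross-product, with
    the Haldane +0.5 correction applied to all cells when any cell is 0.
    """
    set_a, set_b = list(gene_set_a), list(gene_set_b)
    if not set_a:
        raise ValueError("gene_set_a is empty")
    if not set_b:
        raise ValueError("gene_set_b is empty")
    a_pos = sum(bool(epi_positive[g]) for g in set_a)
    b_pos = sum(bool(epi_positive[g]) for g in set_b)
    a_neg, b_neg = len(set_a) - a_pos, len(set_b) - b_pos
    table = np.array([[a_pos, a_neg], [b_pos, b_neg]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        ap, an, bp, bn = (x + 0.5 for x in (a_pos, a_neg, b_pos, b_neg))
    else:
        ap, an, bp, bn = a_pos, a_neg, b_pos, b_neg
    return EnrichmentResult(
        a_positive=a_pos,
        a_negative=a_neg,
        b_positive=b_pos,
        b_negative=b_neg,
        fraction_a=a_pos / len(set_a),
        fraction_b=b_pos / len(set_b),
        odds_ratio=(ap * bn) / (an * bp),
        p_two_sided=float(p),
    )


@dataclass(frozen=True)
class ContrastResult:
    mean_a: float
    mean_b: float
    mean_diff: float
    t_statistic: float
    p_two_sided: float
    degenerate: bool = False


def expression_contrast(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
) -> ContrastResult:
    """Welch t (default) or paired t comparison of two value sets.

    Degenerate inputs (zero pooled variance, e.g. identical constant sets)
    report p = 1 with the ``degenerate`` flag instead of NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("expression_contrast needs >= 2 values per set")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired contrast needs equal-length sets")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            t, p, degenerate = 0.0, 1.0, True
        else:
            t, p = stats.ttest_rel(a, b)
            degenerate = False
    else:
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            t, p, degenerate = 0.0, 1.0, True
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            degenerate = False
    return ContrastResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_diff=float(a.mean() - b.mean()),
        t_statistic=float(t),
        p_two_sided=float(p),
        degenerate=degenerate,
    )


def gene_epi_scores(
    interactions: Sequence[Interaction],
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Aggregate EPI scores per bait gene: mean (primary), sum and count.

    Genes with no EPI simply do not appear (restrict with ``genes`` to
    subset). Baits spanning several promoters contribute to every overlapped
    gene.
    """
    per_gene: dict[str, list[float]] = {}
    for it in interactions:
        if it.regulatory_class != "EPI":
            continue
        if it.score is None:
            raise ValueError(f"interaction {it.id} lacks a score")
        bait_ann = it.ann1 if (it.end_roles or ("bait",))[0] == "bait" else it.ann2
        for g in bait_ann.overlapping_gene_ids:
            per_gene.setdefault(g, []).append(float(it.score))
    if genes is not None:
        wanted = set(genes)
        per_gene = {g: v for g, v in per_gene.items() if g in wanted}
    rows = {
        g: {
            "epi_score_mean": float(np.mean(v)),
            "epi_score_sum": float(np.sum(v)),
            "epi_count": len(v),
        }
        for g, v in sorted(per_gene.items())
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")


def gene_loop_counts(
    per_sample: Mapping[str, Sequence[Interaction]],
    promoter_windows: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Count loops per gene per sample via promoter-window overlap of either end."""
    lookups = {
        g: _OverlapLookup(windows) for g, windows in promoter_windows.items()
    }
    counts = {
        sample: {g: 0 for g in promoter_windows} for sample in per_sample
    }
    for sample, loops in per_sample.items():
        for it in loops:
            for g, lookup in lookups.items():
                if lookup.any_overlap(it.end1) or lookup.any_overlap(it.end2):
                    counts[sample][g] += 1
    return pd.DataFrame(counts).rename_axis("gene_id")


def hichip_gene_log2fc(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """log2 of group-mean loop counts per gene: log2((mA + c) / (mB + c)).

    Antisymmetric in the two groups by construction.
    """
    mean_a = counts[list(group_a)].mean(axis=1)
    mean_b = counts[list(group_b)].mean(axis=1)
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount)).rename(
        "loop_log2fc"
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for tiny n (used as an oracle path)."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in permutations(ry):
        r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
        total += 1
        if r >= obs - 1e-12:
            count += 1
    return count / total


def interaction_expression_concordance(
    loop_log2fc: pd.Series,
    expression_log2fc: pd.Series,
    min_genes: int = 10,
) -> tuple[float, float, int]:
    """Spearman rank correlation between loop change and expression change.

    Computed on the genes present in both series; fewer than ``min_genes``
    shared genes is an error. Ties use midranks; the p-value is the
    t-approximation (exact enumeration is available only at trivial n).
    Returns (rho, p_two_sided, n_shared).
    """
    shared = loop_log2fc.index.intersection(expression_log2fc.index)
    if len(shared) < min_genes:
        raise ValueError(
            f"concordance needs >= {min_genes} shared genes, got {len(shared)}"
        )
    x = loop_log2fc.loc[shared].to_numpy(dtype=float)
    y = expression_log2fc.loc[shared].to_numpy(dtype=float)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), int(len(shared))


def peak_dependency_overlap(
    pondown_regions: Sequence[GenomicInterval],
    tf_down_regions: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Fraction of drug-downregulated regions overlapping each TF-dependent set.

    A region counts as overlapping a TF set when it shares >= 1 bp with any
    region in it; the union row reports regions hit by at least one TF.
    """
    pondown = list(pondown_regions)
    if not pondown:
        raise ValueError("pondown region set is empty")
    rows = {}
    hit_any = np.zeros(len(pondown), dtype=bool)
    for tf, regions in tf_down_regions.items():
        lookup = _OverlapLookup(regions)
        hits = np.array([lookup.any_overlap(r) for r in pondown])
        hit_any |= hits
        rows[tf] = {"n_overlap": int(hits.sum()), "fraction": hits.mean()}
    rows["union"] = {"n_overlap": int(hit_any.sum()), "fraction": hit_any.mean()}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("tf")


@dataclass
class SynergyResult:
    """Bliss excess grid (x100) over combination cells and the overall call."""

    excess: pd.DataFrame
    mean_score: float
    call: str


def bliss_synergy(viability: pd.DataFrame) -> SynergyResult:
    """Score a two-drug dose grid against Bliss independence.

    ``viability`` holds the fraction of live cells with drug-A doses on the
    index and drug-B doses on the columns, including the zero-dose margins
    (so ``viability.loc[0, 0]`` is the untreated well). Inhibition is
    ``y = 1 - viability``; the expected combination inhibition under
    independence is ``yA + yB - yA*yB``, and each combination cell's excess
    ``(y_obs - expected) x 100`` is averaged (margins excluded) into the mean
    score. Calls: > +10 synergistic, < -10 antagonistic, else additive.
    """
    v = viability.astype(float)
    if ((v.to_numpy() < 0) | (v.to_numpy() > 1)).any():
        raise ValueError("viability values must lie in [0, 1]; normalize first")
    doses_a = [float(d) for d in v.index]
    doses_b = [float(d) for d in v.columns]
    if 0.0 not in doses_a or 0.0 not in doses_b:
        raise ValueError("dose grid must include zero-dose margins for both drugs")
    a0 = v.index[doses_a.index(0.0)]
    b0 = v.columns[doses_b.index(0.0)]
    y = 1.0 - v
    combo_a = [i for i, d in zip(v.index, doses_a) if d > 0]
    combo_b = [j for j, d in zip(v.columns, doses_b) if d > 0]
    excess = pd.DataFrame(index=combo_a, columns=combo_b, dtype=float)
    for i in combo_a:
        ya = y.loc[i, b0]
        for j in combo_b:
            yb = y.loc[a0, j]
            expected = ya + yb - ya * yb
            excess.loc[i, j] = (y.loc[i, j] - expected) * 100.0
    mean_score = float(excess.to_numpy().mean())
    if mean_score > 10.0:
        call = "synergistic"
    elif mean_score < -10.0:
        call = "antagonistic"
    else:
        call = "additive"
    return SynergyResult(excess=excess, mean_score=mean_score, call=call)


def normalize_viability(
    raw: pd.DataFrame,
    reference_wells: Sequence[tuple[object, object]],
) -> pd.DataFrame:
    """Scale a raw-signal plate by the mean of its reference wells.

    Reference wells (e.g. the kinase-inhibitor-only column) map to 1.0 on
    average; scaling the whole plate by a constant leaves the output
    invariant.
    """
    if not reference_wells:
        raise ValueError("no reference wells given")
    ref = [float(raw.loc[i, j]) for i, j in reference_wells]
    mean_ref = float(np.mean(ref))
    if math.isclose(mean_ref, 0.0):
        raise ValueError("reference wells have zero mean signal")
    return raw.astype(float) / mean_ref
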