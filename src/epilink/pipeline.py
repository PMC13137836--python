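"""Study-shaped pipeline stages over a data bundle.

Each stage is a pure function from loaded study tables to result tables, so
the CLI subcommands, the numbered analysis scripts and the test suite all
execute exactly the same code path. A *study* here is the file bundle the
generator emits (or equivalently real downstream tables in the same
dialects): gene annotation, per-sample H3K27ac peaks for two conditions,
per-sample promoter-capture interactions, HiChIP loops with raw counts,
expression replicates, DEG tables per contrast, region tag counts and
viability plates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify as _classify
from . import differential as _diff
from . import integrate as _int
from . import signatures as _sig
from .intervals import (
    GenomicInterval,
    PromoterRecord,
    make_promoter_windows,
    presence_absence_differential,
)
from .io import (
    Interaction,
    read_bed,
    read_deg,
    read_expression,
    read_gene_table,
    read_interactions_bedpe,
    read_interactions_ibed,
)
from .simulate import SyntheticBundle

__all__ = [
    "Thresholds",
    "load_study",
    "classify_stage",
    "signature_stage",
    "differential_stage",
    "integrate_stage",
    "run_all",
]


@dataclass
class Thresholds:
    """Every printed analysis parameter, in one place."""

    chicago_min: float = 5.0
    active_count_min: float = 10.0
    lfc_min: float = 1.0
    padj_max: float = 0.05
    fold_min: float = 2.0
    p_max: float = 0.05
    merge_gap: int = 1000
    flank: int = 1000
    size: int = 500
    synergy_bound: float = 10.0
    pseudocount: float = 0.5

    def validate(self) -> None:
        for name in ("chicago_min", "active_count_min", "lfc_min", "padj_max",
                     "fold_min", "p_max", "merge_gap", "flank", "size",
                     "synergy_bound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


def load_study(bundle_dir: str | Path, chicago_min: float = 5.0) -> SyntheticBundle:
    """Load a written study bundle back through the dialect readers.

    The CHiCAGO-score filter is applied at read time, as it would be on real
    interaction calls; ground truth (if present) is not loaded — pipeline
    stages never see it.
    """
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    files = manifest["files"]
    genes = read_gene_table(bundle_dir / files["genes"])
    peaks: dict[str, dict[str, list[GenomicInterval]]] = {}
    pchic: dict[str, list[Interaction]] = {}
    hichip: dict[str, list[Interaction]] = {}
    for key, rel in files.items():
        if key.startswith("peaks/"):
            _, cond, sample = key.split("/")
            peaks.setdefault(cond, {})[sample] = read_bed(bundle_dir / rel)
        elif key.startswith("pchic/"):
            sample = key.split("/")[1]
            pchic[sample] = read_interactions_ibed(
                bundle_dir / rel, sample=sample, min_score=chicago_min
            )
        elif key.startswith("hichip/"):
            sample = key.split("/")[1]
            hichip[sample] = read_interactions_bedpe(bundle_dir / rel, sample=sample)
    expression = read_expression(bundle_dir / files["expression"])
    deg = {
        key.split("/")[1]: read_deg(bundle_dir / rel)
        for key, rel in files.items()
        if key.startswith("deg/")
    }
    region_counts = pd.read_csv(
        bundle_dir / files["region_counts"], sep="\t", index_col="region"
    )
    regions = read_bed(bundle_dir / files["regions"])
    viability = {
        key.split("/")[1]: pd.read_csv(bundle_dir / rel, sep="\t",
                                       index_col="dose_tki")
        for key, rel in files.items()
        if key.startswith("viability/")
    }
    for grid in viability.values():
        grid.columns = [float(c) for c in grid.columns]
        grid.index = [float(i) for i in grid.index]
    from .simulate import SyntheticConfig

    return SyntheticBundle(
        config=SyntheticConfig(seed=manifest["seed"]),
        genes=genes,
        peaks=peaks,
        pchic=pchic,
        hichip=hichip,
        hichip_library_sizes=manifest["hichip_library_sizes"],
        expression=expression,
        deg=deg,
        region_counts=region_counts,
        chip_library_sizes=manifest["chip_library_sizes"],
        regions=regions,
        viability=viability,
        truth=None,
    )


def _filter_min_score(
    interactions: Sequence[Interaction], min_score: float
) -> list[Interaction]:
    return [it for it in interactions if it.score is not None and
            it.score >= min_score]


def _group1_samples(pchic: Mapping[str, Sequence[Interaction]]) -> list[str]:
    g1 = sorted(s for s in pchic if s.startswith("PH"))
    return g1 if g1 else sorted(pchic)


@dataclass
class ClassifyResult:
    promoters: list[PromoterRecord]
    reference_peaks: list[GenomicInterval]
    per_sample: dict                 # sample -> classified [Interaction]
    unique_interactions: list        # one record per canonical id (group 1)
    summaries: dict                  # gene_id -> PromoterSummary
    active_genes: set
    class_counts: pd.Series

    def summary_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": s.gene_id,
                "promoter_class": s.promoter_class,
                "n_EPI": s.n_epi,
                "n_PPI": s.n_ppi,
                "has_any_interaction": s.has_any_interaction,
            }
            for s in self.summaries.values()
        ]
        return pd.DataFrame(rows)


def classify_stage(
    bundle: SyntheticBundle, thresholds: Thresholds | None = None
) -> ClassifyResult:
    """Annotate and classify promoter-capture interactions; label active genes.

    Reference H3K27ac peaks are the first control-condition sample; the
    promoter classification aggregates the deduplicated union of the disease
    group's interactions, with activity judged on the mean of the
    control-condition expression replicates.
    """
    th = thresholds or Thresholds()
    promoters = make_promoter_windows(bundle.genes, flank=th.flank)
    ref_sample = sorted(bundle.peaks["dmso"])[0]
    ref_peaks = bundle.peaks["dmso"][ref_sample]
    g1 = _group1_samples(bundle.pchic)
    per_sample: dict[str, list[Interaction]] = {}
    for sample, rows in bundle.pchic.items():
        kept = _classify.deduplicate_interactions(
            _filter_min_score(rows, th.chicago_min)
        )
        _classify.annotate_ends(kept, ref_peaks, promoters)
        _classify.classify_interactions(kept, mode="pchic")
        per_sample[sample] = kept
    unique: dict[str, Interaction] = {}
    for sample in g1:
        for it in per_sample[sample]:
            unique.setdefault(it.id, it)
    reference_cols = [c for c in bundle.expression.columns if c.startswith("dmso")]
    summaries = _classify.classify_promoters(
        list(unique.values()),
        promoters,
        ref_peaks,
        bundle.expression,
        active_count_min=th.active_count_min,
        reference_samples=reference_cols or None,
    )
    counts = (
        pd.Series([s.promoter_class for s in summaries.values()])
        .value_counts()
        .reindex(_classify.PROMOTER_CLASSES, fill_value=0)
    )
    return ClassifyResult(
        promoters=promoters,
        reference_peaks=ref_peaks,
        per_sample=per_sample,
        unique_interactions=list(unique.values()),
        summaries=summaries,
        active_genes=set(summaries),
        class_counts=counts,
    )


@dataclass
class SignatureResult:
    core_ids: set
    matrix: pd.DataFrame
    dendrogram: _sig.Dendrogram
    pca: _sig.PCAResult


def signature_stage(
    classified: ClassifyResult,
    core_samples: Sequence[str] | None = None,
    class_filter: Sequence[str] = ("EPI", "PPI"),
) -> SignatureResult:
    """Core interaction set, score matrix over all samples, UPGMA and PCA."""
    per_sample = classified.per_sample
    g1 = list(core_samples) if core_samples else _group1_samples(per_sample)
    core = _sig.core_interactions(
        {s: per_sample[s] for s in g1}, class_filter=class_filter
    )
    all_ids = sorted({it.id for rows in per_sample.values() for it in rows})
    scores = {
        sample: {it.id: float(it.score) for it in rows}
        for sample, rows in per_sample.items()
    }
    matrix = _sig.build_matrix(all_ids, scores, missing_policy="zero")
    return SignatureResult(
        core_ids=core,
        matrix=matrix,
        dendrogram=_sig.upgma(matrix),
        pca=_sig.pca(matrix),
    )


@dataclass
class DifferentialResult:
    nonpromoter_peaks: dict          # condition -> sample -> [interval]
    lost_consensus: list             # presence/absence mode, all samples agree
    gained_consensus: list
    region_scores: pd.DataFrame      # per-10M normalized tags
    down_regions: list               # count-mode consensus down regions
    zscores: pd.DataFrame
    deg_sets: dict                   # contrast -> DEGSets
    gene_groups: dict                # gene_id -> group label


def differential_stage(
    bundle: SyntheticBundle,
    promoters: Sequence[PromoterRecord],
    thresholds: Thresholds | None = None,
) -> DifferentialResult:
    """Differential H3K27ac in both modes, DEG calls and gene grouping."""
    th = thresholds or Thresholds()
    windows = [p.window for p in promoters]
    nonprom = {
        cond: {
            s: _diff.filter_nonpromoter_peaks(ivs, windows)
            for s, ivs in samples.items()
        }
        for cond, samples in bundle.peaks.items()
    }
    dmso_samples = sorted(nonprom["dmso"])
    tki_samples = sorted(nonprom["tki"])
    lost_sets, gained_sets = [], []
    for ds, ts in zip(dmso_samples, tki_samples):
        lost, gained = presence_absence_differential(
            nonprom["dmso"][ds], nonprom["tki"][ts]
        )
        lost_sets.append(lost)
        gained_sets.append(gained)
    lost_consensus = (
        _diff.consensus_differential(lost_sets) if all(lost_sets) else []
    )
    gained_consensus = (
        _diff.consensus_differential(gained_sets)
        if all(len(g) > 0 for g in gained_sets)
        else []
    )

    scores = _diff.score_regions(bundle.region_counts, bundle.chip_library_sizes)
    region_by_name = {r.name: r for r in bundle.regions}
    per_rep_down = []
    for ds, ts in zip(dmso_samples, tki_samples):
        control = {region_by_name[n]: scores.loc[n, ds] for n in scores.index}
        treatment = {region_by_name[n]: scores.loc[n, ts] for n in scores.index}
        per_rep_down.append(
            _diff.differential_regions_by_count(
                control, treatment, fold_min=th.fold_min, p_max=th.p_max,
                direction="down",
            )
        )
    down_regions = (
        _diff.consensus_differential(per_rep_down)
        if all(len(d) > 0 for d in per_rep_down)
        else []
    )
    deg_sets = {
        contrast: _diff.call_degs(records, lfc_min=th.lfc_min,
                                  padj_max=th.padj_max)
        for contrast, records in bundle.deg.items()
    }
    universe = list(bundle.expression.index)
    gene_groups = _diff.group_genes(
        deg_sets["ph_vs_healthy"], deg_sets["tki_vs_dmso"], universe
    )
    return DifferentialResult(
        nonpromoter_peaks=nonprom,
        lost_consensus=lost_consensus,
        gained_consensus=gained_consensus,
        region_scores=scores,
        down_regions=down_regions,
        zscores=_diff.row_zscore(scores),
        deg_sets=deg_sets,
        gene_groups=gene_groups,
    )


@dataclass
class IntegrateResult:
    sensitive_genes: set
    enrichment_by_epi: _int.EnrichmentResult     # sensitive fraction, EPI+ vs EPI-
    enrichment_by_sensitivity: _int.EnrichmentResult  # EPI fraction, sens vs insens
    expression_contrast: _int.ContrastResult     # EPI+ vs NO_ACTIVE_OE expression
    epi_scores: pd.DataFrame
    loop_counts: pd.DataFrame
    loop_log2fc: pd.Series
    concordance: tuple                            # (rho, p, n)
    synergy: dict                                 # plate -> SynergyResult


def integrate_stage(
    bundle: SyntheticBundle,
    classified: ClassifyResult,
    diff_result: DifferentialResult,
    thresholds: Thresholds | None = None,
) -> IntegrateResult:
    """Gene-level integration of classes with expression, drugs and loops."""
    th = thresholds or Thresholds()
    summaries = classified.summaries
    epi_positive = {
        g: s.promoter_class in ("EPI_ONLY", "EPI_AND_PPI")
        for g, s in summaries.items()
    }
    active = set(summaries)
    drug_down = set(diff_result.deg_sets["drug_vs_dmso"].down)
    sensitive = drug_down & active
    insensitive = active - sensitive
    epi_plus = {g for g in active if epi_positive[g]}
    epi_minus = active - epi_plus
    sensitive_map = {g: g in sensitive for g in active}
    enrichment_by_epi = _int.epi_enrichment(
        sorted(epi_plus), sorted(epi_minus), sensitive_map
    )
    enrichment_by_sensitivity = _int.epi_enrichment(
        sorted(sensitive), sorted(insensitive), epi_positive
    )

    ref_cols = [c for c in bundle.expression.columns if c.startswith("dmso")]
    mean_expr = bundle.expression[ref_cols].mean(axis=1)
    no_oe = [g for g in active if summaries[g].promoter_class == "NO_ACTIVE_OE"]
    contrast = _int.expression_contrast(
        mean_expr.loc[sorted(epi_plus)].to_numpy(),
        mean_expr.loc[no_oe].to_numpy(),
    )

    epi_scores = _int.gene_epi_scores(classified.unique_interactions)

    promoter_windows: dict[str, list[GenomicInterval]] = {}
    for p in classified.promoters:
        promoter_windows.setdefault(p.gene_id, []).append(p.window)
    hichip_norm = {}
    for sample, loops in bundle.hichip.items():
        loops = _classify.deduplicate_interactions(loops)
        _classify.normalize_per_10M(loops, bundle.hichip_library_sizes[sample])
        hichip_norm[sample] = loops
    loop_counts = _int.gene_loop_counts(hichip_norm, promoter_windows)
    g1 = sorted(s for s in hichip_norm if s.startswith("PH")) or sorted(hichip_norm)[:1]
    g2 = sorted(set(hichip_norm) - set(g1))
    loop_lfc = _int.hichip_gene_log2fc(loop_counts, g1, g2,
                                       pseudocount=th.pseudocount)
    ph_deg = diff_result.deg_sets["ph_vs_healthy"]
    deg_genes = sorted(ph_deg.deregulated)
    expr_lfc = pd.Series(
        {r.gene_id: r.log2fc for r in bundle.deg["ph_vs_healthy"]}
    ).loc[deg_genes]
    concordance = _int.interaction_expression_concordance(
        loop_lfc.loc[loop_lfc.index.intersection(expr_lfc.index)], expr_lfc
    )

    synergy = {plate: _int.bliss_synergy(grid)
               for plate, grid in bundle.viability.items()}
    return IntegrateResult(
        sensitive_genes=sensitive,
        enrichment_by_epi=enrichment_by_epi,
        enrichment_by_sensitivity=enrichment_by_sensitivity,
        expression_contrast=contrast,
        epi_scores=epi_scores,
        loop_counts=loop_counts,
        loop_log2fc=loop_lfc,
        concordance=concordance,
        synergy=synergy,
    )


def run_all(
    bundle: SyntheticBundle, thresholds: Thresholds | None = None
) -> dict:
    """Execute classify -> signature -> differential -> integrate in order."""
    th = thresholds or Thresholds()
    th.validate()
    classified = classify_stage(bundle, th)
    signature = signature_stage(classified)
    diff_result = differential_stage(bundle, classified.promoters, th)
    integrated = integrate_stage(bundle, classified, diff_result, th)
    return {
        "classify": classified,
        "signature": signature,
        "differential": diff_result,
        "integrate": integrated,
    }
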