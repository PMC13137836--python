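"""Differential H3K27ac activity and gene grouping.

Two differential-region modes mirror the study's rules:

* presence/absence — a peak counted as lost or gained when it has no >=1 bp
  overlap in the other condition (``intersect -v`` logic; delegated to
  :mod:`epilink.intervals`);
* count-based — a fold-change plus one-sided Poisson tail test on per-10M
  normalized tag counts over a shared region set (fold >= 2, P < 0.05, fixed
  500-bp windows by default), the documented core of Homer's
  getDifferentialPeaks.

DEG thresholding (padj < 0.05, |log2FC| > 1) and the four-way gene grouping
(disease-upregulated x kinase-inhibitor-sensitive) complete the stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .intervals import (
    GenomicInterval,
    _OverlapLookup,
    consensus_regions,
)
from .io import DEGRecord

__all__ = [
    "filter_nonpromoter_peaks",
    "recenter_regions",
    "differential_regions_by_count",
    "consensus_differential",
    "score_regions",
    "row_zscore",
    "DEGSets",
    "call_degs",
    "group_genes",
    "GENE_GROUPS",
]

GENE_GROUPS = ("PH_UP_ONLY", "PH_UP_TKI_DOWN", "TKI_DOWN_ONLY", "OTHER")


def filter_nonpromoter_peaks(
    peaks: Iterable[GenomicInterval],
    promoter_windows: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Drop peaks with any promoter-window overlap (non-promoter peak set)."""
    lookup = _OverlapLookup(promoter_windows)
    return [p for p in peaks if not lookup.any_overlap(p)]


def recenter_regions(
    regions: Iterable[GenomicInterval], size: int = 500
) -> list[GenomicInterval]:
    """Re-center each region to a fixed-width window around its midpoint.

    Harmonizes merged peaks of varying width before tag counting (the
    ``-size 500`` convention); windows are clipped at position 0.
    """
    out = []
    for r in regions:
        mid = (r.start + r.end) // 2
        start = max(0, mid - size // 2)
        out.append(GenomicInterval(r.chrom, start, start + size, r.strand, r.name))
    return out


def poisson_tail(observed: float, mean: float) -> float:
    """P(X >= observed) for X ~ Poisson(mean), with observed rounded up."""
    k = int(np.ceil(observed))
    return float(poisson.sf(k - 1, mean))


def differential_regions_by_count(
    control_scores: Mapping[GenomicInterval, float],
    treatment_scores: Mapping[GenomicInterval, float],
    fold_min: float = 2.0,
    p_max: float = 0.05,
    direction: str = "up",
) -> list[GenomicInterval]:
    """Flag regions with a directional fold change backed by a Poisson test.

    Scores are per-10M normalized tag counts on a shared region set. For
    ``direction='up'`` a region is flagged when
    ``treatment / max(control, 1) >= fold_min`` and the one-sided tail
    ``P(X >= treatment)`` under ``X ~ Poisson(max(control, 1))`` is below
    ``p_max``; 'down' swaps the roles. The floor of one pseudo-tag keeps
    empty-control regions testable without dividing by zero.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    regions = list(control_scores)
    if not regions:
        raise ValueError("differential test needs a non-empty region set")
    flagged = []
    for region in regions:
        c = float(control_scores[region])
        t = float(treatment_scores[region])
        obs, comparison = (t, c) if direction == "up" else (c, t)
        lam = max(comparison, 1.0)
        if obs / lam >= fold_min and poisson_tail(obs, lam) < p_max:
            flagged.append(region)
    return flagged


def consensus_differential(
    per_sample_regions: Sequence[Iterable[GenomicInterval]],
) -> list[GenomicInterval]:
    """Sub-regions flagged differential in every sample (bp-resolution)."""
    return consensus_regions(per_sample_regions, require_all=True)


def score_regions(
    raw_counts: pd.DataFrame,
    library_sizes: Mapping[str, float],
) -> pd.DataFrame:
    """Normalize per-region raw tag counts to tags per 10 million reads.

    ``raw_counts`` is regions x samples; each column is scaled by
    ``1e7 / library_size`` of its sample.
    """
    out = raw_counts.astype(float).copy()
    for sample in out.columns:
        lib = library_sizes[sample]
        if lib <= 0:
            raise ValueError(f"library size for {sample} must be positive")
        out[sample] = out[sample] * 1e7 / lib
    return out


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores for heatmap export (``scale="row"`` convention).

    Zero-variance rows map to all-0 rather than NaN so exports stay
    deterministic.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


@dataclass(frozen=True)
class DEGSets:
    up: frozenset[str]
    down: frozenset[str]

    @property
    def deregulated(self) -> frozenset[str]:
        return self.up | self.down


def call_degs(
    deg_table: Sequence[DEGRecord],
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
) -> DEGSets:
    """Partition a DEG table into up/down sets by the printed thresholds.

    Strict inequalities on both axes: log2FC must exceed ``lfc_min`` in
    magnitude and padj must be below ``padj_max``.
    """
    up = frozenset(
        r.gene_id for r in deg_table if r.log2fc > lfc_min and r.padj < padj_max
    )
    down = frozenset(
        r.gene_id for r in deg_table if r.log2fc < -lfc_min and r.padj < padj_max
    )
    return DEGSets(up=up, down=down)


def group_genes(
    ph_vs_healthy: DEGSets,
    dmso_vs_tki: DEGSets,
    universe: Iterable[str],
) -> dict[str, str]:
    """Four-way gene grouping from the disease and treatment contrasts.

    PH_UP_TKI_DOWN: disease-upregulated and kinase-inhibitor-downregulated;
    PH_UP_ONLY: disease-upregulated but not inhibitor-sensitive;
    TKI_DOWN_ONLY: inhibitor-downregulated and not disease-deregulated;
    OTHER: everything else in the assessed universe. The result is asserted
    to partition the universe.
    """
    universe = set(universe)
    out: dict[str, str] = {}
    for g in sorted(universe):
        ph_up = g in ph_vs_healthy.up
        tki_down = g in dmso_vs_tki.down
        if ph_up and tki_down:
            out[g] = "PH_UP_TKI_DOWN"
        elif ph_up:
            out[g] = "PH_UP_ONLY"
        elif tki_down and g not in ph_vs_healthy.deregulated:
            out[g] = "TKI_DOWN_ONLY"
        else:
            out[g] = "OTHER"
    assert set(out) == universe and all(v in GENE_GROUPS for v in out.values())
    return out
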