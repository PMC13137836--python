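#!/usr/bin/env python
"""Differential H3K27ac activity and gene grouping under kinase inhibition.

Two region modes: presence/absence (peaks with no overlap in the other
condition, intersected across replicates) and count-based (fold >= 2 with a
one-sided Poisson tail < 0.05 on per-10M tags, consensus across replicate
pairs). DEG tables are thresholded (|log2FC| > 1, padj < 0.05) and genes are
grouped by disease induction x inhibitor sensitivity.
"""

from pathlib import Path

import pandas as pd

from epilink.io import write_bed
from epilink.pipeline import classify_stage, differential_stage, load_study

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = load_study(ROOT / "bundle")
    classified = classify_stage(bundle)
    diff = differential_stage(bundle, classified.promoters)
    write_bed(diff.down_regions, ROOT / "down_regions.bed")
    write_bed(diff.lost_consensus, ROOT / "lost_consensus.bed")
    diff.zscores.round(9).to_csv(ROOT / "region_zscores.tsv", sep="\t")
    pd.Series(diff.gene_groups, name="group").rename_axis("gene_id").to_csv(
        ROOT / "gene_groups.tsv", sep="\t"
    )
    print(f"count-mode consensus down-regions: {len(diff.down_regions)}")
    print(f"presence/absence consensus lost peaks: {len(diff.lost_consensus)}")
    if diff.down_regions and diff.lost_consensus:
        from epilink.integrate import peak_dependency_overlap

        agree = peak_dependency_overlap(
            diff.down_regions, {"presence_absence": diff.lost_consensus}
        )
        frac = agree.loc["presence_absence", "fraction"]
        print(f"down-regions also called by presence/absence: {100 * frac:.1f}%")
    for contrast, sets in diff.deg_sets.items():
        print(f"DEGs {contrast}: {len(sets.up)} up, {len(sets.down)} down")
    groups = pd.Series(diff.gene_groups).value_counts()
    print("gene groups:")
    print(groups.to_string())


if __name__ == "__main__":
    main()
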