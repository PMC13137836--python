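# epilink

Integrative analysis of enhancer regulation from chromatin-interaction data.

`epilink` classifies promoter-capture Hi-C (PCHi-C) and HiChIP chromatin
contacts by H3K27ac and promoter-window status, builds cross-sample
interaction signatures (core sets, UPGMA clustering, PCA), calls consensus
differential H3K27ac regions, and integrates interaction classes per gene
with expression changes and drug sensitivity — including Bliss synergy
scoring of two-drug viability grids. It is aimed at regulatory-genomics
analyses of the kind used to dissect leukemia enhancer programs: which
active genes contact active enhancers, whether those genes are
preferentially drug-sensitive, and whether interaction signatures separate
disease subtypes.

## The core classifications and statistics

**Interaction classes.** With promoter windows W(g) = [TSS − 1 kb, TSS + 1 kb)
and an H3K27ac peak set K, a PCHi-C contact (bait b, other end o) is

- **EPI** (enhancer–promoter) if b is an H3K27ac⁺ promoter, o ∩ K ≠ ∅ and o
  overlaps no promoter window;
- **PPI** (promoter–promoter) if b is an H3K27ac⁺ promoter and o is an
  H3K27ac⁺ promoter;
- otherwise **none**, with the activity class (AP/IP × AO/IO) crossing
  bait/other-end peak status.

HiChIP loops are symmetric: **PPI** if both ends are promoters, **EEI**
(enhancer–enhancer) if neither is, **EPI** otherwise; raw loop counts are
normalized to score = count × 10⁷ / library size.

**Promoter classes.** Each *active* gene (promoter H3K27ac⁺ and mean
normalized count ≥ 10 in the reference condition) is labelled EPI_ONLY /
PPI_ONLY / EPI_AND_PPI / NO_ACTIVE_OE by aggregating its bait interactions;
the four labels partition the active-gene set.

**Signatures.** Interaction×sample score matrices (score ≥ 5 significance
filter; undetected contacts zero-filled) feed average-linkage (UPGMA)
clustering on Euclidean distances between samples and SVD-based PCA with
samples as observations — the R idiom `t() |> dist("euclidean") |>
hclust("average")` and `t() |> prcomp()`.

**Differential activity.** Non-promoter peaks lost/gained by presence/absence
(no ≥1 bp overlap in the other condition), or count-based: a region is
differential when fold ≥ 2 and the one-sided Poisson tail P(X ≥ observed |
λ = comparison tags per 10M, floor 1) < 0.05 on fixed 500-bp windows; per-
replicate calls are intersected at bp resolution. DEGs use padj < 0.05 and
|log₂FC| > 1.

**Integration.** Fisher's exact test on 2×2 gene-set memberships (EPI⁺ ×
drug-sensitive), Welch/paired t contrasts of expression, Spearman rank
correlation between per-gene HiChIP loop log₂FC (pseudocount 0.5) and
expression log₂FC, and Bliss synergy: with inhibition y = 1 − viability, the
expected combination inhibition is yA + yB − yA·yB and the score is the mean
of (y_obs − expected) × 100 over combination cells; mean > 10 is called
synergistic, < −10 antagonistic.

## Worked example

The numbered scripts under `analysis/` run the full study on a seeded
synthetic cohort with planted ground truth:

```bash
python analysis/01_simulate_study.py 1
python analysis/02_classify_interactions.py
python analysis/03_interaction_signatures.py
python analysis/04_differential_h3k27ac.py
python analysis/05_integrate_expression_drugs.py
```

Output of the classification and integration steps (seed 1):

```
active genes: 159
  EPI_ONLY        45  (28.3%)
  PPI_ONLY        27  (17.0%)
  EPI_AND_PPI     24  (15.1%)
  NO_ACTIVE_OE    63  (39.6%)
genes with EPIs: 43.4% of active genes

drug-sensitive: 69.6% of EPI+ genes vs 23.3% of EPI- genes (OR 7.5, Fisher p 8.16e-09)
mean expression EPI+ vs no-active-OE genes: 244 vs 86 (Welch p 7.42e-06)
loop-change vs expression-change Spearman rho 0.71 (p 1.11e-10, n 61)
Bliss combo_additive: mean score 0.4 -> additive
Bliss combo_synergistic: mean score 12.8 -> synergistic
```

43.4% of active genes carry enhancer contacts; those genes are strongly
enriched for sensitivity to the CBP/P300 inhibitor (69.6% vs 23.3%) and are
higher expressed; per-gene loop changes between the two sample groups track
expression changes; and the planted-synergistic drug combination scores
above the +10 Bliss call threshold while the additive plate stays near 0.
All of these recover the values planted by the generator (the study
conditions), which is what the test suite asserts.

The same pipeline is available as a CLI
(`epilink run-all --seed 1 --outdir out`, with `simulate / classify /
signature / differential / integrate` subcommands and a YAML config whose
unknown keys are rejected).

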