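# Methods

## Coordinate conventions and interval algebra

All coordinates are BED-style 0-based half-open `[start, end)`; readers for
1-based annotation dialects convert at the boundary (`read_gene_table(...,
one_based=True)`) so no downstream code ever mixes conventions. Overlap is
≥ 1 bp on the same chromosome; strand is carried but ignored for overlap and
used only to place the TSS (txStart on `+`, txEnd − 1 on `−`). Chromosome
names match by exact string equality; a `chr1`/`1` normalizer exists but is
off by default because silent aliasing corrupts overlap counts.

Promoter windows are TSS ± `flank` (default 1000 bp, i.e. a 2-kb window),
clipped at position 0, one window per transcript TSS with identical
duplicates per gene collapsed. Merging uses bedtools `-d` semantics: two
intervals join when their gap is ≤ `gap` (default 1000 bp), transitively.
Consensus regions are the maximal sub-intervals covered by *every* sample,
resolved by an event sweep at bp resolution over each sample's merged
footprint. Presence/absence differential peaks are those with no ≥ 1 bp
overlap in the other condition. All four operations are tested against
per-base brute-force oracles (rasterized base sets) on ≥ 1000 random
instances each.

## Interaction classification

PCHi-C rows are read from 10-column ibed files and filtered at the
significance score threshold (default 5, inclusive — matching the upstream
caller's own output convention). Interaction identity across samples is the
canonical id: the lexicographically ordered pair of end coordinates, which
assumes one shared fragment map across samples; a tolerance-window matcher
is deliberately out of scope. Duplicates per (sample, id) collapse to the
record with the highest raw count (ties: first seen).

An other end that overlaps both a promoter window and a peak is classified
PPI — promoter identity takes precedence, because the three-way EPI/PPI/
mixed outcome needs a precedence rule. The optional `ambiguous_oe="both"`
additionally counts such contacts toward the gene's EPI tally. Baits
spanning several promoter windows distribute their classification to every
overlapped gene, since fragment-level capture cannot resolve shared
promoters. HiChIP mode is fully symmetric (no bait), never emits activity
classes, and is the only mode that emits EEI; PCHi-C mode never does.

"Active gene" means: promoter window overlaps an H3K27ac peak *and* mean
normalized count ≥ `active_count_min` (default 10) over the
reference-condition replicates (the aggregate, not per-sample, since either
reading is defensible and the aggregate is stabler at n = 3). Genes missing
from the expression table count as 0 with a warning. The four promoter
classes partition the active-gene set; this is asserted at run time, not
merely tested.

## Signatures

The signature matrix holds one row per canonical interaction id and one
column per sample. Undetected interactions are zero-filled by default: at a
fixed significance threshold, non-detection is evidence of absence; a
`drop` policy (remove rows with any absence) is available for sensitivity
analysis. No variance filter is applied before clustering. UPGMA is
average-linkage agglomeration (scipy) on Euclidean distances between sample
columns; merge heights are average inter-cluster distances and are
non-decreasing (UPGMA admits no inversions). PCA treats samples as
observations (matrix transposed relative to storage), centers columns, does
not scale (the `prcomp` defaults), and canonicalizes component signs so the
largest-magnitude loading is positive — SVD signs are otherwise arbitrary
and determinism matters for byte-identical reruns.

## Differential H3K27ac

Three engines existed upstream; this package implements two. Presence/
absence reuses the interval algebra. The count-based rule is a simplified
surrogate for the fold-plus-Poisson core of the Homer differential-peak
test, parameter-compatible with `-F 2 -P 0.05 -size 500`: regions are
recentered to fixed 500-bp windows around their midpoints, tag counts are
normalized to tags per 10 million reads, and a region is flagged in a
direction when fold ≥ 2 against the comparison sample (floored at one
pseudo-tag, which keeps empty regions testable) and the one-sided Poisson
tail P(X ≥ observed | λ = comparison) < 0.05. The exact background scaling
and pseudo-count conventions of the original tool are not published; this
rule is the package's own, documented choice. Dispersion-model (DiffBind
style) results enter only as external tables. Heatmap exports are per-region
z-scores with zero-variance rows mapped to 0 (not NaN) for deterministic
files.

DEG thresholds are strict inequalities: log₂FC > 1 in magnitude and padj <
0.05. The four-way gene grouping (disease-up ∩ inhibitor-down, disease-up
only, inhibitor-down only and not disease-deregulated, other) partitions the
assessed universe by construction.

## Integration statistics

Fraction comparisons between gene sets are 2×2 problems and use Fisher's
exact test (two-sided), with the Haldane +0.5 correction on the odds ratio
when any cell is zero; a Welch t contrast is also emitted where figure
parity with bar-chart statistics is wanted. Degenerate-variance contrasts
report p = 1 with a flag instead of NaN. Per-gene EPI score aggregation
defaults to the mean, with sum and count carried alongside, since either is
a defensible summary. HiChIP per-gene loop change is
log₂((mean_A + c)/(mean_B + c)) with pseudocount c = 0.5 (antisymmetric in
the groups). Loop/expression concordance is Spearman's rho with midranks for
ties; the p-value uses the t approximation (an exact permutation enumeration
exists for n ≤ 8 and serves as a test oracle; the operation itself requires
≥ 10 shared genes, so the pipeline path is always the approximation).
Rank correlation deliberately replaces trend-line smoothing as the
quantitative statistic — a smoother is a visualization, not a test.

Bliss synergy: inhibition y = 1 − viability; expected combination inhibition
yA + yB − yA·yB from the single-agent margins; per-cell excess
(y_obs − expected) × 100; the plate score is the unweighted mean over
combination cells only (margins excluded), and the per-cell grid is exported
so window-maxima can be read off if preferred. Calls: > +10 synergistic,
< −10 antagonistic, otherwise additive. Viability normalization divides each
well by the mean of the experiment's reference wells (e.g. the
kinase-inhibitor-only wells) and is invariant to plate-wide scaling.

## Synthetic study generator

The generator emulates the *downstream tabular products* of a two-group
regulatory study — interaction calls with scores, peak calls, loop counts,
expression replicates, DEG tables, viability plates — never raw reads,
fragment-level contact noise, or copy number. Geometry: each chromosome
(default 3 × 4 Mb) is tiled into 5-kb fragments forming one shared fragment
map; genes (default 160) sit on even fragments with mid-fragment TSSs,
enhancer/other-end fragments come from the odd pool, so planted enhancers
can never overlap promoter windows and class truth is unambiguous at zero
peak jitter. Reciprocal promoter-pair contacts are resampled so every
planted PPI has a unique canonical id.

Planted structure and defaults (the study conditions):

- promoter-class fractions 0.28 / 0.17 / 0.15 / 0.40 (EPI_ONLY / PPI_ONLY /
  EPI_AND_PPI / NO_ACTIVE_OE), so ~43% of active genes carry EPIs;
- expression: per-gene base log₂ count ~ N(6, 1.2²), replicate noise
  sd 0.25 (log₂), +1.5 log₂ boost for EPI⁺ genes;
- drug model: P(sensitive) = 0.7 for EPI⁺ genes vs 0.2 otherwise, −2 log₂
  treatment effect — the enrichment the integration stage estimates;
- groups: 2 × 3 samples; 40 group-specific interactions per group with a
  score shift of 8 against per-sample score noise sd 0.5 (16× — well above
  the 5× shift-to-noise ratio at which within-group UPGMA merges are
  expected first);
- differential regions: 30% of enhancer regions lose H3K27ac fourfold under
  kinase inhibition at 40 expected tags per region;
- HiChIP loop rates per gene: 6 vs 1.5 between groups for disease-up genes,
  reversed for disease-down genes, 3/3 otherwise, library size 2 × 10⁷;
- viability plates: 4 × 4 dose grids from single-agent saturation curves,
  one plate with a planted Bliss excess of 0.15 (score ≈ +15) and one
  additive plate, well noise sd 0.005.

DEG tables are *computed* from the generated replicate counts — per-gene
Welch t on log₂(count + 1) with Benjamini–Hochberg adjustment — rather than
sampled independently, so the pipeline and the truth cannot disagree by
construction; differential-expression *model* fitting is intentionally not
re-implemented (DEG tables are pipeline inputs). All randomness flows from
one mandatory seed through `numpy.random.default_rng`; per-element draws
iterate ordered gene lists, never Python sets, so bundles are byte-identical
across processes.

What passing tests show — and do not. Exact recovery at zero jitter shows
the classification logic is correct under unambiguous geometry; it says
nothing about fragment-boundary ambiguity, peak-calling noise, or
promoter-sharing in real genomes (the jitter parameter degrades recovery
monotonically and is regression-tested at three levels, which probes the
overlap resolution but not real noise structure). The multi-seed checks
(100% class recovery per seed, per-seed binomial CIs covering the planted
0.7/0.2 sensitivity fractions in ≥ 90/100 seeds, PC1 separation in ≥ 95/100,
within-group-first UPGMA merges) are statements about these study
conditions, not universal claims.

## Problem sizes and numerical choices

Default problem sizes (160 genes, ~350 interactions × 6 samples, ~70
regions, 100-seed sweeps) keep a full pipeline run under a second and the
entire suite in well under a minute of compute per criterion; they were
chosen as the smallest sizes at which the planted effects are comfortably
detectable. Poisson tails round the observed count up (P(X ≥ ⌈obs⌉));
Fisher p-values come from scipy and are oracle-checked against direct
hypergeometric enumeration to 1e-9; UPGMA/PCA invariants (no inversions,
reconstruction to 1e-8 Frobenius, explained variance summing to ≤ 1 + 1e-9)
are tested rather than assumed. The exact-ten Bliss boundary is additive by
definition (−10..10), and tests construct exactly representable margins to
probe it.

## Known limitations

No `.hic`/`.cool` parsing, no loop or peak calling, no contact-significance
or dispersion modeling, no strand-aware overlap, no dose–response (IC50)
fitting, and no ZIP/LOEWE/HSA synergy models. Cross-sample interaction
identity requires a shared fragment map; data from heterogeneous digests
would need a matching step this package does not provide.
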