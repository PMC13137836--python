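"""Seeded generator for a complete toy regulatory-genomics study.

The generator plants known structure at every level the pipeline measures —
promoter interaction classes, drug-sensitivity enrichment among EPI genes,
group-specific interaction signatures, differential H3K27ac regions,
loop/expression concordance and Bliss synergy — and emits exactly the tabular
dialects the readers in :mod:`epilink.io` consume (BED peaks, ibed
interactions, BEDPE loops with raw counts, expression and DEG TSVs,
viability plates), plus the ground truth needed to score recovery.

Geometry: each chromosome is tiled into fixed fragments (one shared fragment
map across samples, so canonical interaction ids intersect cleanly). Genes
occupy even-index fragments; enhancer/other-end fragments come from the odd
pool, so a planted enhancer can never overlap a promoter window and class
truth is unambiguous at zero jitter.

DEG tables are *computed* from the generated replicate counts (per-gene Welch
t on log2 counts, Benjamini-Hochberg adjusted), never sampled independently,
so pipeline and truth cannot disagree by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .io import (
    DEGRecord,
    Interaction,
    write_bed,
    write_deg,
    write_expression,
    write_interactions_bedpe,
    write_interactions_ibed,
)

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticBundle", "generate",
           "write_bundle", "worked_example"]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the proportions the pipeline is meant to detect: ~43% of
    active genes carry EPIs, drug sensitivity 0.7 among EPI+ genes vs 0.2
    among the rest, a two-group interaction signature whose score shift is
    16x the per-sample score noise, and fourfold H3K27ac loss at planted
    differential regions.
    """

    seed: int
    # geometry
    n_chroms: int = 3
    chrom_length_bp: int = 4_000_000
    frag_size: int = 5_000
    n_genes: int = 160
    flank: int = 1_000
    # planted promoter-class fractions (must sum to 1)
    class_fractions: dict = field(
        default_factory=lambda: {
            "EPI_ONLY": 0.28,
            "PPI_ONLY": 0.17,
            "EPI_AND_PPI": 0.15,
            "NO_ACTIVE_OE": 0.40,
        }
    )
    # expression model (log2 scale)
    base_log2_mean: float = 6.0
    base_log2_sd: float = 1.2
    rep_log2_sd: float = 0.25
    epi_boost_log2: float = 1.5
    n_reps: int = 3
    # drug (CBP/P300-inhibitor) sensitivity model
    p_sensitive_epi: float = 0.7
    p_sensitive_non_epi: float = 0.2
    drug_effect_log2: float = -2.0
    # disease (Ph) and kinase-inhibitor (TKI) model
    p_ph_up: float = 0.30
    p_ph_down: float = 0.20
    ph_effect_log2: float = 2.0
    p_tki_reversal: float = 0.8
    p_tki_off_target: float = 0.05
    tki_effect_log2: float = -2.0
    # interaction group model
    n_samples_per_group: int = 3
    n_group_specific: int = 40
    group_score_shift: float = 8.0
    score_noise_sd: float = 0.5
    n_shared_background: int = 60
    n_noise_per_sample: int = 10
    n_subthreshold: int = 5
    score_base_low: float = 6.0
    score_base_high: float = 14.0
    # peak model
    peak_halfwidth: int = 300
    jitter_sd: float = 0.0
    # HiChIP model
    base_loop_rate: float = 3.0
    ph_loop_rate: float = 6.0
    ph_depleted_rate: float = 1.5
    hichip_library_size: float = 2e7
    # differential-region model
    region_base_tags: float = 40.0
    region_down_fold: float = 4.0
    p_region_down: float = 0.30
    chip_library_size: float = 1e7
    # viability / synergy model
    doses_tki: tuple = (0.0, 1.0, 3.0, 10.0)
    doses_cbpi: tuple = (0.0, 50.0, 150.0, 500.0)
    ic50_tki: float = 3.0
    ic50_cbpi: float = 150.0
    planted_bliss_excess: float = 0.15
    viability_noise_sd: float = 0.005

    def validate(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        for name in ("base_log2_sd", "rep_log2_sd", "score_noise_sd", "jitter_sd",
                     "viability_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Everything planted, keyed the way the pipeline reports it."""

    gene_class: dict            # gene_id -> planted promoter class
    sensitive: set              # genes responsive to the CBP/P300 inhibitor
    ph_up: set                  # disease-upregulated genes
    ph_down: set                # disease-downregulated genes
    tki_down: set               # kinase-inhibitor-downregulated genes
    sample_groups: dict         # sample -> group label
    group_specific_ids: dict    # group -> set of interaction ids
    planted_core_ids: set       # gene-anchored ids present in every group-1 sample
    differential_down_regions: set  # region names with planted H3K27ac loss
    dead_oe_genes: set          # NO_ACTIVE_OE genes that do have an interaction
    planted_bliss: dict         # plate name -> planted mean excess (x100)
    loop_rates: dict            # gene -> (rate in group 1, rate in group 2)


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genes: list                                  # (chrom, start, end, strand, id)
    peaks: dict                                  # condition -> sample -> [interval]
    pchic: dict                                  # sample -> [Interaction]
    hichip: dict                                 # sample -> [Interaction]
    hichip_library_sizes: dict
    expression: pd.DataFrame
    deg: dict                                    # contrast -> [DEGRecord]
    region_counts: pd.DataFrame                  # regions x chip samples (raw tags)
    chip_library_sizes: dict
    regions: list                                # scored enhancer regions
    viability: dict                              # plate -> DataFrame
    truth: GroundTruth


def _largest_remainder(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    raw = {k: v * n for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(pvals, method="bh")


def _deg_from_counts(
    expression: pd.DataFrame, cols_a: Sequence[str], cols_b: Sequence[str]
) -> list[DEGRecord]:
    """Welch t on log2 counts, BH-adjusted: contrast A over B."""
    a = np.log2(expression[list(cols_a)].to_numpy() + 1.0)
    b = np.log2(expression[list(cols_b)].to_numpy() + 1.0)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    padj = _bh_adjust(p)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    return [
        DEGRecord(gene_id=g, log2fc=float(l), padj=float(q))
        for g, l, q in zip(expression.index, lfc, padj)
    ]


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full in-memory study bundle (deterministic under seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    frag = config.frag_size
    n_frags_per_chrom = config.chrom_length_bp // frag
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]

    even_pool = [
        (c, i) for c in chroms for i in range(0, n_frags_per_chrom, 2)
    ]
    odd_pool = [
        (c, i) for c in chroms for i in range(1, n_frags_per_chrom, 2)
    ]
    if config.n_genes > len(even_pool):
        raise ValueError(
            "infeasible geometry: more genes than available promoter fragments"
        )
    rng.shuffle(even_pool)
    rng.shuffle(odd_pool)
    odd_cursor = [0]

    def take_odd(n: int) -> list[tuple[str, int]]:
        if odd_cursor[0] + n > len(odd_pool):
            raise ValueError(
                "infeasible geometry: enhancer fragment pool exhausted"
            )
        out = odd_pool[odd_cursor[0]: odd_cursor[0] + n]
        odd_cursor[0] += n
        return out

    def frag_interval(loc: tuple[str, int]) -> GenomicInterval:
        c, i = loc
        return GenomicInterval(c, i * frag, (i + 1) * frag)

    # --- genes, planted classes -------------------------------------------
    gene_locs = even_pool[: config.n_genes]
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    genes = []
    tss: dict[str, int] = {}
    gene_frag: dict[str, GenomicInterval] = {}
    for gid, loc in zip(gene_ids, gene_locs):
        c, i = loc
        start = i * frag
        t = start + frag // 2
        strand = "+" if rng.random() < 0.5 else "-"
        # transcript spans so that the TSS lands mid-fragment on either strand
        if strand == "+":
            genes.append((c, t, min(t + 20_000, config.chrom_length_bp), strand, gid))
        else:
            genes.append((c, max(0, t - 20_000), t + 1, strand, gid))
        tss[gid] = t
        gene_frag[gid] = frag_interval(loc)

    counts = _largest_remainder(config.class_fractions, config.n_genes)
    labels = [k for k, n in counts.items() for _ in range(n)]
    rng.shuffle(labels)
    gene_class = dict(zip(gene_ids, labels))

    # --- planted PCHi-C interactions --------------------------------------
    g1 = [f"PH{i + 1}" for i in range(config.n_samples_per_group)]
    g2 = [f"OT{i + 1}" for i in range(config.n_samples_per_group)]
    sample_groups = {s: "group1" for s in g1} | {s: "group2" for s in g2}

    enhancer_frags: list[GenomicInterval] = []  # peaked, planted EPI other ends
    planted: list[tuple[Interaction, str]] = []  # template interaction (sample-free)
    dead_oe_genes: set[str] = set()
    dead_ids: set[str] = set()
    epi_oe_of_gene: dict[str, GenomicInterval] = {}

    ppi_partner_pool = list(gene_ids)
    planted_ids: set[str] = set()
    for gid in gene_ids:
        cls = gene_class[gid]
        bait = gene_frag[gid]
        if cls in ("EPI_ONLY", "EPI_AND_PPI"):
            oe = frag_interval(take_odd(1)[0])
            enhancer_frags.append(oe)
            epi_oe_of_gene[gid] = oe
            it = Interaction(bait, oe, sample="", score=0.0,
                             end_roles=("bait", "other_end"))
            planted_ids.add(it.id)
            planted.append((it, gid))
        if cls in ("PPI_ONLY", "EPI_AND_PPI"):
            # resample partners whose unordered pair is already planted —
            # reciprocal X-Y / Y-X pairs share one canonical id and would
            # collapse in deduplication, silently unplanting one gene's PPI
            while True:
                partner = ppi_partner_pool[int(rng.integers(len(ppi_partner_pool)))]
                if partner == gid:
                    continue
                it = Interaction(bait, gene_frag[partner], sample="", score=0.0,
                                 end_roles=("bait", "other_end"))
                if it.id not in planted_ids:
                    break
            planted_ids.add(it.id)
            planted.append((it, gid))
        if cls == "NO_ACTIVE_OE" and rng.random() < 0.5:
            oe = frag_interval(take_odd(1)[0])  # stays peakless
            dead_oe_genes.add(gid)
            it = Interaction(bait, oe, sample="", score=0.0,
                             end_roles=("bait", "other_end"))
            dead_ids.add(it.id)
            planted.append((it, gid))

    used_ids = {it.id for it, _ in planted}

    def draw_pairs(n: int) -> list[tuple[GenomicInterval, GenomicInterval]]:
        out = []
        while len(out) < n:
            a, b = take_odd(2)
            e1, e2 = frag_interval(a), frag_interval(b)
            it_id = Interaction(e1, e2, sample="").id
            if it_id in used_ids:
                continue
            used_ids.add(it_id)
            out.append((e1, e2))
        return out

    group_specific = {
        "group1": draw_pairs(config.n_group_specific),
        "group2": draw_pairs(config.n_group_specific),
    }
    background = draw_pairs(config.n_shared_background)

    base_score = {
        it.id: float(rng.uniform(config.score_base_low, config.score_base_high))
        for it, _ in planted
    }
    for pairs in (*group_specific.values(), background):
        for e1, e2 in pairs:
            base_score[Interaction(e1, e2, sample="").id] = float(
                rng.uniform(config.score_base_low, config.score_base_high)
            )

    def noisy(mu: float) -> float:
        return max(5.0, mu + rng.normal(0.0, config.score_noise_sd))

    pchic: dict[str, list[Interaction]] = {}
    for sample in g1 + g2:
        rows: list[Interaction] = []
        if sample_groups[sample] == "group1":
            for it, _gid in planted:
                rows.append(
                    Interaction(it.end1, it.end2, sample=sample,
                                score=noisy(base_score[it.id]),
                                raw_count=int(rng.poisson(20) + 1),
                                end_roles=("bait", "other_end"))
                )
        for e1, e2 in group_specific[sample_groups[sample]]:
            mu = config.group_score_shift + base_score[
                Interaction(e1, e2, sample="").id
            ]
            rows.append(Interaction(e1, e2, sample=sample, score=noisy(mu),
                                    raw_count=int(rng.poisson(20) + 1),
                                    end_roles=("bait", "other_end")))
        for e1, e2 in background:
            rows.append(
                Interaction(e1, e2, sample=sample,
                            score=noisy(base_score[Interaction(e1, e2, sample="").id]),
                            raw_count=int(rng.poisson(20) + 1),
                            end_roles=("bait", "other_end"))
            )
        for e1, e2 in draw_pairs(config.n_noise_per_sample):
            rows.append(Interaction(e1, e2, sample=sample,
                                    score=float(rng.uniform(5.0, 8.0)),
                                    raw_count=int(rng.poisson(10) + 1),
                                    end_roles=("bait", "other_end")))
        for e1, e2 in draw_pairs(config.n_subthreshold):
            rows.append(Interaction(e1, e2, sample=sample,
                                    score=float(rng.uniform(0.5, 4.9)),
                                    raw_count=int(rng.poisson(3) + 1),
                                    end_roles=("bait", "other_end")))
        pchic[sample] = rows

    # class-qualified core: the planted EPIs/PPIs, not the peakless dead ends
    planted_core_ids = {it.id for it, _ in planted} - dead_ids

    # --- peaks per condition/sample ---------------------------------------
    def jitter(x: int) -> int:
        if config.jitter_sd == 0:
            return x
        return max(0, int(round(x + rng.normal(0.0, config.jitter_sd))))

    hw = config.peak_halfwidth
    conditions = {"dmso": [f"dmso_{i + 1}" for i in range(3)],
                  "tki": [f"tki_{i + 1}" for i in range(3)]}
    # TKI removes enhancer peaks of disease-driven, inhibitor-reversed genes
    ph_up = set(
        gid for gid in gene_ids if rng.random() < config.p_ph_up
    )
    ph_down = {
        gid for gid in gene_ids
        if gid not in ph_up and rng.random() < config.p_ph_down
    }
    # iterate gene_ids (stable order), never sets, so draws map to the same
    # genes in every process
    tki_down = set()
    for gid in gene_ids:
        if gid in ph_up:
            if rng.random() < config.p_tki_reversal:
                tki_down.add(gid)
        elif rng.random() < config.p_tki_off_target:
            tki_down.add(gid)
    lost_enhancer_genes = {
        g for g in (ph_up & tki_down) if g in epi_oe_of_gene
    }
    peaks: dict[str, dict[str, list[GenomicInterval]]] = {}
    for cond, samples in conditions.items():
        peaks[cond] = {}
        for sample in samples:
            rows = []
            for gid in gene_ids:
                c = jitter(tss[gid])
                rows.append(GenomicInterval(gene_frag[gid].chrom, max(0, c - hw),
                                            c + hw, name=f"prom_{gid}"))
            for gid, oe in epi_oe_of_gene.items():
                if cond == "tki" and gid in lost_enhancer_genes:
                    continue
                c = jitter((oe.start + oe.end) // 2)
                rows.append(GenomicInterval(oe.chrom, max(0, c - hw), c + hw,
                                            name=f"enh_{gid}"))
            peaks[cond][sample] = sorted(rows)

    # --- expression and DEG tables ----------------------------------------
    epi_plus = {g for g, c in gene_class.items() if c in ("EPI_ONLY", "EPI_AND_PPI")}
    sensitive = {
        g for g in gene_ids
        if rng.random() < (config.p_sensitive_epi if g in epi_plus
                           else config.p_sensitive_non_epi)
    }
    base = rng.normal(config.base_log2_mean, config.base_log2_sd, config.n_genes)
    base = base + np.array(
        [config.epi_boost_log2 if g in epi_plus else 0.0 for g in gene_ids]
    )
    cols = {}
    for cond_name, effect in (
        ("healthy", {g: -config.ph_effect_log2 for g in ph_up}
                    | {g: config.ph_effect_log2 for g in ph_down}),
        ("dmso", {}),
        ("drug", {g: config.drug_effect_log2 for g in sensitive}),
        ("tki", {g: config.tki_effect_log2 for g in tki_down}),
    ):
        shift = np.array([effect.get(g, 0.0) for g in gene_ids])
        for rep in range(config.n_reps):
            noise = rng.normal(0.0, config.rep_log2_sd, config.n_genes)
            cols[f"{cond_name}_{rep + 1}"] = np.power(2.0, base + shift + noise)
    expression = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    rep_cols = lambda c: [f"{c}_{i + 1}" for i in range(config.n_reps)]
    deg = {
        "ph_vs_healthy": _deg_from_counts(expression, rep_cols("dmso"),
                                          rep_cols("healthy")),
        "drug_vs_dmso": _deg_from_counts(expression, rep_cols("drug"),
                                         rep_cols("dmso")),
        "tki_vs_dmso": _deg_from_counts(expression, rep_cols("tki"),
                                        rep_cols("dmso")),
    }

    # --- HiChIP loops -------------------------------------------------------
    loop_rates = {}
    for gid in gene_ids:
        if gid in ph_up:
            loop_rates[gid] = (config.ph_loop_rate, config.ph_depleted_rate)
        elif gid in ph_down:
            loop_rates[gid] = (config.ph_depleted_rate, config.ph_loop_rate)
        else:
            loop_rates[gid] = (config.base_loop_rate, config.base_loop_rate)
    odd_all = [
        (c, i) for c in chroms for i in range(1, n_frags_per_chrom, 2)
    ]
    hichip: dict[str, list[Interaction]] = {}
    hichip_library_sizes = {}
    for sample in g1 + g2:
        rate_idx = 0 if sample_groups[sample] == "group1" else 1
        loops: list[Interaction] = []
        for gid in gene_ids:
            k = int(rng.poisson(loop_rates[gid][rate_idx]))
            if k == 0:
                continue
            # anchors drawn with replacement across genes (the HiChIP anchor
            # pool is shared), without replacement within one gene's loops
            picks = rng.choice(len(odd_all), size=min(k, len(odd_all)),
                               replace=False)
            for idx in picks:
                loops.append(
                    Interaction(gene_frag[gid], frag_interval(odd_all[int(idx)]),
                                sample=sample, raw_count=int(rng.poisson(4) + 1))
                )
        # a few promoter-promoter and enhancer-enhancer loops for class variety
        for _ in range(5):
            ga, gb = rng.choice(config.n_genes, size=2, replace=False)
            loops.append(Interaction(gene_frag[gene_ids[int(ga)]],
                                     gene_frag[gene_ids[int(gb)]], sample=sample,
                                     raw_count=int(rng.poisson(4) + 1)))
            ea, eb = rng.choice(len(odd_all), size=2, replace=False)
            loops.append(Interaction(frag_interval(odd_all[int(ea)]),
                                     frag_interval(odd_all[int(eb)]), sample=sample,
                                     raw_count=int(rng.poisson(4) + 1)))
        hichip[sample] = loops
        hichip_library_sizes[sample] = config.hichip_library_size

    # --- differential H3K27ac regions --------------------------------------
    regions = []
    region_down = set()
    for gid, oe in sorted(epi_oe_of_gene.items()):
        mid = (oe.start + oe.end) // 2
        region = GenomicInterval(oe.chrom, mid - 250, mid + 250, name=f"enh_{gid}")
        regions.append(region)
        if rng.random() < config.p_region_down:
            region_down.add(region.name)
    chip_samples = conditions["dmso"] + conditions["tki"]
    counts_rows = {}
    for region in regions:
        mus = []
        for sample in chip_samples:
            mu = config.region_base_tags
            if sample.startswith("tki") and region.name in region_down:
                mu = mu / config.region_down_fold
            mus.append(rng.poisson(mu))
        counts_rows[region.name] = mus
    region_counts = pd.DataFrame.from_dict(
        counts_rows, orient="index", columns=chip_samples
    ).rename_axis("region")
    chip_library_sizes = {s: config.chip_library_size for s in chip_samples}

    # --- viability plates ---------------------------------------------------
    viability = {}
    planted_bliss = {}
    for plate, excess in (("combo_synergistic", config.planted_bliss_excess),
                          ("combo_additive", 0.0)):
        grid = pd.DataFrame(index=list(config.doses_tki),
                            columns=list(config.doses_cbpi), dtype=float)
        for da in config.doses_tki:
            ya = da / (da + config.ic50_tki) if da > 0 else 0.0
            for db in config.doses_cbpi:
                yb = db / (db + config.ic50_cbpi) if db > 0 else 0.0
                v = (1 - ya) * (1 - yb)
                if da > 0 and db > 0:
                    v -= excess
                v += rng.normal(0.0, config.viability_noise_sd)
                grid.loc[da, db] = float(np.clip(v, 0.0, 1.0))
        viability[plate] = grid
        planted_bliss[plate] = excess * 100.0

    truth = GroundTruth(
        gene_class=gene_class,
        sensitive=sensitive,
        ph_up=ph_up,
        ph_down=ph_down,
        tki_down=tki_down,
        sample_groups=sample_groups,
        group_specific_ids={
            g: {Interaction(a, b, sample="").id for a, b in pairs}
            for g, pairs in group_specific.items()
        },
        planted_core_ids=planted_core_ids,
        differential_down_regions=region_down,
        dead_oe_genes=dead_oe_genes,
        planted_bliss=planted_bliss,
        loop_rates=loop_rates,
    )
    return SyntheticBundle(
        config=config,
        genes=genes,
        peaks=peaks,
        pchic=pchic,
        hichip=hichip,
        hichip_library_sizes=hichip_library_sizes,
        expression=expression,
        deg=deg,
        region_counts=region_counts,
        chip_library_sizes=chip_library_sizes,
        regions=regions,
        viability=viability,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict:
    """Write every bundle table in its on-disk dialect; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": bundle.config.seed,
        "config_hash": bundle.config.hash(),
        "files": {},
    }

    def record(key: str, path: Path) -> Path:
        manifest["files"][key] = str(path.relative_to(outdir))
        return path

    with open(record("genes", outdir / "genes.tsv"), "w", encoding="utf-8") as fh:
        fh.write("chrom\tstart\tend\tstrand\tgene_id\n")
        for c, s, e, st, gid in bundle.genes:
            fh.write(f"{c}\t{s}\t{e}\t{st}\t{gid}\n")
    for cond, samples in bundle.peaks.items():
        for sample, ivs in samples.items():
            write_bed(ivs, record(f"peaks/{cond}/{sample}",
                                  outdir / f"peaks_{cond}_{sample}.bed"))
    for sample, rows in bundle.pchic.items():
        write_interactions_ibed(
            rows, record(f"pchic/{sample}", outdir / f"pchic_{sample}.ibed")
        )
    for sample, rows in bundle.hichip.items():
        write_interactions_bedpe(
            rows, record(f"hichip/{sample}", outdir / f"hichip_{sample}.bedpe")
        )
    write_expression(bundle.expression,
                     record("expression", outdir / "expression.tsv"))
    for contrast, records in bundle.deg.items():
        write_deg(records, record(f"deg/{contrast}", outdir / f"deg_{contrast}.tsv"))
    bundle.region_counts.to_csv(
        record("region_counts", outdir / "region_counts.tsv"), sep="\t"
    )
    write_bed(bundle.regions, record("regions", outdir / "regions.bed"))
    for plate, grid in bundle.viability.items():
        grid.to_csv(record(f"viability/{plate}", outdir / f"viability_{plate}.tsv"),
                    sep="\t", index_label="dose_tki")
    manifest["hichip_library_sizes"] = bundle.hichip_library_sizes
    manifest["chip_library_sizes"] = bundle.chip_library_sizes
    manifest["sample_groups"] = bundle.truth.sample_groups
    truth_path = outdir / "ground_truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "gene_class": bundle.truth.gene_class,
                "sensitive": sorted(bundle.truth.sensitive),
                "ph_up": sorted(bundle.truth.ph_up),
                "ph_down": sorted(bundle.truth.ph_down),
                "tki_down": sorted(bundle.truth.tki_down),
                "group_specific_ids": {
                    g: sorted(v) for g, v in bundle.truth.group_specific_ids.items()
                },
                "planted_core_ids": sorted(bundle.truth.planted_core_ids),
                "differential_down_regions": sorted(
                    bundle.truth.differential_down_regions
                ),
                "dead_oe_genes": sorted(bundle.truth.dead_oe_genes),
                "planted_bliss": bundle.truth.planted_bliss,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    manifest["files"]["ground_truth"] = "ground_truth.json"
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def worked_example() -> SyntheticBundle:
    """A miniature fixed bundle (20 genes) for hand-checkable walkthroughs."""
    config = SyntheticConfig(
        seed=20_240_101,
        n_chroms=1,
        chrom_length_bp=2_000_000,
        frag_size=5_000,
        n_genes=20,
        p_ph_up=0.6,
        n_group_specific=6,
        n_shared_background=8,
        n_noise_per_sample=2,
        n_subthreshold=2,
    )
    return generate(config)
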