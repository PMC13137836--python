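"""Readers and writers for the pipeline's tabular dialects.

Every format decision lives here: BED3/6, CHiCAGO-style ibed, BEDPE with raw
loop counts, wide interaction-score matrices, expression/DEG tables and the
WashU longrange export (write-only). All files are tab-separated UTF-8 with
``#`` comment lines skipped; coordinates are BED 0-based half-open. A
converter flag handles 1-based annotation dialects at the boundary so nothing
downstream ever sees mixed conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "Interaction",
    "DEGRecord",
    "canonical_interaction_id",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "read_interactions_ibed",
    "write_interactions_ibed",
    "read_interactions_bedpe",
    "write_interactions_bedpe",
    "read_peak_matrix",
    "write_peak_matrix",
    "read_expression",
    "write_expression",
    "read_deg",
    "write_deg",
    "write_washu_longrange",
]


def canonical_interaction_id(end1: GenomicInterval, end2: GenomicInterval) -> str:
    """Order-invariant key for a two-ended contact.

    The two ends are sorted lexicographically by (chrom, start, end) so the
    same fragment pair yields the same id regardless of row orientation.
    """
    k1 = (end1.chrom, end1.start, end1.end)
    k2 = (end2.chrom, end2.start, end2.end)
    a, b = sorted([k1, k2])
    return f"{a[0]}:{a[1]}-{a[2]}|{b[0]}:{b[1]}-{b[2]}"


@dataclass
class Interaction:
    """A two-ended chromatin contact with score/count and per-end annotations.

    ``score`` follows the CHiCAGO convention for promoter-capture Hi-C and the
    per-10M-normalized count for HiChIP; ``raw_count`` is the unnormalized
    read support where the format carries one. ``end_roles`` tags capture
    asymmetry (bait vs other end) and is absent for symmetric HiChIP loops.
    """

    end1: GenomicInterval
    end2: GenomicInterval
    sample: str
    score: float | None = None
    raw_count: int | None = None
    end_roles: tuple[str, str] | None = None
    id: str = field(default="", compare=False)
    # filled by interaction_classify.annotate_ends / classify_interactions
    ann1: object | None = field(default=None, compare=False, repr=False)
    ann2: object | None = field(default=None, compare=False, repr=False)
    activity_class: str | None = field(default=None, compare=False)
    regulatory_class: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValueError(f"interaction score must be >= 0, got {self.score}")
        if self.raw_count is not None and self.raw_count < 0:
            raise ValueError(f"raw_count must be >= 0, got {self.raw_count}")
        if not self.id:
            self.id = canonical_interaction_id(self.end1, self.end2)

    @property
    def bait(self) -> GenomicInterval:
        if self.end_roles is None:
            raise ValueError("interaction has no bait/other_end role tags")
        return self.end1 if self.end_roles[0] == "bait" else self.end2

    @property
    def other_end(self) -> GenomicInterval:
        if self.end_roles is None:
            raise ValueError("interaction has no bait/other_end role tags")
        return self.end2 if self.end_roles[0] == "bait" else self.end1


@dataclass(frozen=True)
class DEGRecord:
    """One row of a differential-expression table."""

    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError(
                f"padj for {self.gene_id} must be in [0, 1], got {self.padj}"
            )

    @property
    def direction(self) -> str:
        if self.log2fc > 0:
            return "up"
        if self.log2fc < 0:
            return "down"
        return "none"


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (half-open, as on disk)."""
    out: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed BED row") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = (
            float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else None
        )
        strand = fields[5] if len(fields) > 5 else "."
        out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                cols += [
                    iv.name if iv.name is not None else ".",
                    f"{iv.score:g}" if iv.score is not None else ".",
                    iv.strand,
                ]
            handle.write("\t".join(cols) + "\n")


def read_gene_table(path: str | Path, one_based: bool = False):
    """Read a gene/transcript table: chrom, start, end, strand, gene_id.

    ``one_based=True`` converts 1-based inclusive starts (GTF-lite dialects)
    to the internal 0-based half-open convention.
    """
    records = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 5:
            raise ValueError(f"{path}:{lineno}: gene table needs >= 5 columns")
        if fields[1] in ("start", "txStart"):  # header
            continue
        chrom, start, end, strand, gene_id = (
            fields[0],
            int(fields[1]),
            int(fields[2]),
            fields[3],
            fields[4],
        )
        if one_based:
            start -= 1
        records.append((chrom, start, end, strand, gene_id))
    return records


# ---------------------------------------------------------------------------
# ibed (CHiCAGO convention)

_IBED_COLUMNS = [
    "bait_chr",
    "bait_start",
    "bait_end",
    "bait_name",
    "otherEnd_chr",
    "otherEnd_start",
    "otherEnd_end",
    "otherEnd_name",
    "N_reads",
    "score",
]


def read_interactions_ibed(
    path: str | Path, sample: str, min_score: float = 5.0
) -> list[Interaction]:
    """Read a 10-column ibed file, keeping rows with score >= ``min_score``.

    The score-5 significance convention is inclusive, matching the upstream
    caller's own output. End 1 is always the bait.
    """
    out: list[Interaction] = []
    saw_rows = False
    for lineno, fields in _data_lines(path):
        if len(fields) != 10:
            raise ValueError(
                f"{path}:{lineno}: ibed rows must have 10 columns, got {len(fields)}"
            )
        if fields[0] == "bait_chr":  # header
            continue
        saw_rows = True
        try:
            bait = GenomicInterval(
                fields[0], int(fields[1]), int(fields[2]), name=fields[3]
            )
            oe = GenomicInterval(
                fields[4], int(fields[5]), int(fields[6]), name=fields[7]
            )
            n_reads = int(fields[8])
            score = float(fields[9])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed ibed row") from exc
        if score < min_score:
            continue
        out.append(
            Interaction(
                end1=bait,
                end2=oe,
                sample=sample,
                score=score,
                raw_count=n_reads,
                end_roles=("bait", "other_end"),
            )
        )
    if not saw_rows:
        warnings.warn(f"{path}: no interaction rows found", stacklevel=2)
    return out


def write_interactions_ibed(
    interactions: Iterable[Interaction], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(_IBED_COLUMNS) + "\n")
        for it in interactions:
            bait, oe = it.bait, it.other_end
            handle.write(
                "\t".join(
                    [
                        bait.chrom,
                        str(bait.start),
                        str(bait.end),
                        bait.name or ".",
                        oe.chrom,
                        str(oe.start),
                        str(oe.end),
                        oe.name or ".",
                        str(it.raw_count if it.raw_count is not None else 0),
                        f"{it.score:g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BEDPE (HiChIP loops with raw counts)


def read_interactions_bedpe(path: str | Path, sample: str) -> list[Interaction]:
    """Read BEDPE loops; the last column is the raw read count.

    Scores are left unset — per-10M normalization against the sample's library
    size is a separate, explicit step.
    """
    out: list[Interaction] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 7:
            raise ValueError(
                f"{path}:{lineno}: BEDPE needs chrom1,start1,end1,chrom2,"
                f"start2,end2,...,count (>= 7 columns), got {len(fields)}"
            )
        if fields[1] in ("start1",):  # header
            continue
        try:
            end1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            end2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            raw_count = int(fields[-1])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: malformed BEDPE row (count must be the "
                "final integer column)"
            ) from exc
        out.append(Interaction(end1=end1, end2=end2, sample=sample, raw_count=raw_count))
    return out


def write_interactions_bedpe(
    interactions: Iterable[Interaction], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for it in interactions:
            handle.write(
                "\t".join(
                    [
                        it.end1.chrom,
                        str(it.end1.start),
                        str(it.end1.end),
                        it.end2.chrom,
                        str(it.end2.start),
                        str(it.end2.end),
                        str(it.raw_count if it.raw_count is not None else 0),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# wide interaction-score matrix (peak matrix)

_MATRIX_COORD_COLS = ["chr1", "start1", "end1", "chr2", "start2", "end2"]


def read_peak_matrix(path: str | Path) -> pd.DataFrame:
    """Read a wide interaction x sample score matrix.

    Layout: six coordinate columns (both ends), then one score column per
    sample. Absent scores are NA on disk and stay NaN in memory — distinct
    from an observed 0; the fill policy belongs to the signatures stage.
    Rows are indexed by the canonical interaction id; duplicates are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _MATRIX_COORD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: peak matrix missing columns {missing}")
    ids = [
        canonical_interaction_id(
            GenomicInterval(r.chr1, r.start1, r.end1),
            GenomicInterval(r.chr2, r.start2, r.end2),
        )
        for r in df.itertuples()
    ]
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
        raise ValueError(f"{path}: duplicate interaction rows: {list(dupes)[:5]}")
    samples = [c for c in df.columns if c not in _MATRIX_COORD_COLS]
    out = df[samples].copy()
    out.index = pd.Index(ids, name="interaction_id")
    return out.astype(float)


def write_peak_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a score matrix whose index holds canonical interaction ids."""
    rows = []
    for iid in matrix.index:
        ends = []
        for token in iid.split("|"):
            chrom, span = token.rsplit(":", 1)
            start, end = span.split("-")
            ends.append((chrom, int(start), int(end)))
        rows.append(ends[0] + ends[1])
    coords = pd.DataFrame(rows, columns=_MATRIX_COORD_COLS, index=matrix.index)
    pd.concat([coords, matrix], axis=1).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression / DEG tables


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a normalized-count table, genes x samples, indexed by gene_id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: expression table needs a gene_id column")
    dup = df[df.duplicated("gene_id", keep=False)]
    if not dup.empty:
        if dup.groupby("gene_id").nunique().to_numpy().max() > 1:
            raise ValueError(f"{path}: conflicting rows for duplicated gene_id")
        df = df.drop_duplicates("gene_id")
    df = df.set_index("gene_id")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression values") from exc
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression counts")
    return df


def write_expression(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_deg(path: str | Path) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene_id", "log2fc", "padj"):
        if col not in df.columns:
            raise ValueError(f"{path}: DEG table needs a {col} column")
    dup = df[df.duplicated("gene_id", keep=False)]
    if not dup.empty:
        if dup.groupby("gene_id").nunique().to_numpy().max() > 1:
            raise ValueError(f"{path}: conflicting rows for duplicated gene_id")
        df = df.drop_duplicates("gene_id")
    return [
        DEGRecord(gene_id=str(r.gene_id), log2fc=float(r.log2fc), padj=float(r.padj))
        for r in df.itertuples()
    ]


def write_deg(records: Sequence[DEGRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "padj": [r.padj for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# WashU longrange (write-only browser export)


def write_washu_longrange(
    interactions: Iterable[Interaction], path: str | Path
) -> None:
    """Export contacts as WashU longrange text (never re-imported)."""
    with open(path, "w", encoding="utf-8") as handle:
        for it in interactions:
            score = it.score if it.score is not None else 0.0
            handle.write(
                f"{it.end1.chrom}\t{it.end1.start}\t{it.end1.end}\t"
                f"{it.end2.chrom}:{it.end2.start}-{it.end2.end},{score:g}\n"
            )
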