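"""Genomic interval algebra on BED-style half-open coordinates.

Everything downstream — peak/promoter overlap, peak merging, consensus
differential regions — reduces to the small set of operations here, all on
0-based half-open ``[start, end)`` spans. Strand is carried but never used for
overlap; it only places the transcription start site when promoter windows are
built.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "PromoterRecord",
    "make_promoter_windows",
    "overlaps",
    "merge_within_gap",
    "consensus_regions",
    "presence_absence_differential",
    "normalize_chrom_name",
]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive, so width is
    ``end - start`` and two intervals touch without overlapping when one ends
    where the other begins.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . — got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # used for canonical ids
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class PromoterRecord:
    """A TSS with its flanking window and (later-assigned) activity state."""

    gene_id: str
    tss: int
    strand: str
    window: GenomicInterval
    active: bool = False


def normalize_chrom_name(chrom: str) -> str:
    """Map 'chr1' and '1' dialects to a common 'chr1' form.

    Off by default everywhere; silent aliasing of chromosome names corrupts
    overlap counts, so callers must opt in explicitly.
    """
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def make_promoter_windows(
    annotation: Iterable[tuple[str, int, int, str, str]],
    flank: int = 1000,
) -> list[PromoterRecord]:
    """Build +/-``flank`` bp promoter windows around each record's TSS.

    ``annotation`` yields ``(chrom, txStart, txEnd, strand, gene_id)`` with
    0-based half-open transcript coordinates. The TSS is ``txStart`` on the
    plus strand and ``txEnd - 1`` on the minus strand; the window is
    ``[tss - flank, tss + flank)`` clipped at position 0. Duplicate identical
    windows for the same gene collapse to one record.
    """
    seen: set[tuple[str, str, int, int]] = set()
    records: list[PromoterRecord] = []
    for rec in annotation:
        chrom, tx_start, tx_end, strand, gene_id = rec
        if tx_start < 0 or tx_end <= tx_start:
            raise ValueError(
                f"invalid transcript coordinates for {gene_id}: "
                f"{chrom}:{tx_start}-{tx_end}"
            )
        if strand == "+":
            tss = tx_start
        elif strand == "-":
            tss = tx_end - 1
        else:
            raise ValueError(f"unknown strand {strand!r} for {gene_id}")
        win_start = max(0, tss - flank)
        win_end = tss + flank
        key = (gene_id, chrom, win_start, win_end)
        if key in seen:
            continue
        seen.add(key)
        records.append(
            PromoterRecord(
                gene_id=gene_id,
                tss=tss,
                strand=strand,
                window=GenomicInterval(chrom, win_start, win_end, strand, name=gene_id),
            )
        )
    return records


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share >= 1 bp (same chrom, half-open)."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def _sorted_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge_within_gap(
    intervals: Iterable[GenomicInterval], gap: int = 1000
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= ``gap`` bp (bedtools merge -d semantics).

    Output is sorted, pairwise separated by more than ``gap`` bp, and covers
    exactly the union of the inputs (merging is transitive, so chains of
    near-neighbours collapse into one span).
    """
    merged: list[GenomicInterval] = []
    by_chrom = _sorted_by_chrom(intervals)
    for chrom in sorted(by_chrom):
        cur_start: int | None = None
        cur_end = 0
        for iv in by_chrom[chrom]:
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start <= cur_end + gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def consensus_regions(
    per_sample: Sequence[Iterable[GenomicInterval]],
    require_all: bool = True,
) -> list[GenomicInterval]:
    """Maximal sub-intervals covered by every sample (bedtools multiinter style).

    Coverage is resolved at bp resolution by an event sweep over each sample's
    merged footprint. With ``require_all=False`` the union of all samples'
    footprints is returned instead.
    """
    samples = [list(s) for s in per_sample]
    if len(samples) == 0:
        raise ValueError("consensus_regions requires a non-empty sample set")
    if len(samples) < 2:
        raise ValueError("consensus_regions requires >= 2 samples")
    need = len(samples) if require_all else 1
    # Merge each sample first so one sample never counts a base twice.
    footprints = [merge_within_gap(s, gap=0) for s in samples]
    events: dict[str, list[tuple[int, int]]] = {}
    for fp in footprints:
        for iv in fp:
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        depth = 0
        seg_start: int | None = None
        for pos, delta in sorted(events[chrom]):
            prev_depth = depth
            depth += delta
            if prev_depth < need <= depth:
                seg_start = pos
            elif prev_depth >= need > depth and seg_start is not None:
                if pos > seg_start:
                    out.append(GenomicInterval(chrom, seg_start, pos))
                seg_start = None
    # Adjacent qualifying segments can abut when events coincide; re-merge at gap 0.
    return merge_within_gap(out, gap=0)


class _OverlapLookup:
    """Per-chrom sorted starts with prefix-max ends for O(log n) any-overlap."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, ivs in _sorted_by_chrom(intervals).items():
            starts = [iv.start for iv in ivs]
            prefix_max_end: list[int] = []
            running = 0
            for iv in ivs:
                running = max(running, iv.end)
                prefix_max_end.append(running)
            self._by_chrom[chrom] = (starts, prefix_max_end)

    def any_overlap(self, iv: GenomicInterval) -> bool:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, prefix_max_end = entry
        # candidates: intervals starting before iv.end
        k = bisect_left(starts, iv.end)
        return k > 0 and prefix_max_end[k - 1] > iv.start


def presence_absence_differential(
    reference_peaks: Iterable[GenomicInterval],
    treatment_peaks: Iterable[GenomicInterval],
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Peaks unique to each condition by >=1 bp overlap (intersect -v logic).

    Returns ``(lost, gained)``: reference peaks with no treatment overlap, and
    treatment peaks with no reference overlap.
    """
    ref = list(reference_peaks)
    treat = list(treatment_peaks)
    treat_lookup = _OverlapLookup(treat)
    ref_lookup = _OverlapLookup(ref)
    lost = [iv for iv in ref if not treat_lookup.any_overlap(iv)]
    gained = [iv for iv in treat if not ref_lookup.any_overlap(iv)]
    return lost, gained
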