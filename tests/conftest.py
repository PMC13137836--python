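"""Shared fixtures: synthetic study bundles and interval oracles.

All fixtures are generated programmatically at test time; nothing is read
from checked-in data files.
"""

from __future__ import annotations

import random

import pytest

from epilink.intervals import GenomicInterval
from epilink.pipeline import run_all
from epilink.simulate import SyntheticConfig, generate, worked_example


@pytest.fixture(scope="session")
def default_bundle():
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_results(default_bundle):
    return run_all(default_bundle)


@pytest.fixture(scope="session")
def mini_bundle():
    return worked_example()


# ---------------------------------------------------------------------------
# per-base oracles for interval algebra


def rasterize(intervals) -> set[tuple[str, int]]:
    """Explicit base-pair set covered by a collection of intervals."""
    covered = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            covered.add((iv.chrom, pos))
    return covered


def oracle_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return bool(rasterize([a]) & rasterize([b]))


def oracle_merge_within_gap(intervals, gap: int):
    """Union-then-dilate oracle: dilate each interval rightward by gap (so two
    intervals connect iff their gap is <= gap), take the covered base set,
    extract runs, then trim the dilation back."""
    dilated = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end + gap):
            dilated.add((iv.chrom, pos))
    true_cov = rasterize(intervals)
    runs = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in dilated:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        start = prev = positions[0]
        for pos in positions[1:] + [None]:
            if pos is None or pos != prev + 1:
                # trim to the true covered extremes inside this run
                inside = [
                    p for p in range(start, prev + 1) if (chrom, p) in true_cov
                ]
                if inside:
                    runs.append(GenomicInterval(chrom, inside[0], inside[-1] + 1))
                if pos is not None:
                    start = pos
            if pos is not None:
                prev = pos
    return runs


def oracle_consensus(per_sample, n_required: int):
    """Coverage-count oracle at base resolution."""
    sample_sets = [rasterize(s) for s in per_sample]
    counts: dict[tuple[str, int], int] = {}
    for cov in sample_sets:
        for key in cov:
            counts[key] = counts.get(key, 0) + 1
    qualifying = {k for k, v in counts.items() if v >= n_required}
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in qualifying:
        by_chrom.setdefault(chrom, []).append(pos)
    out = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        start = prev = positions[0]
        for pos in positions[1:] + [None]:
            if pos is None or pos != prev + 1:
                out.append(GenomicInterval(chrom, start, prev + 1))
                if pos is not None:
                    start = pos
            if pos is not None:
                prev = pos
    return out


def oracle_presence_absence(ref, treat):
    """All-pairs overlap oracle."""
    lost = [r for r in ref if not any(oracle_overlaps(r, t) for t in treat)]
    gained = [t for t in treat if not any(oracle_overlaps(t, r) for r in ref)]
    return lost, gained


def random_intervals(rng: random.Random, n: int, chroms=("chr1", "chr2"),
                     span: int = 3000, max_len: int = 120):
    out = []
    for _ in range(n):
        start = rng.randrange(0, span)
        out.append(
            GenomicInterval(
                rng.choice(list(chroms)), start, start + rng.randrange(1, max_len)
            )
        )
    return out
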