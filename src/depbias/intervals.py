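"""Genomic-interval algebra for loop and peak comparison.

Coordinates are 0-based half-open throughout (BED convention); two
intervals overlap iff they share the chromosome and at least one base.
A chromatin loop is a pair of same-chromosome anchor intervals; a test
loop is "shared" with a reference set when one single reference loop's
left anchor overlaps its left anchor AND that same loop's right anchor
overlaps its right anchor — otherwise it is "gained". Loop length is the
distance between anchor midpoints (resolution-robust for binned loop
calls; anchor-start distance is available as an alternative).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Loop",
    "LoopSet",
    "LoopClassification",
    "PeakVenn",
    "intervals_overlap",
    "classify_loops",
    "loop_length_stats",
    "peak_set_venn",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
]

LOOP_LABELS = ("shared", "gained", "control_only")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def expanded(self, slop: int) -> "GenomicInterval":
        if slop == 0:
            return self
        return GenomicInterval(self.chrom, max(0, self.start - slop), self.end + slop)


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """>=1 bp shared under half-open semantics; abutting intervals do not overlap."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


@dataclass(frozen=True)
class Loop:
    left: GenomicInterval
    right: GenomicInterval
    label: str | None = None

    def __post_init__(self) -> None:
        if self.left.chrom != self.right.chrom:
            raise ValueError(
                f"loop anchors on different chromosomes: {self.left.chrom} vs {self.right.chrom}"
            )
        if self.left.start > self.right.start:
            raise ValueError("left anchor must not start after right anchor")
        if self.label is not None and self.label not in LOOP_LABELS:
            raise ValueError(f"label {self.label!r} not in {LOOP_LABELS}")

    def length(self, method: Literal["midpoint", "start"] = "midpoint") -> float:
        if method == "midpoint":
            return self.right.midpoint - self.left.midpoint
        if method == "start":
            return float(self.right.start - self.left.start)
        raise ValueError(f"unknown length method {method!r}")


@dataclass
class LoopSet:
    name: str
    loops: list[Loop]

    def __post_init__(self) -> None:
        keys = [(l.left, l.right) for l in self.loops]
        if len(set(keys)) != len(keys):
            raise ValueError(f"loop set {self.name!r} contains duplicate anchor pairs")

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)


@dataclass
class LoopClassification:
    test: LoopSet  # every loop labeled shared/gained
    control_only: list[Loop]  # reference loops matched by no test loop
    counts: dict[str, int]


def classify_loops(
    test: LoopSet, reference: LoopSet, slop: int = 0
) -> LoopClassification:
    """Label every test loop shared or gained against a reference loop set.

    A test loop is shared iff some single reference loop overlaps it on
    both anchors (left-with-left and right-with-right). ``slop`` expands
    every anchor symmetrically before the overlap test (default 0: plain
    >=1 bp overlap). Reference loops never matched on both anchors by any
    test loop come back as the control_only subset.
    """
    # interval tree over reference left anchors, per chromosome
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    ref_loops = list(reference)
    for i, loop in enumerate(ref_loops):
        a = loop.left.expanded(slop)
        trees[a.chrom].addi(a.start, a.end, i)

    matched_ref: set[int] = set()
    labeled: list[Loop] = []
    n_shared = 0
    for loop in test:
        left = loop.left.expanded(slop)
        right = loop.right.expanded(slop)
        shared = False
        for hit in trees[left.chrom].overlap(left.start, left.end):
            ref = ref_loops[hit.data]
            if intervals_overlap(ref.right.expanded(slop), right):
                shared = True
                matched_ref.add(hit.data)
        labeled.append(replace(loop, label="shared" if shared else "gained"))
        n_shared += shared
    control_only = [
        replace(ref_loops[i], label="control_only")
        for i in range(len(ref_loops))
        if i not in matched_ref
    ]
    counts = {
        "shared": n_shared,
        "gained": len(labeled) - n_shared,
        "control_only": len(control_only),
    }
    return LoopClassification(
        test=LoopSet(name=test.name, loops=labeled),
        control_only=control_only,
        counts=counts,
    )


def loop_length_stats(
    s: LoopSet | Sequence[Loop], method: Literal["midpoint", "start"] = "midpoint"
) -> dict:
    """n, median and quartiles of loop lengths in bp."""
    loops = list(s)
    if not loops:
        raise ValueError("cannot compute length statistics of an empty loop set")
    lengths = np.array([l.length(method) for l in loops], dtype=float)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return {"n": len(lengths), "median": float(med), "q1": float(q1), "q3": float(q3), "lengths": lengths}


@dataclass
class PeakVenn:
    a_with_overlap: int
    a_only: int
    b_with_overlap: int
    b_only: int


def peak_set_venn(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> PeakVenn:
    """Directional peak-overlap counts for a two-set Venn.

    A peak in A "overlaps" if it overlaps >=1 peak in B, and symmetrically;
    with multi-overlaps the two directions may count differently, which is
    why both are reported.
    """
    trees_b: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in b:
        trees_b[p.chrom].addi(p.start, p.end)
    trees_a: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in a:
        trees_a[p.chrom].addi(p.start, p.end)
    a_hit = sum(bool(trees_b[p.chrom].overlap(p.start, p.end)) for p in a)
    b_hit = sum(bool(trees_a[p.chrom].overlap(p.start, p.end)) for p in b)
    return PeakVenn(
        a_with_overlap=a_hit,
        a_only=len(a) - a_hit,
        b_with_overlap=b_hit,
        b_only=len(b) - b_hit,
    )


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """3+ column BED; track/browser/comment lines skipped."""
    path = Path(path)
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
        try:
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: {e}") from e
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedpe(path: str | Path, name: str | None = None) -> LoopSet:
    """6+ column BEDPE; column 7 (if present) is kept as the loop label."""
    path = Path(path)
    loops: list[Loop] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: BEDPE line has <6 columns")
        try:
            left = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            right = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            label = fields[6] if len(fields) > 6 and fields[6] in LOOP_LABELS else None
            loops.append(Loop(left=left, right=right, label=label))
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: {e}") from e
    return LoopSet(name=name or path.stem, loops=loops)


def write_bedpe(s: LoopSet, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for l in s:
            row = [
                l.left.chrom, str(l.left.start), str(l.left.end),
                l.right.chrom, str(l.right.start), str(l.right.end),
            ]
            if l.label is not None:
                row.append(l.label)
            fh.write("\t".join(row) + "\n")
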