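"""Demultiplexing and exact-match guide counting for pooled-screen reads.

Amplicon reads follow a fixed layout::

    [stagger (variable-length filler)][sample barcode][anchor][protospacer][...]

The stagger is a per-sample run of arbitrary bases that diversifies
sequencing cycles; the anchor is the invariant vector sequence immediately
5' of the protospacer. A read is assigned to a sample by exact barcode
match at offset ``stagger_len``, and to a guide only if the bases
immediately after the anchor equal a library protospacer exactly — no
mismatches, no indels. Everything that fails either test is counted, never
silently dropped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .library_io import SgRNALibrary

__all__ = [
    "SampleSheet",
    "SampleSheetError",
    "CountMatrix",
    "QCReport",
    "read_sample_sheet",
    "read_fastq_sequences",
    "demultiplex",
    "count_guides",
    "quantify",
    "representation_qc",
]

TIMEPOINTS = ("initial", "final")

SHEET_COLUMNS = ("sample_id", "cell_line", "timepoint", "barcode", "stagger_len")


class SampleSheetError(ValueError):
    """Invalid sample sheet (duplicates, bad timepoint, ambiguous barcodes)."""


@dataclass(frozen=True)
class SheetRow:
    sample_id: str
    cell_line: str
    timepoint: str
    barcode: str
    stagger_len: int


@dataclass
class SampleSheet:
    """Per-sample demultiplexing metadata.

    Raises at construction if two samples' (stagger, barcode) patterns are
    mutually compatible, i.e. some read prefix would satisfy both — such a
    design cannot assign reads unambiguously.
    """

    rows: list[SheetRow]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise SampleSheetError("duplicate sample_id values in sample sheet")
        for r in self.rows:
            if r.timepoint not in TIMEPOINTS:
                raise SampleSheetError(
                    f"sample {r.sample_id}: timepoint {r.timepoint!r} not in {TIMEPOINTS}"
                )
            if r.stagger_len < 0:
                raise SampleSheetError(f"sample {r.sample_id}: negative stagger_len")
            if not r.barcode or set(r.barcode) - set("ACGT"):
                raise SampleSheetError(f"sample {r.sample_id}: barcode must be non-empty A/C/G/T")
        keys = [(r.barcode, r.stagger_len) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise SampleSheetError("duplicate (barcode, stagger_len) combination")
        for i, a in enumerate(self.rows):
            for b in self.rows[i + 1 :]:
                if _patterns_compatible(a, b):
                    raise SampleSheetError(
                        f"samples {a.sample_id} and {b.sample_id} have compatible "
                        "(stagger, barcode) patterns; a read could match both"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]

    def __iter__(self) -> Iterator[SheetRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def sample_for(self, cell_line: str, timepoint: str) -> SheetRow:
        hits = [r for r in self.rows if r.cell_line == cell_line and r.timepoint == timepoint]
        if len(hits) != 1:
            raise SampleSheetError(
                f"expected exactly one sample for ({cell_line}, {timepoint}), found {len(hits)}"
            )
        return hits[0]


def _patterns_compatible(a: SheetRow, b: SheetRow) -> bool:
    """True if one read prefix could carry both samples' barcodes."""
    constraints: dict[int, str] = {}
    for pos, base in enumerate(a.barcode, start=a.stagger_len):
        constraints[pos] = base
    for pos, base in enumerate(b.barcode, start=b.stagger_len):
        if constraints.get(pos, base) != base:
            return False
    return True


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SampleSheetError(f"{path}: sample sheet missing columns {missing}")
    rows = [
        SheetRow(
            sample_id=r.sample_id,
            cell_line=r.cell_line,
            timepoint=r.timepoint,
            barcode=r.barcode.upper(),
            stagger_len=int(r.stagger_len),
        )
        for r in df.itertuples()
    ]
    return SampleSheet(rows=rows)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(SHEET_COLUMNS) + "\n")
        for r in sheet:
            fh.write(f"{r.sample_id}\t{r.cell_line}\t{r.timepoint}\t{r.barcode}\t{r.stagger_len}\n")


@dataclass
class CountMatrix:
    """Guide x sample integer counts plus per-sample unassigned-read tallies.

    Invariant: per sample, ``counts[:, s].sum() + unassigned[s]`` equals the
    number of reads demultiplexed to that sample.
    """

    counts: pd.DataFrame  # index: guide_id, columns: sample_id, dtype int64
    unassigned: pd.Series  # index: sample_id

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.unassigned = self.unassigned.reindex(self.counts.columns).fillna(0).astype(int)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def guides(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.loc["__unassigned__"] = self.unassigned
        out.to_csv(path, sep="\t", index_label="guide_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="guide_id")
        if "__unassigned__" in df.index:
            unassigned = df.loc["__unassigned__"].astype(int)
            df = df.drop(index="__unassigned__")
        else:
            unassigned = pd.Series(0, index=df.columns)
        return cls(counts=df.astype(int), unassigned=unassigned)


def read_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences (upper-case) from a FASTQ file, gzip-transparent."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def demultiplex(
    reads: Iterable[str], sheet: SampleSheet
) -> tuple[dict[str, list[str]], int]:
    """Split reads by exact barcode match at each sample's stagger offset.

    Returns per-sample read lists plus the orphan count (reads matching no
    sample). The sheet's construction-time ambiguity check guarantees at
    most one sample can match any read.
    """
    by_sample: dict[str, list[str]] = {r.sample_id: [] for r in sheet}
    patterns = [(r.sample_id, r.stagger_len, r.barcode) for r in sheet]
    orphans = 0
    for read in reads:
        for sample_id, stagger, barcode in patterns:
            if read[stagger : stagger + len(barcode)] == barcode:
                by_sample[sample_id].append(read)
                break
        else:
            orphans += 1
    return by_sample, orphans


def count_guides(
    reads_by_sample: dict[str, Iterable[str]],
    lib: SgRNALibrary,
    anchor: str,
    sheet: SampleSheet | None = None,
    scan_all_offsets: bool = False,
) -> CountMatrix:
    """Exact-match protospacer counting per sample.

    The anchor is located at the expected offset (stagger + barcode length,
    from the sheet) or, with ``scan_all_offsets``, at the first position
    where it occurs. The bases immediately following the anchor must equal
    a library protospacer exactly; when one protospacer is a prefix of
    another, the longest match wins. Reads failing any step increment the
    sample's unassigned tally.
    """
    anchor = anchor.upper()
    if not anchor:
        raise ValueError("anchor must be non-empty")
    spacer_to_guide = lib.protospacer_to_guide()
    lengths = sorted({len(p) for p in spacer_to_guide}, reverse=True)
    offsets = {}
    if sheet is not None:
        offsets = {r.sample_id: r.stagger_len + len(r.barcode) for r in sheet}

    sample_ids = list(reads_by_sample)
    counts = pd.DataFrame(0, index=lib.guide_ids, columns=sample_ids, dtype="int64")
    unassigned = pd.Series(0, index=sample_ids, dtype="int64")
    for sample_id, reads in reads_by_sample.items():
        tally: dict[str, int] = {}
        miss = 0
        expected = offsets.get(sample_id)
        for read in reads:
            pos = _locate_anchor(read, anchor, expected, scan_all_offsets)
            guide = None
            if pos is not None:
                start = pos + len(anchor)
                for L in lengths:
                    candidate = read[start : start + L]
                    if len(candidate) == L and candidate in spacer_to_guide:
                        guide = spacer_to_guide[candidate]
                        break
            if guide is None:
                miss += 1
            else:
                tally[guide] = tally.get(guide, 0) + 1
        if tally:
            counts.loc[list(tally), sample_id] = list(tally.values())
        unassigned[sample_id] = miss
    return CountMatrix(counts=counts, unassigned=unassigned)


def _locate_anchor(
    read: str, anchor: str, expected_offset: int | None, scan_all_offsets: bool
) -> int | None:
    if expected_offset is not None and not scan_all_offsets:
        if read[expected_offset : expected_offset + len(anchor)] == anchor:
            return expected_offset
        return None
    pos = read.find(anchor)
    return pos if pos >= 0 else None


def quantify(
    reads: Iterable[str],
    sheet: SampleSheet,
    lib: SgRNALibrary,
    anchor: str,
    scan_all_offsets: bool = False,
) -> tuple[CountMatrix, int]:
    """Demultiplex then count; returns (matrix, orphan read count)."""
    by_sample, orphans = demultiplex(reads, sheet)
    cm = count_guides(by_sample, lib, anchor, sheet=sheet, scan_all_offsets=scan_all_offsets)
    return cm, orphans


@dataclass
class QCReport:
    per_sample: pd.DataFrame  # assigned, fold_representation, frac_zero_guides, frac_assigned, flagged
    threshold: float


def representation_qc(
    cm: CountMatrix, lib: SgRNALibrary, threshold: float = 1000.0
) -> QCReport:
    """Per-sample library-representation summary.

    fold_representation = assigned reads / number of guides; a screen is
    conventionally maintained at >=1000x so each guide's depletion is
    measured from ~thousands of cells.
    """
    n_guides = len(lib)
    assigned = cm.counts.sum(axis=0)
    total = assigned + cm.unassigned
    fold = assigned / n_guides
    frac_zero = (cm.counts == 0).sum(axis=0) / n_guides
    frac_assigned = (assigned / total.where(total > 0)).fillna(0.0)
    df = pd.DataFrame(
        {
            "assigned": assigned,
            "fold_representation": fold,
            "frac_zero_guides": frac_zero,
            "frac_assigned": frac_assigned,
            "flagged": fold < threshold,
        }
    )
    return QCReport(per_sample=df, threshold=threshold)
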