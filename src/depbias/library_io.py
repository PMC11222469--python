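"""sgRNA library manifest: model, read, write, validate.

A domain-focused CRISPR library is a flat table of guides. Each guide
targets either a gene (``targeting``), nothing in the genome
(``non_targeting``, used to calibrate the null depletion distribution), or
a pan-essential control gene (``positive_control``, used to confirm the
screen produced dropout). Manifests are tab-separated UTF-8 with a header
row and no quoting.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "NON_TARGETING_SENTINEL",
    "CATEGORIES",
    "SgRNARecord",
    "SgRNALibrary",
    "ValidationReport",
    "LibraryError",
    "read_library_manifest",
    "write_library_manifest",
    "validate_library",
]

#: gene_symbol reserved for guides that target nothing in the genome
NON_TARGETING_SENTINEL = "NON_TARGETING"

CATEGORIES = ("targeting", "non_targeting", "positive_control")

MANIFEST_COLUMNS = (
    "guide_id",
    "gene_symbol",
    "protospacer",
    "category",
    "domain_annotation",
)

_PROTOSPACER_RE = re.compile(r"^[ACGT]{18,23}$")


class LibraryError(ValueError):
    """Malformed or internally inconsistent sgRNA library."""


@dataclass(frozen=True)
class SgRNARecord:
    """One guide: identifier, target gene, spacer sequence, role."""

    guide_id: str
    gene_symbol: str
    protospacer: str
    category: str
    domain_annotation: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LibraryError(
                f"guide {self.guide_id!r}: category {self.category!r} not in {CATEGORIES}"
            )
        if not _PROTOSPACER_RE.match(self.protospacer):
            raise LibraryError(
                f"guide {self.guide_id!r}: protospacer {self.protospacer!r} must be "
                "18-23 nt of A/C/G/T"
            )
        if self.category == "non_targeting" and self.gene_symbol != NON_TARGETING_SENTINEL:
            raise LibraryError(
                f"guide {self.guide_id!r}: non_targeting guides must use gene_symbol "
                f"{NON_TARGETING_SENTINEL!r}, got {self.gene_symbol!r}"
            )


@dataclass
class SgRNALibrary:
    """Ordered collection of guides with unique ids and spacers."""

    records: list[SgRNARecord]
    name: str = "library"

    def __post_init__(self) -> None:
        _check_unique("guide_id", [r.guide_id for r in self.records], self.records)
        _check_unique("protospacer", [r.protospacer for r in self.records], self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    def category_counts(self) -> dict[str, int]:
        c = Counter(r.category for r in self.records)
        return {cat: c.get(cat, 0) for cat in CATEGORIES}

    def guide_to_gene(self) -> dict[str, str]:
        """guide_id -> gene_symbol (non-targeting guides map to the sentinel)."""
        return {r.guide_id: r.gene_symbol for r in self.records}

    def protospacer_to_guide(self) -> dict[str, str]:
        return {r.protospacer: r.guide_id for r in self.records}

    def genes(self, category: str = "targeting") -> list[str]:
        """Distinct gene symbols of one category, in first-seen order."""
        seen: dict[str, None] = {}
        for r in self.records:
            if r.category == category:
                seen.setdefault(r.gene_symbol, None)
        return list(seen)


def _check_unique(field_name: str, values: list[str], records: list[SgRNARecord]) -> None:
    dupes = {v for v, n in Counter(values).items() if n > 1}
    if dupes:
        offenders = [r.guide_id for r, v in zip(records, values) if v in dupes]
        raise LibraryError(
            f"duplicate {field_name} values {sorted(dupes)!r} "
            f"shared by guides {offenders!r}"
        )


@dataclass
class ValidationReport:
    total: int
    category_counts: dict[str, int]
    n_targeting_genes: int
    n_positive_control_genes: int
    guides_per_gene: dict[str, int]
    warnings: list[str] = field(default_factory=list)


def read_library_manifest(path: str | Path, name: str | None = None) -> SgRNALibrary:
    """Parse a TSV manifest into an :class:`SgRNALibrary`.

    Row order is preserved; lowercase bases are upper-cased. Raises
    :class:`LibraryError` with the offending line number for malformed rows
    and with the offending guide ids for duplicate keys.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in MANIFEST_COLUMNS[:4] if c not in header]
        if missing:
            raise LibraryError(f"{path}: header missing required columns {missing}")
        idx = {c: header.index(c) for c in header}
        records: list[SgRNARecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise LibraryError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            try:
                records.append(
                    SgRNARecord(
                        guide_id=fields[idx["guide_id"]],
                        gene_symbol=fields[idx["gene_symbol"]],
                        protospacer=fields[idx["protospacer"]].upper(),
                        category=fields[idx["category"]],
                        domain_annotation=(
                            fields[idx["domain_annotation"]]
                            if "domain_annotation" in idx and len(fields) > idx["domain_annotation"]
                            else ""
                        ),
                    )
                )
            except LibraryError as e:
                raise LibraryError(f"{path}:{lineno}: {e}") from e
    if not records:
        raise LibraryError(f"{path}: manifest contains no records")
    return SgRNALibrary(records=records, name=name or path.stem)


def write_library_manifest(lib: SgRNALibrary, path: str | Path) -> None:
    """Serialize a library back to TSV; round-trips field-for-field."""
    if not lib.records:
        raise LibraryError("refusing to write an empty library")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for r in lib.records:
            fh.write(
                f"{r.guide_id}\t{r.gene_symbol}\t{r.protospacer}\t{r.category}\t{r.domain_annotation}\n"
            )


def validate_library(lib: SgRNALibrary, min_guides_per_gene: int = 5) -> ValidationReport:
    """Summarize composition and flag under-covered targeting genes.

    Genes with fewer than ``min_guides_per_gene`` guides are warnings, not
    errors: a well-designed library carries five to six guides per gene but
    smaller designs are legal.
    """
    if not lib.records:
        raise LibraryError("cannot validate an empty library")
    per_gene: dict[str, int] = defaultdict(int)
    pc_genes: set[str] = set()
    for r in lib.records:
        if r.category == "targeting":
            per_gene[r.gene_symbol] += 1
        elif r.category == "positive_control":
            pc_genes.add(r.gene_symbol)
    warnings = [
        f"{gene}: {n} guides (<{min_guides_per_gene})"
        for gene, n in sorted(per_gene.items())
        if n < min_guides_per_gene
    ]
    return ValidationReport(
        total=len(lib),
        category_counts=lib.category_counts(),
        n_targeting_genes=len(per_gene),
        n_positive_control_genes=len(pc_genes),
        guides_per_gene=dict(per_gene),
        warnings=warnings,
    )
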