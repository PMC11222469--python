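"""Unique-peptide fold enrichment and interactome set intersection.

Two orthogonal interactome experiments — an affinity-purification
(FLAG-IP vs empty vector) and a proximity-labeling run (ligase-fused bait,
with vs without a neddylation inhibitor that traps substrate encounters) —
each yield a table of unique-peptide counts per protein in a case and a
control condition. A protein is called an interactor when its case/control
unique-peptide ratio reaches a fold threshold (inclusive, default 5). The
intersection of the two enriched sets nominates high-confidence partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PeptideCountTable",
    "EnrichmentResult",
    "VennResult",
    "read_peptide_table",
    "fold_enrichment",
    "enriched_set",
    "intersect_sets",
    "normalize_symbol",
]

ZERO_POLICIES = ("floor_one", "exclude")


def normalize_symbol(name: str, aliases: dict[str, str] | None = None) -> str:
    """Case-insensitive gene-symbol harmonization with an optional alias map."""
    key = name.strip().upper()
    if aliases:
        key = {k.upper(): v.upper() for k, v in aliases.items()}.get(key, key)
    return key


@dataclass
class PeptideCountTable:
    """Per-protein unique-peptide counts for one case/control pair."""

    table: pd.DataFrame  # columns: protein_id, case_peptides, control_peptides
    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self) -> None:
        t = self.table
        required = {"protein_id", "case_peptides", "control_peptides"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"peptide table missing columns {sorted(missing)}")
        if t["protein_id"].duplicated().any():
            dupes = t.loc[t["protein_id"].duplicated(), "protein_id"].tolist()
            raise ValueError(f"duplicate protein_id values: {dupes[:5]}")
        for col in ("case_peptides", "control_peptides"):
            vals = t[col]
            if (vals < 0).any() or not (vals == vals.astype(int)).all():
                raise ValueError(f"{col} must be non-negative integers")
        self.table = t.astype({"case_peptides": int, "control_peptides": int})


def read_peptide_table(
    path: str | Path, case_label: str = "case", control_label: str = "control"
) -> PeptideCountTable:
    df = pd.read_csv(path, sep="\t")
    return PeptideCountTable(table=df, case_label=case_label, control_label=control_label)


@dataclass
class EnrichmentResult:
    """Per-protein case/control ratios and the policy that produced them."""

    ratios: pd.Series  # index: protein_id
    zero_policy: str
    n_dropped: int = 0

    def to_frame(self, threshold: float = 5.0) -> pd.DataFrame:
        return pd.DataFrame(
            {"ratio": self.ratios, "enriched": self.ratios >= threshold}
        )


def fold_enrichment(
    t: PeptideCountTable, zero_policy: str = "floor_one"
) -> EnrichmentResult:
    """Case-over-control unique-peptide ratios under an explicit zero policy.

    ``floor_one`` (default): ratio = case / max(control, 1), so proteins
    absent from the control still get a finite ratio; rows with
    case = control = 0 are dropped. ``exclude``: rows with control = 0 are
    dropped entirely.
    """
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"unknown zero_policy {zero_policy!r}; choose from {ZERO_POLICIES}")
    df = t.table
    if zero_policy == "floor_one":
        keep = ~((df["case_peptides"] == 0) & (df["control_peptides"] == 0))
        sub = df[keep]
        ratios = sub["case_peptides"] / sub["control_peptides"].clip(lower=1)
    else:
        keep = df["control_peptides"] > 0
        sub = df[keep]
        ratios = sub["case_peptides"] / sub["control_peptides"]
    ratios.index = sub["protein_id"]
    return EnrichmentResult(
        ratios=ratios.astype(float), zero_policy=zero_policy, n_dropped=int((~keep).sum())
    )


def enriched_set(r: EnrichmentResult, threshold: float = 5.0) -> set[str]:
    """Proteins whose ratio meets the fold threshold (inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return set(r.ratios.index[r.ratios >= threshold])


@dataclass
class VennResult:
    a_only: set[str]
    b_only: set[str]
    both: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {"a_only": len(self.a_only), "b_only": len(self.b_only), "both": len(self.both)}


def intersect_sets(
    a: set[str], b: set[str], aliases: dict[str, str] | None = None
) -> VennResult:
    """Exact two-set Venn after case-insensitive symbol harmonization."""
    na = {normalize_symbol(x, aliases) for x in a}
    nb = {normalize_symbol(x, aliases) for x in b}
    return VennResult(a_only=na - nb, b_only=nb - na, both=na & nb)
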