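"""Essentiality Scores and group-differential (lineage-biased) dependency ranking.

A dropout screen measures gene essentiality as guide depletion between an
initial pool (collected shortly after transduction) and a final pool
(collected after several population doublings). The per-gene Essentiality
Score (ES) is the mean over the gene's guides of

    log2((final_abundance + c) / (initial_abundance + c)),   c = pseudocount

on depth-normalized abundances. Negative ES means the gene is required for
proliferation in that cell line. A lineage-biased ES contrasts two groups
of cell lines:

    biased_es(gene) = mean_{lines in group B}(ES) - mean_{lines in group A}(ES)

so a gene strongly essential only in the focal group A (e.g. AML lines)
gets a large positive biased ES; genes are ranked by it descending.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .library_io import NON_TARGETING_SENTINEL, SgRNALibrary
from .screen_quant import CountMatrix, SampleSheet

__all__ = [
    "NormalizedMatrix",
    "ESTable",
    "BiasTable",
    "normalize_to_common_total",
    "sgrna_log2fc",
    "gene_es",
    "compute_es_table",
    "biased_es",
    "export_es_heatmap_table",
]


@dataclass
class NormalizedMatrix:
    """Depth-normalized guide abundances; every column sums to target_total."""

    values: pd.DataFrame
    target_total: float

    def __post_init__(self) -> None:
        totals = self.values.sum(axis=0)
        if not np.allclose(totals, self.target_total, rtol=1e-9):
            raise ValueError("normalized columns do not sum to target_total")


@dataclass
class ESTable:
    """Per-gene ES per cell line, plus the guide count behind each gene."""

    es: pd.DataFrame  # index: gene, columns: cell_line
    guide_counts: pd.Series  # index: gene

    def to_tsv(self, path: str | Path) -> None:
        out = self.es.copy()
        out["n_guides"] = self.guide_counts
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ESTable":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        counts = df.pop("n_guides").astype(int)
        return cls(es=df, guide_counts=counts)


@dataclass
class BiasTable:
    """Genes ranked by group-differential ES (rank 1 = most focal-biased)."""

    table: pd.DataFrame  # columns: biased_es, mean_group_a, mean_group_b, rank
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def top(self, n: int) -> list[str]:
        return list(self.table.sort_values("rank").index[:n])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def normalize_to_common_total(
    cm: CountMatrix | pd.DataFrame, target_total: float | str = "mean"
) -> NormalizedMatrix:
    """Scale every sample column to the same total read count.

    ``target_total`` is either a positive number or ``"mean"`` (the mean of
    the raw column totals, the default — the screen convention of
    "normalize to the same number of total reads" without naming a number).
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    totals = counts.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    if target_total == "mean":
        target = float(totals.mean())
    else:
        target = float(target_total)
        if target <= 0:
            raise ValueError("target_total must be positive")
    scaled = counts.astype(float) * (target / totals)
    return NormalizedMatrix(values=scaled, target_total=target)


def sgrna_log2fc(
    initial,
    final,
    pseudocount: float = 1.0,
    numerator_only: bool = False,
):
    """Per-guide log2 fold change of final over initial abundance.

    Default is the symmetric form log2((final+c)/(initial+c)), which is
    zero when final equals initial and finite for zero abundances. The
    ``numerator_only`` switch reproduces the literal one-sided reading
    log2((final+c)/initial) and will reject zero initial abundance.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    initial = np.asarray(initial, dtype=float)
    final = np.asarray(final, dtype=float)
    if (initial < 0).any() or (final < 0).any():
        raise ValueError("abundances must be non-negative")
    if numerator_only:
        if (initial == 0).any():
            raise ValueError("numerator_only pseudocount cannot handle zero initial abundance")
        return np.log2((final + pseudocount) / initial)
    return np.log2((final + pseudocount) / (initial + pseudocount))


def gene_es(lfc: pd.Series, lib: SgRNALibrary) -> pd.Series:
    """Collapse per-guide log2 fold changes to per-gene means.

    Non-targeting guides aggregate under the sentinel pseudo-gene so the
    null depletion distribution is reportable alongside real genes.
    """
    mapping = lib.guide_to_gene()
    unknown = [g for g in lfc.index if g not in mapping]
    if unknown:
        raise KeyError(f"guides absent from library: {unknown[:5]!r}...")
    genes = lfc.index.map(mapping)
    return lfc.groupby(genes).mean()


def compute_es_table(
    nm: NormalizedMatrix,
    sheet: SampleSheet,
    lib: SgRNALibrary,
    pseudocount: float = 1.0,
    numerator_only: bool = False,
) -> ESTable:
    """ES for every gene in every cell line, from one initial/final pair per line."""
    lines: list[str] = []
    for r in sheet:
        if r.cell_line not in lines:
            lines.append(r.cell_line)
    cols = {}
    for line in lines:
        s0 = sheet.sample_for(line, "initial").sample_id
        s1 = sheet.sample_for(line, "final").sample_id
        lfc = pd.Series(
            sgrna_log2fc(
                nm.values[s0], nm.values[s1], pseudocount=pseudocount, numerator_only=numerator_only
            ),
            index=nm.values.index,
        )
        cols[line] = gene_es(lfc, lib)
    es = pd.DataFrame(cols)
    mapping = lib.guide_to_gene()
    counts = pd.Series(list(mapping.values())).value_counts()
    return ESTable(es=es, guide_counts=counts.reindex(es.index).astype(int))


def biased_es(
    es: ESTable | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    exclude_genes: Sequence[str] = (),
    exclude_controls: bool = True,
    lib: SgRNALibrary | None = None,
) -> BiasTable:
    """Rank genes by group-differential ES, focal group = ``group_a``.

    biased_es = mean(ES over group_b) - mean(ES over group_a): large and
    positive when the gene is a selective dependency of group A. Control
    entries (the non-targeting sentinel, and positive-control genes when a
    library is supplied) are excluded from ranking by default. Ties are
    broken lexicographically by gene symbol.
    """
    df = es.es if isinstance(es, ESTable) else es
    ga, gb = list(dict.fromkeys(group_a)), list(dict.fromkeys(group_b))
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError(f"groups overlap: {sorted(set(ga) & set(gb))}")
    missing = [c for c in ga + gb if c not in df.columns]
    if missing:
        raise KeyError(f"cell lines absent from ES table: {missing}")

    drop = set(exclude_genes)
    if exclude_controls:
        drop.add(NON_TARGETING_SENTINEL)
        if lib is not None:
            drop.update(lib.genes("positive_control"))
    sub = df.drop(index=[g for g in drop if g in df.index])

    mean_a = sub[ga].mean(axis=1)
    mean_b = sub[gb].mean(axis=1)
    bias = mean_b - mean_a
    out = pd.DataFrame(
        {"biased_es": bias, "mean_group_a": mean_a, "mean_group_b": mean_b}
    )
    out = _sort_bias(out)
    out["rank"] = np.arange(1, len(out) + 1)
    return BiasTable(table=out, group_a=tuple(ga), group_b=tuple(gb))


def _sort_bias(out: pd.DataFrame) -> pd.DataFrame:
    # descending biased_es, ties by gene symbol ascending
    tmp = out.copy()
    tmp.index.name = "gene"
    tmp = tmp.sort_index(kind="mergesort")
    return tmp.sort_values("biased_es", ascending=False, kind="mergesort")


def export_es_heatmap_table(
    es: ESTable, bias: BiasTable, path: str | Path
) -> pd.DataFrame:
    """One row per ranked gene: ES per line, biased ES, rank; sorted by rank."""
    ranked = bias.table.index
    missing = [g for g in ranked if g not in es.es.index]
    if missing:
        raise KeyError(f"genes in bias table missing from ES table: {missing[:5]}")
    out = es.es.loc[ranked].copy()
    out["biased_es"] = bias.table["biased_es"]
    out["rank"] = bias.table["rank"]
    out.to_csv(path, sep="\t", index_label="gene")
    return out
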