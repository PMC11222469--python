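"""Seeded generators with planted ground truth for every pipeline stage.

Three generators emulate the study's data shapes so the whole pipeline is
testable without any external download:

* :func:`simulate_screen` — a domain-focused dropout screen: a library of
  2405 targeting guides over 381 genes plus 100 non-targeting and 20
  positive-control guides (the published library composition), guide
  counts drawn negative-binomially at initial and final timepoints across
  six cell lines in two lineage groups, with planted per-gene fitness
  effects; optionally emitted as stacking-barcoded FASTQ reads.
* :func:`simulate_peptides` — paired case/control unique-peptide count
  tables for two interactome experiments with planted enriched proteins,
  a configurable subset planted in both to seed the Venn intersection.
* :func:`simulate_loops` — reference and test chromatin-loop sets with
  planted shared/gained/control-only classes and log-normal loop-length
  distributions on a Hi-C-like bin grid.

Every generator is driven by one integer seed and reproduces its output
byte-for-byte; planted truth comes back in a truth object so recovery is
checkable exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Loop, LoopSet
from .library_io import NON_TARGETING_SENTINEL, SgRNALibrary, SgRNARecord
from .proteome import PeptideCountTable
from .screen_quant import CountMatrix, SampleSheet, SheetRow

__all__ = [
    "ScreenSimConfig",
    "ScreenSimTruth",
    "PeptideSimTruth",
    "LoopSimTruth",
    "build_library",
    "build_sample_sheet",
    "simulate_screen",
    "reads_from_counts",
    "write_fastq",
    "simulate_peptides",
    "simulate_loops",
    "DEFAULT_CELL_LINES",
]

BASES = np.array(list("ACGT"))

#: six lines, two lineage groups: the screen's AML-vs-other design
DEFAULT_CELL_LINES: dict[str, str] = {
    "MOLM13": "aml",
    "MV411": "aml",
    "JURKAT": "other",
    "U2932": "other",
    "OPM1": "other",
    "HEPG2": "other",
}

POSITIVE_CONTROL_GENES = ("CDK1", "CDK9", "PCNA", "POLR2A", "RPA3", "RPL23A")


@dataclass
class ScreenSimConfig:
    """Study conditions for the dropout-screen generator.

    Defaults mirror the published library (2405 targeting guides across
    381 genes, 100 non-targeting, 20 positive-control guides over 6
    pan-essential genes), 1000x library representation per sample, a tight
    plasmid-pool-like negative-binomial dispersion of 0.05, and fitness
    effects of -3 (pan-essential controls, all lines) and -2 (20 planted
    focal-group-biased genes, focal lines only) in log2 depletion units.
    """

    n_genes: int = 381
    n_targeting_guides: int = 2405
    n_nontargeting: int = 100
    n_positive_control_guides: int = 20
    positive_control_genes: tuple[str, ...] = POSITIVE_CONTROL_GENES
    cell_lines: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CELL_LINES))
    focal_group: str = "aml"
    representation: float = 1000.0  # expected reads per guide per sample
    dispersion: float = 0.05
    pan_essential_effect: float = -3.0
    biased_effect: float = -2.0
    n_biased_genes: int = 20
    protospacer_len: int = 20
    barcode_len: int = 6
    anchor: str = "CGAAACACCG"
    read_len: int = 60
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_targeting_guides < self.n_genes:
            raise ValueError("need >=1 guide per targeting gene")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.representation <= 0:
            raise ValueError("representation must be > 0")
        if self.n_biased_genes > self.n_genes:
            raise ValueError("more biased genes than genes")
        if self.focal_group not in set(self.cell_lines.values()):
            raise ValueError(f"focal_group {self.focal_group!r} not among line groups")


@dataclass
class ScreenSimTruth:
    """Planted per-gene fitness effects and the exact counts drawn."""

    gene_effects: pd.DataFrame  # gene x cell_line, log2 depletion units
    biased_genes: list[str]
    counts: CountMatrix
    seed: int


def _random_spacers(rng: np.random.Generator, n: int, length: int, forbidden: str) -> list[str]:
    """Unique random protospacers avoiding the anchor substring."""
    spacers: list[str] = []
    seen: set[str] = set()
    while len(spacers) < n:
        block = rng.integers(0, 4, size=(max(64, n - len(spacers)), length))
        for row in block:
            s = "".join(BASES[row])
            if s in seen or forbidden in s:
                continue
            seen.add(s)
            spacers.append(s)
            if len(spacers) == n:
                break
    return spacers


def build_library(cfg: ScreenSimConfig, rng: np.random.Generator | None = None) -> SgRNALibrary:
    """Synthetic library with the configured composition.

    Targeting guides are spread as evenly as possible over the genes
    (with 2405 guides and 381 genes: 119 genes get 7 guides, the rest 6);
    positive-control guides are spread round-robin over their genes.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n_total = cfg.n_targeting_guides + cfg.n_nontargeting + cfg.n_positive_control_guides
    spacers = iter(_random_spacers(rng, n_total, cfg.protospacer_len, cfg.anchor))
    records: list[SgRNARecord] = []
    base, extra = divmod(cfg.n_targeting_guides, cfg.n_genes)
    for gi in range(cfg.n_genes):
        gene = f"GENE{gi + 1:04d}"
        for k in range(base + (1 if gi < extra else 0)):
            records.append(
                SgRNARecord(
                    guide_id=f"{gene}_sg{k + 1}",
                    gene_symbol=gene,
                    protospacer=next(spacers),
                    category="targeting",
                    domain_annotation="receptor-adaptor interface",
                )
            )
    for k in range(cfg.n_nontargeting):
        records.append(
            SgRNARecord(
                guide_id=f"NT_sg{k + 1}",
                gene_symbol=NON_TARGETING_SENTINEL,
                protospacer=next(spacers),
                category="non_targeting",
            )
        )
    for k in range(cfg.n_positive_control_guides):
        gene = cfg.positive_control_genes[k % len(cfg.positive_control_genes)]
        records.append(
            SgRNARecord(
                guide_id=f"{gene}_pc{k // len(cfg.positive_control_genes) + 1}",
                gene_symbol=gene,
                protospacer=next(spacers),
                category="positive_control",
            )
        )
    return SgRNALibrary(records=records, name="synthetic_crl_library")


def build_sample_sheet(cfg: ScreenSimConfig, rng: np.random.Generator | None = None) -> SampleSheet:
    """One (initial, final) sample pair per cell line with stacking barcodes.

    Barcodes are drawn at distinct stagger offsets and redrawn (bounded)
    until no two samples' patterns could match the same read prefix.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    rows: list[SheetRow] = []
    idx = 0
    for line in cfg.cell_lines:
        for tp in ("initial", "final"):
            rows.append(
                SheetRow(
                    sample_id=f"{line}_{tp}",
                    cell_line=line,
                    timepoint=tp,
                    barcode="",
                    # keep every pair of barcode windows overlapping so the
                    # sheet's ambiguity check can always be satisfied
                    stagger_len=idx % min(4, cfg.barcode_len - 1),
                )
            )
            idx += 1
    for attempt in range(200):
        candidate = [
            SheetRow(
                sample_id=r.sample_id,
                cell_line=r.cell_line,
                timepoint=r.timepoint,
                barcode="".join(BASES[rng.integers(0, 4, size=cfg.barcode_len)]),
                stagger_len=r.stagger_len,
            )
            for r in rows
        ]
        try:
            return SampleSheet(rows=candidate)
        except Exception:
            continue
    raise RuntimeError("could not draw a conflict-free barcode set in 200 attempts")


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson mixture: var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_screen(
    cfg: ScreenSimConfig,
) -> tuple[SgRNALibrary, SampleSheet, CountMatrix, ScreenSimTruth]:
    """Draw a full screen at the count level.

    Initial counts are negative-binomial around the configured
    representation; expected final counts multiply the initial expectation
    by 2^effect(gene, line). Non-targeting guides have effect 0
    everywhere, positive controls the pan-essential effect in every line,
    and the planted biased genes the biased effect in focal-group lines
    only.
    """
    rng = np.random.default_rng(cfg.seed)
    lib = build_library(cfg, rng)
    sheet = build_sample_sheet(cfg, rng)

    genes = lib.genes("targeting")
    biased = sorted(rng.choice(len(genes), size=cfg.n_biased_genes, replace=False))
    biased_genes = [genes[i] for i in biased]

    lines = list(cfg.cell_lines)
    all_genes = genes + [NON_TARGETING_SENTINEL] + list(lib.genes("positive_control"))
    effects = pd.DataFrame(0.0, index=all_genes, columns=lines)
    for g in lib.genes("positive_control"):
        effects.loc[g, :] = cfg.pan_essential_effect
    focal_lines = [l for l, grp in cfg.cell_lines.items() if grp == cfg.focal_group]
    for g in biased_genes:
        effects.loc[g, focal_lines] = cfg.biased_effect

    guide_gene = lib.guide_to_gene()
    guide_ids = lib.guide_ids
    effect_per_guide = {
        line: np.array([effects.loc[guide_gene[g], line] for g in guide_ids]) for line in lines
    }
    counts = pd.DataFrame(0, index=guide_ids, columns=sheet.sample_ids, dtype="int64")
    mu0 = np.full(len(guide_ids), cfg.representation)
    for line in lines:
        s0 = sheet.sample_for(line, "initial").sample_id
        s1 = sheet.sample_for(line, "final").sample_id
        counts[s0] = _negbin(rng, mu0, cfg.dispersion)
        counts[s1] = _negbin(rng, mu0 * np.exp2(effect_per_guide[line]), cfg.dispersion)
    cm = CountMatrix(counts=counts, unassigned=pd.Series(0, index=sheet.sample_ids))
    truth = ScreenSimTruth(
        gene_effects=effects, biased_genes=biased_genes, counts=cm, seed=cfg.seed
    )
    return lib, sheet, cm, truth


def reads_from_counts(
    cm: CountMatrix,
    lib: SgRNALibrary,
    sheet: SampleSheet,
    cfg: ScreenSimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Expand a count matrix into per-sample stacking-barcoded reads.

    Each read is [random stagger fill][barcode][anchor][protospacer]
    padded with random bases to the configured read length, emitted in a
    seeded random order. With a nonzero error rate, bases are substituted
    uniformly to exercise unassigned-read accounting.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    spacer_of = {r.guide_id: r.protospacer for r in lib}
    out: dict[str, list[str]] = {}
    for row in sheet:
        reads: list[str] = []
        for guide_id, n in cm.counts[row.sample_id].items():
            core = row.barcode + cfg.anchor + spacer_of[guide_id]
            for _ in range(int(n)):
                stagger = "".join(BASES[rng.integers(0, 4, size=row.stagger_len)])
                pad_n = max(0, cfg.read_len - row.stagger_len - len(core))
                pad = "".join(BASES[rng.integers(0, 4, size=pad_n)])
                reads.append(stagger + core + pad)
        if cfg.error_rate > 0 and reads:
            reads = _inject_errors(rng, reads, cfg.error_rate)
        order = rng.permutation(len(reads))
        out[row.sample_id] = [reads[i] for i in order]
    return out


def _inject_errors(rng: np.random.Generator, reads: list[str], rate: float) -> list[str]:
    mutated = []
    for read in reads:
        arr = np.array(list(read))
        hits = rng.random(len(arr)) < rate
        if hits.any():
            arr[hits] = BASES[rng.integers(0, 4, size=int(hits.sum()))]
        mutated.append("".join(arr))
    return mutated


def write_fastq(reads: list[str], path: str | Path, prefix: str = "read") -> None:
    """Serialize reads as FASTQ with flat qualities (exact-match counting ignores them)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# peptide-count generator


@dataclass
class PeptideSimTruth:
    planted_a: set[str]
    planted_b: set[str]
    shared: set[str]
    seed: int


def simulate_peptides(
    n_proteins: int = 1000,
    n_planted_a: int = 50,
    n_planted_b: int = 50,
    n_shared: int = 4,
    planted_fold: float = 8.0,
    background_mean_range: tuple[float, float] = (15.0, 60.0),
    planted_control_mean: float = 2.0,
    ambiguity_fold: float = 5.0,
    shared_names: tuple[str, ...] | None = None,
    seed: int = 0,
) -> tuple[PeptideCountTable, PeptideCountTable, PeptideSimTruth]:
    """Two case/control unique-peptide tables with planted interactors.

    Background proteins get correlated Poisson case/control counts around
    a shared per-protein abundance; any background row that would satisfy
    the fold rule at ``ambiguity_fold`` by chance is redrawn (bounded), so
    the planted sets are exactly the enriched sets and truth labels are
    unambiguous. Planted proteins get case >= planted_fold * max(control, 1)
    by construction. ``n_shared`` proteins are planted in both experiments
    (optionally renamed via ``shared_names``) to seed the intersection.
    """
    if n_shared > min(n_planted_a, n_planted_b):
        raise ValueError("n_shared exceeds a planted set size")
    if n_planted_a + n_planted_b - n_shared > n_proteins:
        raise ValueError("planted sets exceed protein count")
    if shared_names is not None and len(shared_names) != n_shared:
        raise ValueError("shared_names length must equal n_shared")
    rng = np.random.default_rng(seed)
    names = [f"PROT{i + 1:05d}" for i in range(n_proteins)]
    order = rng.permutation(n_proteins)
    shared_idx = order[:n_shared]
    a_only_idx = order[n_shared : n_planted_a]
    b_only_idx = order[n_planted_a : n_planted_a + n_planted_b - n_shared]
    if shared_names is not None:
        for i, nm in zip(shared_idx, shared_names):
            names[i] = nm
    planted_a = {names[i] for i in shared_idx} | {names[i] for i in a_only_idx}
    planted_b = {names[i] for i in shared_idx} | {names[i] for i in b_only_idx}

    def one_experiment(planted: set[str], case_label: str, control_label: str) -> PeptideCountTable:
        case = np.zeros(n_proteins, dtype=int)
        control = np.zeros(n_proteins, dtype=int)
        lo, hi = background_mean_range
        for i, nm in enumerate(names):
            if nm in planted:
                c = rng.poisson(planted_control_mean)
                case[i] = math.ceil(planted_fold * max(c, 1)) + rng.poisson(3)
                control[i] = c
            else:
                for _ in range(1000):
                    lam = rng.uniform(lo, hi)
                    ca, co = rng.poisson(lam), rng.poisson(lam)
                    if ca < ambiguity_fold * max(co, 1):
                        break
                else:
                    raise RuntimeError("could not draw unambiguous background row")
                case[i], control[i] = ca, co
        df = pd.DataFrame(
            {"protein_id": names, "case_peptides": case, "control_peptides": control}
        )
        return PeptideCountTable(table=df, case_label=case_label, control_label=control_label)

    table_a = one_experiment(planted_a, "FLAG_bait", "empty_vector")
    table_b = one_experiment(planted_b, "proximity_inhibitor", "proximity_vehicle")
    truth = PeptideSimTruth(
        planted_a=planted_a, planted_b=planted_b, shared={names[i] for i in shared_idx}, seed=seed
    )
    return table_a, table_b, truth


# ---------------------------------------------------------------------------
# loop-set generator


@dataclass
class LoopSimTruth:
    n_shared: int
    n_gained: int
    n_control_only: int
    shared_pairs: list[tuple[int, int]]  # (test index, reference index)
    seed: int


DEFAULT_CHROM_SIZES = {f"chr{i + 1}": 50_000_000 for i in range(5)}


def _snap_length(raw: float, bin_size: int) -> int:
    return max(2 * bin_size, int(round(raw / bin_size)) * bin_size)


def simulate_loops(
    n_shared: int = 100,
    n_gained: int = 50,
    n_control_only: int = 50,
    median_ref: float = 225_000.0,
    median_test: float = 310_000.0,
    sigma: float = 0.5,
    anchor_width: int = 10_000,
    chrom_sizes: dict[str, int] | None = None,
    bin_size: int = 10_000,
    jitter: bool = True,
    seed: int = 0,
    max_retries: int = 10_000,
) -> tuple[LoopSet, LoopSet, LoopSimTruth]:
    """Reference and test loop sets with planted shared/gained classes.

    Anchors sit on a Hi-C-like bin grid; loop lengths (anchor midpoint to
    midpoint) are log-normal with the given medians, snapped to the grid.
    Reference anchors are placed with a one-bin buffer so that shared test
    loops — reference loops copied with sub-anchor-width jitter — overlap
    exactly their source loop, gained loops (placed clear of every
    reference anchor) overlap none, and unmatched reference loops are
    recovered as control-only, all exactly.
    """
    if anchor_width <= 0:
        raise ValueError("anchor_width must be > 0")
    chrom_sizes = chrom_sizes or dict(DEFAULT_CHROM_SIZES)
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    occupied: dict[str, set[int]] = {c: set() for c in chroms}  # buffered anchor bins

    def place(median: float, avoid_buffer: bool) -> Loop:
        for _ in range(max_retries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            size = chrom_sizes[chrom]
            length = _snap_length(float(rng.lognormal(math.log(median), sigma)), bin_size)
            max_start_bin = (size - length - anchor_width) // bin_size
            if max_start_bin < 2:
                continue
            # keep one bin of headroom at the chromosome start so jitter stays valid
            s_bin = int(rng.integers(1, max_start_bin + 1))
            left_bin, right_bin = s_bin, s_bin + length // bin_size
            bins = {left_bin, right_bin}
            if avoid_buffer:
                buffered = {b + d for b in bins for d in (-1, 0, 1)}
                if buffered & occupied[chrom]:
                    continue
            elif bins & occupied[chrom]:
                continue
            for b in bins:
                for d in (-1, 0, 1):
                    occupied[chrom].add(b + d)
            left = GenomicInterval(chrom, left_bin * bin_size, left_bin * bin_size + anchor_width)
            right = GenomicInterval(chrom, right_bin * bin_size, right_bin * bin_size + anchor_width)
            return Loop(left=left, right=right)
        raise RuntimeError("could not place a loop without anchor collisions; genome too small")

    ref_loops = [place(median_ref, avoid_buffer=True) for _ in range(n_shared + n_control_only)]

    test_loops: list[Loop] = []
    shared_pairs: list[tuple[int, int]] = []
    max_jit = min(anchor_width, bin_size) // 2
    for ti in range(n_shared):
        src = ref_loops[ti]
        if jitter and max_jit > 0:
            dl = int(rng.integers(-max_jit, max_jit + 1))
            dr = int(rng.integers(-max_jit, max_jit + 1))
        else:
            dl = dr = 0
        left = GenomicInterval(src.left.chrom, src.left.start + dl, src.left.end + dl)
        right = GenomicInterval(src.right.chrom, src.right.start + dr, src.right.end + dr)
        test_loops.append(Loop(left=left, right=right))
        shared_pairs.append((ti, ti))
    for _ in range(n_gained):
        test_loops.append(place(median_test, avoid_buffer=False))

    reference = LoopSet(name="reference", loops=ref_loops)
    test = LoopSet(name="test", loops=test_loops)
    truth = LoopSimTruth(
        n_shared=n_shared,
        n_gained=n_gained,
        n_control_only=n_control_only,
        shared_pairs=shared_pairs,
        seed=seed,
    )
    return reference, test, truth
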