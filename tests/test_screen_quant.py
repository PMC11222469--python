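"""Demultiplexing and exact-match counting, checked against a brute-force oracle."""

import numpy as np
import pytest

from depbias.screen_quant import (
    CountMatrix,
    SampleSheet,
    SampleSheetError,
    SheetRow,
    count_guides,
    demultiplex,
    quantify,
    representation_qc,
)
from depbias.simulate import ScreenSimConfig, reads_from_counts, simulate_screen

ANCHOR = "CGAAACACCG"


def sheet_of(*rows):
    return SampleSheet(rows=[SheetRow(*r) for r in rows])


class TestDemultiplex:
    def test_exact_barcode_at_zero_stagger(self):
        sheet = sheet_of(("s1", "L1", "initial", "ACGT", 0))
        by, orphans = demultiplex(["ACGT" + ANCHOR + "A" * 20], sheet)
        assert len(by["s1"]) == 1 and orphans == 0

    def test_staggered_barcode_assigned(self):
        sheet = sheet_of(("s1", "L1", "initial", "ACGT", 2))
        read = "TT" + "ACGT" + ANCHOR + "A" * 20
        assert read[2:6] == "ACGT"  # construction check
        by, orphans = demultiplex([read], sheet)
        assert len(by["s1"]) == 1 and orphans == 0

    def test_unknown_barcode_is_orphan(self):
        sheet = sheet_of(("s1", "L1", "initial", "ACGT", 0))
        by, orphans = demultiplex(["GGGG" + ANCHOR + "A" * 20], sheet)
        assert orphans == 1 and not by["s1"]

    def test_compatible_patterns_rejected_at_load(self):
        # same barcode at staggers 0 and 4 -> windows disjoint -> some read fits both
        with pytest.raises(SampleSheetError, match="compatible"):
            sheet_of(("s1", "L1", "initial", "ACGT", 0), ("s2", "L1", "final", "ACGT", 4))

    def test_duplicate_barcode_stagger_rejected(self):
        with pytest.raises(SampleSheetError):
            sheet_of(("s1", "L1", "initial", "ACGT", 0), ("s2", "L1", "final", "ACGT", 0))


class TestCountGuides:
    def test_single_mismatch_goes_unassigned(self, tiny_library):
        spacer = tiny_library.records[0].protospacer
        mutated = ("T" if spacer[0] == "A" else "A") + spacer[1:]
        reads = [ANCHOR + spacer] * 10 + [ANCHOR + mutated]
        cm = count_guides({"s1": reads}, tiny_library, ANCHOR)
        assert cm.counts.loc["g1", "s1"] == 10
        assert cm.unassigned["s1"] == 1

    def test_empty_stream_gives_zero_matrix(self, tiny_library):
        cm = count_guides({"s1": []}, tiny_library, ANCHOR)
        assert cm.counts["s1"].sum() == 0 and cm.unassigned["s1"] == 0

    def test_missing_anchor_counts_unassigned(self, tiny_library):
        spacer = tiny_library.records[0].protospacer
        cm = count_guides({"s1": ["TTTT" + spacer]}, tiny_library, ANCHOR)
        assert cm.unassigned["s1"] == 1

    def test_conservation_assigned_plus_unassigned(self, tiny_library):
        rng = np.random.default_rng(0)
        spacers = [r.protospacer for r in tiny_library]
        reads = [
            ANCHOR + spacers[rng.integers(len(spacers))]
            if rng.random() < 0.7
            else "".join(rng.choice(list("ACGT"), 40))
            for _ in range(200)
        ]
        cm = count_guides({"s1": reads}, tiny_library, ANCHOR)
        assert cm.counts["s1"].sum() + cm.unassigned["s1"] == 200


def brute_force_counts(reads_by_sample, lib, anchor, sheet):
    """Independent oracle: scan every protospacer at every read position."""
    offsets = {r.sample_id: r.stagger_len + len(r.barcode) for r in sheet}
    counts = {s: {g: 0 for g in lib.guide_ids} for s in reads_by_sample}
    unassigned = {s: 0 for s in reads_by_sample}
    spacer_of = {r.guide_id: r.protospacer for r in lib}
    for s, reads in reads_by_sample.items():
        for read in reads:
            hit = None
            off = offsets[s]
            if read[off : off + len(anchor)] == anchor:
                # longest protospacer wins at the anchor-adjacent position
                for gid, sp in sorted(spacer_of.items(), key=lambda kv: -len(kv[1])):
                    if read[off + len(anchor) : off + len(anchor) + len(sp)] == sp:
                        hit = gid
                        break
            if hit is None:
                unassigned[s] += 1
            else:
                counts[s][hit] += 1
    return counts, unassigned


class TestOracleEquivalence:
    def test_counts_equal_brute_force_on_simulated_reads(self):
        cfg = ScreenSimConfig(
            seed=11, n_genes=10, n_targeting_guides=60, n_nontargeting=5,
            n_positive_control_guides=6, representation=4.0, error_rate=0.02,
            n_biased_genes=3,
        )
        lib, sheet, cm, _ = simulate_screen(cfg)
        reads = reads_from_counts(cm, lib, sheet, cfg)
        total = sum(len(v) for v in reads.values())
        assert total <= 5000
        got = count_guides(reads, lib, ANCHOR, sheet=sheet)
        want_counts, want_unassigned = brute_force_counts(reads, lib, ANCHOR, sheet)
        for s in reads:
            assert got.unassigned[s] == want_unassigned[s]
            for g in lib.guide_ids:
                assert got.counts.loc[g, s] == want_counts[s][g]
            assert got.counts[s].sum() + got.unassigned[s] == len(reads[s])

    def test_error_free_simulation_recovers_truth_exactly(self):
        cfg = ScreenSimConfig(
            seed=7, n_genes=8, n_targeting_guides=48, n_nontargeting=4,
            n_positive_control_guides=6, representation=5.0, n_biased_genes=2,
        )
        lib, sheet, cm, truth = simulate_screen(cfg)
        reads = reads_from_counts(cm, lib, sheet, cfg)
        got, orphans = quantify(
            (r for rs in reads.values() for r in rs), sheet, lib, cfg.anchor
        )
        assert orphans == 0
        assert got.counts.loc[cm.counts.index, cm.counts.columns].equals(cm.counts)

    def test_counting_is_permutation_invariant(self, tiny_library):
        rng = np.random.default_rng(3)
        spacers = [r.protospacer for r in tiny_library]
        reads = [ANCHOR + spacers[rng.integers(len(spacers))] for _ in range(100)]
        cm1 = count_guides({"s": list(reads)}, tiny_library, ANCHOR)
        perm = [reads[i] for i in rng.permutation(len(reads))]
        cm2 = count_guides({"s": perm}, tiny_library, ANCHOR)
        assert cm1.counts.equals(cm2.counts)


class TestRepresentationQC:
    @pytest.mark.parametrize(
        "per_guide,flagged", [(2000, False), (100, True)]
    )
    def test_fold_representation_threshold(self, tiny_library, per_guide, flagged):
        import pandas as pd

        counts = pd.DataFrame(
            {"s1": [per_guide] * len(tiny_library)}, index=tiny_library.guide_ids
        )
        cm = CountMatrix(counts=counts, unassigned=pd.Series({"s1": 0}))
        qc = representation_qc(cm, tiny_library, threshold=1000)
        row = qc.per_sample.loc["s1"]
        assert row["fold_representation"] == pytest.approx(per_guide)
        assert bool(row["flagged"]) is flagged

    def test_all_zero_sample_flagged_with_unit_zero_fraction(self, tiny_library):
        import pandas as pd

        counts = pd.DataFrame({"s1": [0] * len(tiny_library)}, index=tiny_library.guide_ids)
        cm = CountMatrix(counts=counts, unassigned=pd.Series({"s1": 0}))
        qc = representation_qc(cm, tiny_library)
        row = qc.per_sample.loc["s1"]
        assert row["frac_zero_guides"] == 1.0 and bool(row["flagged"])


def test_count_matrix_tsv_round_trip(tmp_path, tiny_library):
    import pandas as pd

    counts = pd.DataFrame(
        {"s1": [1, 2, 3, 4], "s2": [0, 0, 5, 1]}, index=tiny_library.guide_ids
    )
    cm = CountMatrix(counts=counts, unassigned=pd.Series({"s1": 7, "s2": 0}))
    p = tmp_path / "c.tsv"
    cm.to_tsv(p)
    back = CountMatrix.from_tsv(p)
    assert back.counts.equals(cm.counts)
    assert back.unassigned.tolist() == cm.unassigned.tolist()
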