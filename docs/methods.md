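# Methods

## Screen quantification

Reads follow the stacking-barcode amplicon layout
`[stagger][barcode][anchor][protospacer][...]`: a variable-length stagger
diversifies sequencing cycles, the sample barcode sits at offset
`stagger_len`, and the invariant vector anchor immediately precedes the
protospacer. Demultiplexing matches the barcode exactly at its expected
offset. The sample sheet is rejected at load time if any two samples'
(stagger, barcode) patterns are mutually compatible — i.e. some read
prefix could satisfy both — which guarantees every read is assignable to
at most one sample regardless of iteration order. A consequence is that
all barcode windows in a sheet must pairwise overlap; the simulator's
sheet builder draws barcodes under that constraint.

Guide counting is exact-match by design: the substring immediately after
the anchor must equal a library protospacer with no mismatch or indel.
Reads failing the barcode, anchor, or protospacer test are tallied as
unassigned, never dropped, so per-sample `assigned + unassigned` always
equals the demultiplexed read count. If one library protospacer is a
prefix of another and both match at the anchor-adjacent position, the
longest match wins (deterministic; cannot occur in libraries with
uniform-length spacers). Base qualities are ignored — exact matching makes
them moot. The anchor is located at the expected offset only by default;
`scan_all_offsets` enables a first-occurrence scan for cassettes with
variable upstream structure. Representation QC reports
assigned-reads-per-guide against a 1000× threshold, the convention for
keeping guide-level depletion measurable.

## Essentiality scoring

Counts are normalized so every sample column sums to the same total
(default: the mean of the raw totals; configurable to a fixed constant —
use a fixed constant when exact depth invariance across re-sequenced
samples matters, since the mean target itself moves with depth). The
per-guide statistic is `log2((final + c)/(initial + c))` with pseudocount
`c = 1` applied to both numerator and denominator: the symmetric form is
finite at zero abundance and is exactly 0 when final equals initial. A
`numerator_only` switch implements the literal one-sided alternative for
comparison; it rejects zero initial abundances. Per-gene ES is the
unweighted mean over the gene's guides; non-targeting guides aggregate
under a sentinel pseudo-gene so the null distribution is reported
alongside real genes.

The biased ES contrasts line groups as `mean(group B) − mean(group A)`
with A the focal group, ranked descending, ties broken lexicographically
by gene symbol for reproducibility. Non-targeting and positive-control
entries are excluded from the ranking by default (they are calibration
controls, not candidate hits) but remain available in the ES table. No
p-values are attached: the screen design has one initial/final pair per
line, so there is no replicate variance to model, and ranking by effect
size is the intended read-out.

## Interactome enrichment

Fold enrichment is the ratio of unique-peptide counts, case over control,
with an explicit zero-denominator policy. The default `floor_one` policy
divides by `max(control, 1)`, so a protein absent from the control
qualifies once its case count reaches the threshold; rows absent from
both conditions are dropped. The alternative `exclude` policy drops
control-absent rows entirely. The interactor rule is inclusive
(ratio ≥ threshold, default 5). Intersection is exact set algebra after
case-insensitive symbol harmonization with an optional alias map, since
affinity-purification and proximity-labeling datasets often use different
accessions for the same protein.

## Loop and peak comparison

Coordinates are 0-based half-open everywhere; two intervals overlap iff
they share a chromosome and ≥1 bp. A test loop is *shared* when a single
reference loop overlaps it left-anchor-to-left-anchor and
right-anchor-to-right-anchor; otherwise *gained*; reference loops matched
by no test loop are *control-only*. Classification uses per-chromosome
interval trees over reference left anchors and is O((n+m) log m); the
test suite checks it against an independent O(n·m) double loop. An
optional symmetric `slop` expands anchors before the overlap test
(default 0). Loop length is the anchor-midpoint distance, which is robust
to anchor-width (bin-size) differences between loop callers; anchor-start
distance is available as an alternative. Peak-set overlap is directional
(a peak counts as overlapping if it hits ≥1 peak in the other set), and
both directions are reported because multi-overlaps make them differ.

## Assay statistics

Competition time courses are normalized to a baseline day (default day 3
post-infection, the earliest read-out after transduction) and optionally
to a co-assayed negative-control guide's same-day value. Drug
sensitization is the day-matched treated/vehicle ratio of sgRNA+
proportions; values below 1 indicate drug-specific depletion. Fiber
restart efficiency is `idu_len / cldu_len` per fork; fibers with a
non-positive CldU tract are excluded with a warning, and zero-IdU fibers
(no restart) are kept with ratio 0 by default, configurable to exclude,
since the biology of a failed restart is informative but some scoring
protocols drop such fibers. Arms are compared with a two-tailed
Mann–Whitney test: exact enumeration when both arms have ≤20 tie-free
values, otherwise the tie-corrected normal approximation — appropriate at
the ≥150 fibers/arm typical of the assay.

## Synthetic data

The generators define the conditions everything is tested under.

**Screen.** The default library mirrors the published design this toolkit
targets: 2405 targeting guides spread as evenly as possible over 381
genes (119 genes get 7 guides, the rest 6), 100 non-targeting guides, and
20 positive-control guides over 6 pan-essential genes. Six cell lines in
two groups (2 focal, 4 other), one initial/final pair each. Counts are
negative-binomial (Gamma–Poisson) with mean = representation (default
1000 reads/guide) and dispersion 0.05 — a tight, plasmid-pool-like spread;
expected final counts multiply the initial mean by `2^effect`. Effects:
0 for non-targeting guides, −3 in every line for positive controls, −2 in
focal lines only for 20 planted biased genes. Read-level output assembles
the stacking-barcode layout with seeded random stagger/padding bases and
a seeded shuffle; sequencing errors are off by default (exact-match
counting is the contract under test) with an optional substitution rate
to exercise unassigned accounting.

**Peptides.** Background proteins draw correlated case/control Poisson
counts around a shared per-protein abundance (uniform on 15–60 unique
peptides). Planted interactors get `case ≥ fold × max(control, 1)` by
construction (default fold 8). Background rows that would satisfy the
fold rule by chance are redrawn (bounded retries) so planted truth and
enriched sets coincide exactly — the generator's ambiguity-avoidance
mirror of the loop generator's collision-free placement. A configurable
subset is planted in both experiments to seed the Venn intersection, with
optional explicit names.

**Loops.** A synthetic genome of 5 × 50 Mb chromosomes with anchors on a
10-kb grid (Hi-C bin resolution). Loop lengths are log-normal with
configurable median (defaults 225 kb reference, 310 kb test) and
log-scale sigma 0.5, chosen to give an approximately two-fold
interquartile spread — typical of loop-call length distributions — while
keeping the sample median of 2,000 loops well within 5% of the target;
lengths snap to the grid. Reference anchors are placed with a one-bin
buffer; shared test loops copy reference anchors with jitter smaller than
half an anchor width, and gained loops avoid all reference anchor bins,
so classification recovers the planted classes exactly.

**What the generators do not emulate:** GC or position-dependent coverage
bias, guide-efficiency heterogeneity within a gene, replicate structure,
peptide shared-sequence ambiguity, loop-strength (contact-count) values,
and realistic base-quality profiles. Passing tests therefore demonstrate
correctness of the computations and recoverability of planted signal
under the stated noise model, not robustness to every artifact of real
sequencing or mass-spectrometry data.

## Problem sizes and numerical choices

The acceptance script runs the screen at full library size and 1000×
representation (5 null seeds + 5 planted-effect seeds), interactome
tables of 2,000 proteins, loop sets of 150 (classification) and 2,000
(length medians) loops, and 1,000 fiber-null replicates at 150
fibers/arm — sizes at which every reported quantity is stable across
seeds. Normalized columns are required to match their target total to
relative 1e−9. Ranking ties break lexicographically. Degenerate inputs
(empty libraries, zero-total samples, empty loop sets, missing baseline
days, non-positive CldU tracts) raise informative errors rather than
propagating NaNs.

## Known limitations

Exact-match counting discards reads with any sequencing error in the
protospacer, biasing absolute counts low at high error rates (relative
depletion is less affected since the loss is shared by both timepoints).
The biased-ES ranking carries no significance estimate by design. Loop
classification treats anchors as unweighted intervals; it does not use
loop strength or FDR annotations from the caller. The Venn peak overlap
does not merge fragmented peaks, so one broad peak overlapping several
narrow ones counts asymmetrically — both directions are reported for this
reason.
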