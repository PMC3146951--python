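# Methods

## The scan model

A protein is screened for a constellation of short motifs whose positions
are constrained relative to predicted transmembrane (TM) segments. Writing
a TM segment as the residue interval `[i, j]` (1-based, inclusive — the
convention used in every file and API of this package), the two
half-windows of a segment are

- C-half: `[⌊(i+j)/2⌋, j + 5]` — the C-terminal half of the TM plus a
  5-residue flank beyond it,
- N-half: `[i − 5, ⌊(i+j)/2⌋]` — the N-terminal half plus a 5-residue
  flank before it,

both clamped to `[1, L]` for a sequence of length `L`. `SxxxH` is searched
in C-half windows and `HxxxH` in N-half windows; a match counts only when
its full 5-residue span lies inside the window. The midpoint uses integer
floor, stated once here and used identically by the scanner, the generator
and the test oracles. Whether a motif overhanging a window edge by one
residue should count is genuinely underdetermined; full containment is this
package's choice, and the brute-force oracle in the tests encodes the same
rule, so the equivalence check is meaningful.

A constellation call pairs one C-half `SxxxH` hit with one N-half `HxxxH`
hit. The pair passes iff the `SxxxH` TM index is strictly smaller than the
`HxxxH` TM index and the index difference is at least `min_tm_separation`
(default 3). In the canonical architecture the motifs sit in TM2 and TM7 —
separation 5, and 7 in SID-1-like architectures with an extra TM pair in
between — and the default is relaxed to 3 to tolerate segments missed by
the topology predictor. "At least 3 TMs apart" is read as an index
difference, not a count of intervening segments; with the canonical
geometry the two readings differ by one, and the index-difference reading
makes the reversed-order case (separation −5) fail both constraints
consistently. All pairs are reported, passing or not, so downstream
filtering is auditable; a protein is positive iff at least one pair passes.

Two scan modes exist. `core` (default) checks only the two
histidine-containing motifs — the pair that defines the executed screening
strategy. `extended` additionally requires at least one literal `D` inside
the N-half window of the TM directly following the SxxxH-bearing one,
reflecting the third conserved motif (a lone aspartate at the start of
TM3). The aspartate motif has no published pattern beyond the single
conserved residue, so the extended mode checks exactly one `D` and is off
by default rather than guessing a stronger pattern.

The naive baseline ignores topology and matches
`S-x(3)-H-x(100,10000)-H-x(3)-H` over the whole sequence: every admissible
spacer length is enumerated, so overlapping and multiply-realised matches
are all reported. Pattern semantics throughout: literals match only the
exact standard residue; the wildcard `x` matches any residue including the
ambiguity letters `X B Z U O J`. Ambiguity letters therefore can never
create a spurious serine/histidine/aspartate call, only fill wildcard
positions.

## TM prediction

The built-in predictor is a transparent stand-in for dedicated topology
tools (the scan consumes any external topology table in the same TSV
dialect, which fully decouples motif calling from predictor quality). It
computes a Kyte–Doolittle window average (window 19, odd; truncated —
not skipped — at the termini so short tails can still host a TM; ambiguity
letters contribute the scale mean, −0.49), thresholds it at 1.6, merges
runs separated by fewer than `merge_gap` = 3 below-threshold positions
(gap residues are absorbed into the merged segment), and discards runs
shorter than `min_tm_len` = 15. Merge-then-filter order is part of the
contract: it lets a single polar active-site residue split a helix without
destroying it, and makes output deterministic. Lowering the threshold can
only grow the above-threshold mask, hence total predicted TM coverage is
monotone in the threshold — one of the tested invariants.

## The synthetic proteome

The generator emulates a multi-pass membrane protein as alternating
hydrophilic loops (10–60 residues) and hydrophobic TM segments (18–25
residues), 7 TMs by default. Positives carry `SxxxH` spanning the TM2
C-boundary (start `j₂−2`), `D` one residue before TM3, and `HxxxH`
spanning the TM7 N-boundary (start `i₇−2`). Placing the motifs astride the
membrane boundary matches their described location at the segment ends
(the scan windows extend 5 residues beyond the TM for the same reason) and
halves the number of polar motif residues inside the hydrophobic core.
Wildcard positions inside planted motifs are drawn from the hydrophobic
alphabet so a planted motif never hydrophilises its segment beyond the
literal S/H/D residues.

Composition defaults were fixed by a design analysis of the predictor's
window arithmetic: with a 19-residue window, threshold 1.6 and minimum run
length 15, an 18-residue TM (the shortest the generator emits) is only
recovered if the boundary windows retain enough margin, which requires a
TM alphabet mean hydropathy near 4 (I/L/V-dominated) and a loop mean near
−0.9 (small polar residues dominating, charged residues a minority —
an all-charged linker at mean ≈ −2 smears short TMs below threshold).
These are the package's standing defaults, not per-run tuning knobs.

Decoy classes violate exactly one constraint each, using the same
backbone: `decoy_order` swaps the motif-bearing TMs (HxxxH at TM2's
N-boundary, SxxxH at TM7's C-boundary — correct windows, reversed order);
`decoy_separation` plants the pair in TM2/TM4 (separation 2); `decoy_window`
plants each motif in the wrong half of its own TM, so the windowed scan
sees nothing; `decoy_no_motif` plants nothing; `soluble` emits a loop-only
sequence with an empty topology. Because loops legitimately contain S and
H, chance motifs can arise; rejection sampling (capped at 1,000 attempts,
then an error) regenerates any decoy that would classify positive under
its planted topology, and for `decoy_no_motif` any draw with a windowed
hit at all. The order decoy's signed separation (−5) necessarily also
fails the separation inequality; the class is defined by the swap, and the
caller records the signed value so the failure mode is visible in the
calls table.

What the benchmark does and does not show: positives satisfy the caller
*by construction*, so planted-topology sensitivity/specificity of 1.0
verifies the scan's logic, not its power on real proteomes. Real membrane
proteins have milder hydrophobicity contrasts, signal peptides, re-entrant
loops and compositional diversity the generator does not model; predictor
performance on the noiseless constructs is an upper bound. The naive-scan
false-positive flood reported for real sequence databases is likewise not
reproduced here — the generator's decoys probe constraint logic, not
database base rates.

## Redundancy filters

`remove_fragments` drops sequences shorter than 100 residues. `dedupe`
performs greedy incremental clustering at 95% identity: records are
visited by decreasing length (ties by id), each joins the first
representative exceeding the threshold, else founds a cluster — so no two
surviving representatives exceed the threshold, by construction.
`group_by_coverage` builds single-linkage groups with an edge when the
per-column score reaches 1.0 and the aligned region covers ≥ 50% of at
least one of the two sequences (one-sided coverage).

All pairwise comparisons use one global BLOSUM62 alignment (biopython
`PairwiseAligner`; gap open 11, extend 1, terminal gaps free). Identity is
identical pairs over alignment columns, where columns span first-to-last
aligned pair and include internal gap columns — stated explicitly because
established tools resolve this denominator differently. The per-column
"bit" score is approximated as half the raw score per column; exact
Karlin–Altschul scaling is deliberately out of scope for what is a
representative-picking heuristic, and the threshold is configurable. No
k-mer prefilter is implemented; the all-pairs cost is O(n²) alignments and
the filters are meant for the set sizes the pipeline produces (hundreds).

## Pipeline and reproducibility

`run_all` executes generate → topology (planted truth or hydropathy
prediction) → fragment/identity filtering → scan → classify → evaluate →
coverage-grouping of the positive calls, writing every intermediate, a
resolved-config snapshot (YAML, with its SHA-256 recorded in every tabular
header), and a log. One global seed fans out to per-stage seeds via stable
hashing of the stage name, so stages are independently reproducible; no
output except the log contains timestamps, making runs byte-identical
under identical config and seed. Config precedence is CLI > file >
defaults; unknown keys fail validation before any stage runs. Default
problem sizes (10 proteins per class for `run_all`, 500 per class in the
acceptance script's classification metrics, 200 random proteins for the
scan-oracle check) keep a full run in seconds-to-minutes on one CPU while
holding the binomial uncertainty on the reported rates to about a
percentage point.

## Known limitations

- The hydropathy predictor has no orientation (in/out) model and no
  signal-peptide handling; the scan does not use membrane sidedness even
  though the three motifs are thought to share a side.
- Identity and score normalisation differ in detail from CD-HIT/BLASTCLUST
  (word filters, exact bit scores); thresholds are comparable in spirit,
  not numerically interchangeable.
- The extended mode's single-`D` check is the weakest defensible reading
  of the third motif; it is off by default.
- `find_pattern` enumerates bounded wildcards explicitly; pathological
  patterns (many wide-bounded wildcards) would be slow, but the shipped
  patterns have at most one wide repeat.
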