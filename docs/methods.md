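# Methods

This note documents the models and procedures implemented in `tecurate`,
the parameters that matter, the numerical conventions, and what the
synthetic study conditions do and do not establish.

## The curation problem

A TE consensus library is a set of representative sequences, one per
family, derived column-wise from alignments of genomic copies. De novo
discovery tools systematically emit fragmented or truncated consensi
(internal-only LTR models, 5'-truncated LINEs), mix diverged variants
under one entry, and duplicate families across entries. Curation means:
recover the copies, separate variants, restore full element length, place
boundaries on real structural signals, and merge redundancy. Every stage
below operates on a rectangular alignment over `{A, C, G, T, N, -}` with
per-row genome provenance.

Column statistics are gap-excluded throughout: a column's nucleotide
proportions are computed over its A/C/G/T count. An input `N` counts
toward the column's nucleotide total (it is sequence, not gap) but
carries no base identity, so it joins neither the proportion numerator
nor denominator. Consequently a `ColumnProfile`'s base counts plus `N`
count plus gaps always sum to the row count.

## Alignment cleaning

**Gap columns** are removed in two passes: (1) gap fraction > 0.8 or
fewer than 5 nucleotides; (2) among survivors, gap fraction in
(0.4, 0.8] with the predominant nucleotide below 0.7 of the column's
nucleotides. Both rules are column-local, so the pass structure does not
change the result, but it is preserved for clarity.

**End cropping** works per row on sliding windows moving inward from each
end, one column at a time:

- *Divergence cropper*: the alignment is first converted to a proportion
  matrix (each cell holds its own base's column proportion; gaps and
  columns with fewer than 5 nucleotides are 0). A window (default 40)
  stops at the first placement whose mean reaches the threshold (default
  0.7); all columns outside the two stopping windows become gaps. A
  polish pass repeats this with window 4 and threshold 1.0, on a
  recomputed proportion matrix (cropping changes proportions).
- *Gap cropper*: same mechanics on the row's own gap indicator; the
  window (default 250) stops when its gap fraction falls below the
  threshold (default 0.1), strictly.

Conventions: the divergence stop uses `mean >= threshold` — a strict
comparison would make the polish pass (threshold 1.0) unable to stop
anywhere and gap every row; the gap stop is strict (`< threshold`) as the
rule is phrased "below". A row with no qualifying window has no conserved
region and becomes all gaps. Cropping converts characters to `-` rather
than deleting them: row, column and shape are preserved, which is what
makes the positionwise cleaning benchmark (below) well-defined. Reported
crop counts are the columns outside the final stopping windows (for the
two-pass divergence cropper, the final pass's extent, in which the first
pass's nests).

## Variant clustering

Divergent columns (every nucleotide proportion < 0.8) and gap blocks
(maximal gap-bearing runs whose adjacent-column gap proportions differ by
≤ 0.10, flanked by columns with a dominant nucleotide > 0.80) are
concatenated into a pseudo-alignment carrying only discriminating signal.
Pairwise Kimura two-parameter distances over it feed neighbor joining
(scikit-bio; negative branch lengths clamped to zero), patristic
distances are divided by the matrix maximum so they lie on [0, 1], and
DBSCAN (scikit-learn, precomputed metric, ε = 0.1, minimum samples 2)
labels the rows. Up to `max_cluster_num` (default 5) clusters proceed, by
size; the noise set is processed as an additional cluster only when it
holds more than 15 sequences, more than 60% of the alignment, and fewer
normal clusters exist than the cap.

Numerical conventions: saturated Kimura distances (log argument ≤ 0) are
capped at 3.0 substitutions/site; row pairs with no comparable site
(possible when truncated copies select disjoint divergent columns) share
no signal and receive the same cap rather than failing the run. The
scalar `k2p_distance` still raises on zero comparable sites. An
externally computed Newick tree can replace the internal NJ step; the
clustering consumes only path lengths. An alignment with nothing to
select (no divergent column, no gap block) is one cluster by definition.

Known limitation: when every variant has exactly the same copy number,
sites mutated in exactly one variant sit exactly at the 0.8 proportion
boundary and are excluded; with many variants the pseudo-alignment then
keeps only saturated multi-variant sites, and NJ on the resulting nearly
flat matrix can distort single tips. Real copy-number imbalance (the
generic case) avoids the degeneracy.

## Extension

Each cluster is extended one end at a time in rounds of 1000 bp per
sequence (strand-aware: "left" is the element's 5' side), capped at
7000 bp per end and clamped at chromosome bounds. Per round only the new
flanks are aligned, gap-column cleaned and gap-cropped; a sequence whose
flank is cropped over 90% has run into unrelated genome and leaves the
round loop for that end. The round consensus (ambiguity rule 0.7 / 5)
is scanned with a 150 bp window from the extending end: when the first
window with `N` fraction < 0.3 lies more than 300 bp from the end, the
flank is dominated by non-homologous sequence and the end is complete (a
consensus with no qualifying window counts as maximally distant).
Afterwards the fully extended sequences are re-extracted, realigned and
gap-column cleaned.

Alignment is pluggable. The internal *coordinate stacker* places rows on
a shared frame by their hit's query offset and pads with gaps — exact for
copies that differ from each other only by substitutions, which is what
the fixture generator produces; a callable hook accepts raw sequences and
returns an alignment for external aligners on real (indel-containing)
data.

## Boundary definition

On the final alignment's consensus (ambiguity 0.8 / 5), sliding 150 bp
windows from both ends first delimit the credible region — the span
between the first windows whose `N` fraction is below 0.2 (windows
included). Boundaries are then set by a cascade:

1. **Terminal repeats.** A seed-and-extend self-comparison of the
   credible consensus (10-mer seeds, X-drop 20, match +1 / mismatch −1),
   direct and against the reverse complement, yields candidate repeat
   pairs. A candidate qualifies when the copies are disjoint, one starts
   in the left terminal zone (25% of the region) and the other ends in
   the right zone, it meets the kind minima (LTR ≥ 100 bp, TIR ≥ 10 bp,
   identity ≥ 0.8), and it passes the relaxed significance gate of the
   self-search: the chance expectation
   `L² · 4^−(matches − 2·mismatches)` must be ≤ 0.05. The gate is what
   keeps chance 10–12 bp inverted matches in multi-kilobase consensi from
   pinning false TIR boundaries; genuine repeats pass it by many orders
   of magnitude. The longer repeat wins when both kinds qualify, and the
   boundary is the distal edge of each copy.
2. **Poly tails**, only when no repeat was found and the classification
   hint contains LINE or SINE: a run of ≥ 10 `A` (3' end) or `T` (5'
   end) with at most one interruption within the terminal 30 bp of the
   credible region (terminal `N` runs are skipped first — they carry no
   sequence), or a user-supplied microsatellite unit (2–6 bp, ≥ 4
   repeats). A 3' tail sets the end boundary; a 5' poly(T) signals minus
   orientation and sets the start.
3. **`N`-window trimming** otherwise: the credible region itself is the
   element.

The two end croppers run afterwards only on the fallback path: a terminal
repeat or tail pins the boundary exactly and everything inside it is
element sequence, whereas the polish pass would erode genuinely
homologous element edges (measured at up to ~17 bp on fixtures).

`finalize_consensus` crops to the boundary columns, emits the ungapped
consensus (`N` kept; all-gap columns dropped, with repeat/tail
coordinates remapped into string coordinates), and flags records for
reclassification when total extension exceeds 4000 bp. Orientation is
decided by the summed length of protein-domain hits per strand when a
domain table is supplied, else by summed ORF lengths (ATG-to-stop, stop
included, ≥ 300 nt, six frames; codons containing `N` never start or
stop); ties keep the current orientation.

## Evaluation and de-duplication

A full-length hit covers > 90% of the consensus at > 85% identity (both
strict). The default level table: Perfect = terminal repeat ∧ classified
∧ MSA ≥ 10 ∧ full-length hits ≥ 5 ∧ coding evidence; Good = classified ∧
MSA ≥ 10 ∧ hits ≥ 5; Reco_check = classified ∧ hits ≥ 2; else
Need_check. All cut-offs are configurable (`EvaluationRules`). Inputs
with at most 10 genomic hits skip the MSA path entirely and face the
low-copy gate: kept as Low_copy only with a terminal repeat and ≥ 2
full-length hits.

Pairwise identity/coverage uses a global alignment with free terminal
gaps (match +1, mismatch −1, gap −2); identity is identical columns over
the shorter sequence's length, coverage the aligned span over each
sequence's length. Greedy clustering visits sequences by decreasing
length and joins the first cluster whose founding (longest) member
satisfies the identity and coverage rule — the incremental convention of
CD-HIT-style tools, under which the clusters need not be transitive
closures. De-duplication: round 1 at identity > 0.90 with shorter-
sequence coverage > 0.90, keeping each cluster's longest Perfect (else
longest Good); all members of clusters without one go to round 2 at
identity > 0.85 with both coverages > 0.80, keeping the longest. The
optional input-library dedup reuses the machinery at 95% / 95% with the
both-sequences rule.

## Benchmarking

- *Cleaning*: three same-shape alignments (original, reference cleaning,
  tool cleaning); over sites that are nucleotides in the original, TP =
  both cleanings gapped the site, FN = reference only, FP = tool only;
  sensitivity, precision, F1.
- *Library recovery*: matches from the internal seed-and-extend
  comparator; per reference sequence: Perfect — one de novo sequence
  alone with identity and reference coverage > 0.95; Good — ≥ 2 matches,
  each > 0.95 identity, union coverage > 0.95; Present — the same at
  0.80 with any match count; else Not found. Coverage is the union of
  matched reference intervals over the reference length.
- *Genome annotation*: annotations (BED or RepeatMasker `.out`) are
  resolved into disjoint typed intervals — overlapping or bookended
  intervals merge, each base takes the type of the longest originating
  interval (ties by a configured type order) — then every base is one
  trial: TP both, FP test only, FN reference only, TN neither;
  sensitivity, specificity, accuracy, precision, F1 and FDR follow, and
  TP+FP+FN+TN equals the genome length. Zero-denominator ratios are
  reported as NaN, never 0.

## Synthetic study conditions

The generator plants structural ground truth: LTR families carry
identical terminal direct repeats, TIR families terminal inverted
repeats, LINE families a 3' poly(A) run; copies are substituted per base
at a configurable rate with a 2:1 transition bias, optionally
5'-truncated, fragmented or nested inside a host copy of another family,
and inserted with target-site duplications into i.i.d. background of GC
content 0.42. Divergence is substitution-only so the coordinate stacker
is exact and every benchmark is positionally well-defined. Defaults
chosen as the realistic regime for a curatable family: 20 rows and 1%
row divergence with 150 bp noise flanks for the cleaning fixtures; 20
copies per planted family (enough for the noise-cluster rescue to
operate); variant fixtures at 12% variant divergence (pairwise ≥ 20%)
with 0.5% copy divergence.

What passing fixtures shows — and does not. The fixtures establish the
window mechanics, the clustering geometry, the extension stop logic and
the boundary cascade against exact truth. They do not contain indels,
sequencing error, low-complexity regions or segmental duplications, so
they say nothing about external-aligner behaviour on gapped alignments
(the aligner hook exists for that), and the internal k-mer search is only
validated to ~20% divergence. Runtime-scale problem sizes were chosen at
desk scale throughout: genomes of 70–210 kb, families of 2–3 kb, 14–20
copies.

## Determinism

All randomness flows from a single integer seed through numpy PCG64
streams (per-input substreams keyed by input index); hit sampling,
generators and the pipeline are reproducible bit-for-bit, outputs contain
no timestamps, and inputs are processed in file order regardless of the
`threads` setting, so a rerun with the same seed writes byte-identical
files.
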