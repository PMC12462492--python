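# tecurate

Automated curation of transposable-element (TE) consensus libraries.

De novo TE discovery tools (RepeatModeler2, EDTA, REPET, ...) produce
consensus libraries whose sequences are frequently fragmented, truncated,
chimeric or redundant; making them usable traditionally requires slow
manual curation of each family's alignment. `tecurate` automates that
curation loop against the source genome: for every input consensus it

1. recovers genomic copies (a supplied 12-column hit table or an internal
   k-mer seeded search),
2. stacks them into a multiple sequence alignment (MSA) and removes gappy
   columns,
3. **clusters** the alignment into TE variants — divergent columns and gap
   blocks form a pseudo-alignment, pairwise Kimura two-parameter distances
   feed a neighbor-joining tree, and DBSCAN (ε = 0.1, minimum samples 2)
   runs on the max-normalised patristic distances, with an oversized noise
   set processed as its own cluster,
4. **extends** each cluster iteratively into the genome (1000 bp per end
   per round, at most 7000 bp per end), stopping an end once the flank
   consensus turns ambiguous — the sliding 150 bp window whose `N`
   fraction first drops below 0.3 must sit more than 300 bp from the end,
5. **defines boundaries** by a cascade: terminal repeats (LTR/TIR) from a
   significance-gated self-comparison of the consensus → poly(A)/poly(T)
   tails for LINE/SINE inputs → sliding-window `N` trimming,
6. **cleans** row ends with two sliding-window croppers (proportion-matrix
   divergence windows and gap-fraction windows),
7. emits an evaluated consensus (Perfect / Good / Reco_check / Need_check /
   Low_copy, from terminal repeats, classification, MSA size, full-length
   hit count and coding evidence), and
8. **de-duplicates** the library in two greedy clustering rounds
   (90% identity / 90% coverage of the shorter sequence, then 85% / 80% of
   both), preferring the longest Perfect or Good representative.

Companion modules implement three benchmarking procedures (per-base MSA
cleaning confusion matrix; Perfect/Good/Present/Not-found library
recovery; six-metric genome-annotation confusion matrix) and a seeded
synthetic-fixture generator (planted LTR/TIR/LINE families with nested,
fragmented and diverged copies, plus truth annotations) so every stage is
testable at desk scale without external aligners or search tools.

## Key definitions

- Column consensus: a column emits its predominant nucleotide iff its
  gap-excluded proportion ≥ *p* and the column holds ≥ 5 nucleotides, else
  `N` (*p* = 0.7 during extension, 0.8 for boundaries).
- Kimura two-parameter distance: with transition fraction *P* and
  transversion fraction *Q* over compared sites,
  *d* = −½ ln(1 − 2*P* − *Q*) − ¼ ln(1 − 2*Q*).
- Full-length hit: genomic match covering > 90% of a consensus at > 85%
  identity.
- Cleaning benchmark: over sites that carry a nucleotide in the original
  MSA, TP = both reference and tool converted the site to a gap;
  sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
  F1 = 2·sens·prec/(sens+prec).

## Worked example

`examples/curate_library.py` plants an LTR family (3000 bp element,
300 bp terminal repeats, 18 copies at 2% divergence) in a 120 kb genome
and feeds the pipeline only the middle 60% of the element:

```
input: 1800 bp fragment of a 3000 bp element
curated consensus: 3000 bp, evaluation Good
terminal repeat: LTR at (0, 300) / (2700, 3000) (planted arms: (0, 300) / (2700, 3000))
identity to the planted element: 1.0000 (extension used: 1000 bp left, 1000 bp right)
```

The pipeline recovered the full element from the fragment: the consensus
is the planted 3000 bp sequence, the terminal-repeat arms sit exactly at
the planted coordinates, and one 1000 bp extension round per end sufficed.
The other examples cover alignment cleaning (`clean_alignment.py`, with
the cleaning confusion matrix), variant separation
(`separate_variants.py`) and the two annotation benchmarks
(`benchmark_annotation.py`).

A thin CLI mirrors the library:

```bash
tecurate make-fixtures --out fx --seed 3          # planted genome + truth
tecurate run --input fx/library.fasta --genome fx/genome.fasta --output out --seed 1
tecurate crop-div in.fasta out.fasta              # and clean-columns, crop-gap,
tecurate benchmark-library ref.fasta denovo.fasta # cluster, dedup, benchmark-*
```

`tecurate run` writes `consensus_all.fasta`, `consensus_merged.fasta`,
`summary.tsv`, `boundary_reports.tsv`, `failed.txt` and `run_log.json`;
reruns with the same seed are byte-identical.

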