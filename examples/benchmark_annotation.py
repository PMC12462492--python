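"""Benchmark a TE library and a genome annotation against references.

Two of the three benchmarking procedures: (1) library recovery — every
reference consensus is rated Perfect / Good / Present / Not found by its
best matches in a de novo library; (2) per-base genome annotation — a test
annotation is scored against a reference annotation with a six-metric
confusion matrix.
"""

import numpy as np

from tecurate import (
    Annotation,
    genome_confusion_matrix,
    library_benchmark,
    resolve_annotation_overlaps,
)
from tecurate.synthetic import mutate_sequence, random_sequence

rng = np.random.default_rng(9)

# --- library recovery ----------------------------------------------------
reference = [("ref_element", random_sequence(2000, rng))]
denovo = [
    ("exact", reference[0][1]),                                  # Perfect
    ("half_a", mutate_sequence(reference[0][1][:1100], 0.03, rng)),
    ("diverged", mutate_sequence(reference[0][1], 0.18, rng)),   # 82% identity
]
for name, lib in [("exact copy", [denovo[0]]),
                  ("two 97% halves", denovo[1:2] + [("half_b", mutate_sequence(reference[0][1][900:], 0.03, rng))]),
                  ("82% full-length", [denovo[2]])]:
    category = library_benchmark(reference, lib)["ref_element"]
    print(f"library with {name:18s} -> {category}")

# --- per-base genome annotation -----------------------------------------
test = resolve_annotation_overlaps([Annotation("chr1", 100, 600, "TE")])
truth = resolve_annotation_overlaps([Annotation("chr1", 0, 500, "TE")])
counts, metrics = genome_confusion_matrix(test, truth, 1000)
print(f"\nannotation of a 1 kb genome, 100 bp offset from truth:")
print(f"  TP={counts.tp} FP={counts.fp} FN={counts.fn} TN={counts.tn}")
print(f"  sensitivity {metrics.sensitivity:.2f}, specificity {metrics.specificity:.2f}, "
      f"accuracy {metrics.accuracy:.2f},")
print(f"  precision {metrics.precision:.2f}, F1 {metrics.f1:.2f}, FDR {metrics.fdr:.2f}")
print("each base is one trial: TP = TE in both annotations, FP = test only, "
      "FN = truth only, TN = neither")
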