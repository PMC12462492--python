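"""Benchmarking: library recovery, per-base annotation, MSA cleaning.

Three independent procedures quantify curation quality:

* :func:`library_benchmark` compares a de novo consensus library against a
  reference library, assigning each reference sequence Perfect (one match
  with >95% similarity and coverage), Good (multiple overlapping matches,
  each >95% similarity, union coverage >95%), Present (the same at the 80%
  tier) or Not found.
* :func:`genome_confusion_matrix` scores genome-wide annotation per base:
  a base is TP when both the test and the reference annotation call it TE
  (or the requested type), FP/FN when only one does, TN when neither;
  six metrics follow (sensitivity, specificity, accuracy, precision, F1,
  false discovery rate), with zero-denominator ratios reported as NaN.
* :func:`msa_cleaning_confusion` scores a cleaning run positionwise
  against a manually cleaned reference over the sites that carried a
  nucleotide in the original alignment: TP when both cleanings gapped the
  site, FN when only the reference did, FP when only the tool did.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import diagonal_matches
from .msa import GAP, Msa

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "Annotation",
    "read_bed",
    "read_repeatmasker_out",
    "resolve_annotation_overlaps",
    "genome_confusion_matrix",
    "msa_cleaning_confusion",
    "library_benchmark",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    fdr: float

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "MetricsReport":
        sens = _ratio(c.tp, c.tp + c.fn)
        spec = _ratio(c.tn, c.tn + c.fp)
        acc = _ratio(c.tp + c.tn, c.total)
        prec = _ratio(c.tp, c.tp + c.fp)
        if math.isnan(sens) or math.isnan(prec) or (sens + prec) == 0:
            f1 = math.nan
        else:
            f1 = 2 * sens * prec / (sens + prec)
        fdr = _ratio(c.fp, c.tp + c.fp)
        return cls(sens, spec, acc, prec, f1, fdr)


@dataclass(frozen=True)
class Annotation:
    """One typed annotation interval (BED semantics)."""

    chrom: str
    start: int
    end: int
    te_type: str


def read_bed(path: str | Path) -> list[Annotation]:
    """Read a BED file with the TE type in column 4."""
    out: list[Annotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            te_type = fields[3] if len(fields) > 3 else "TE"
            out.append(Annotation(fields[0], int(fields[1]), int(fields[2]), te_type))
    return out


def read_repeatmasker_out(path: str | Path) -> list[Annotation]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The three header lines are skipped; rows are whitespace-split with the
    query sequence, 1-based inclusive begin/end and the repeat class/family
    in the standard columns.
    """
    out: list[Annotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[3:]:
        fields = line.split()
        if not fields:
            continue
        chrom = fields[4]
        begin, end = int(fields[5]), int(fields[6])
        te_type = fields[10]
        out.append(Annotation(chrom, begin - 1, end, te_type))
    return out


def resolve_annotation_overlaps(
    annotations: Sequence[Annotation], type_order: Sequence[str] | None = None
) -> list[Annotation]:
    """Resolve overlapping typed intervals into disjoint ones.

    Overlapping or bookended intervals are merged; each base takes the type
    of the longest originating interval, ties broken by ``type_order``
    (then lexicographically).  Returns disjoint, ascending intervals with
    maximal same-type runs merged.
    """
    if not annotations:
        return []
    rank = {t: i for i, t in enumerate(type_order or [])}

    def priority(a: Annotation):
        # painted last wins: longer interval, then earlier type order
        return (a.end - a.start, -rank.get(a.te_type, len(rank)), a.te_type)

    out: list[Annotation] = []
    by_chrom: dict[str, list[Annotation]] = {}
    for a in annotations:
        if a.end <= a.start:
            raise ValueError(f"malformed interval {a}")
        by_chrom.setdefault(a.chrom, []).append(a)

    for chrom in sorted(by_chrom):
        anns = by_chrom[chrom]
        lo = min(a.start for a in anns)
        hi = max(a.end for a in anns)
        canvas = np.full(hi - lo, -1, dtype=np.int64)
        ordered = sorted(range(len(anns)), key=lambda i: priority(anns[i]))
        for i in ordered:
            canvas[anns[i].start - lo : anns[i].end - lo] = i
        # extract runs of identical painted type
        pos = 0
        n = canvas.size
        while pos < n:
            if canvas[pos] < 0:
                pos += 1
                continue
            t = anns[canvas[pos]].te_type
            run_start = pos
            while pos < n and canvas[pos] >= 0 and anns[canvas[pos]].te_type == t:
                pos += 1
            out.append(Annotation(chrom, run_start + lo, pos + lo, t))
    return out


def _mask(
    annotations: Iterable[Annotation],
    chrom_lengths: dict[str, int],
    te_type: str | None,
) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
    for a in annotations:
        if a.chrom not in masks:
            raise ValueError(f"annotation on unknown sequence {a.chrom!r}")
        if a.end > chrom_lengths[a.chrom]:
            raise ValueError(
                f"interval {a.chrom}:{a.start}-{a.end} beyond sequence length"
            )
        if te_type is None or a.te_type == te_type:
            masks[a.chrom][a.start : a.end] = True
    return masks


def genome_confusion_matrix(
    test: Sequence[Annotation],
    reference: Sequence[Annotation],
    genome_length: int | dict[str, int],
    te_type: str | None = None,
) -> tuple[ConfusionCounts, MetricsReport]:
    """Per-base confusion matrix of a test annotation against a reference.

    ``genome_length`` is either a total length (single unnamed sequence
    assumed) or a per-sequence length map.  With ``te_type`` the positive
    class is restricted to that type in both annotation sets; otherwise
    any TE annotation counts.  TP+FP+FN+TN always equals the genome
    length.
    """
    if isinstance(genome_length, int):
        chroms = {a.chrom for a in test} | {a.chrom for a in reference}
        if len(chroms) > 1:
            raise ValueError("scalar genome_length with multiple sequences")
        name = chroms.pop() if chroms else "genome"
        lengths = {name: genome_length}
    else:
        lengths = dict(genome_length)
    test_masks = _mask(test, lengths, te_type)
    ref_masks = _mask(reference, lengths, te_type)
    tp = fp = fn = tn = 0
    for chrom in lengths:
        t, r = test_masks[chrom], ref_masks[chrom]
        tp += int((t & r).sum())
        fp += int((t & ~r).sum())
        fn += int((~t & r).sum())
        tn += int((~t & ~r).sum())
    counts = ConfusionCounts(tp, fp, fn, tn)
    return counts, MetricsReport.from_counts(counts)


def msa_cleaning_confusion(
    original: Msa, reference_cleaned: Msa, tool_cleaned: Msa
) -> tuple[ConfusionCounts, MetricsReport]:
    """Positionwise cleaning benchmark over original-nucleotide sites.

    All three alignments must have identical shape and row order.  Sites
    that are gaps in the original are skipped; over the rest, TP counts
    sites gapped by both the reference and the tool cleaning, FN sites
    gapped only by the reference, FP sites gapped only by the tool.
    """
    if not (original.matrix.shape == reference_cleaned.matrix.shape == tool_cleaned.matrix.shape):
        raise ValueError("the three alignments must have identical shape")
    if not (original.ids == reference_cleaned.ids == tool_cleaned.ids):
        raise ValueError("the three alignments must have identical row order")
    site = original.matrix != GAP
    ref_gap = reference_cleaned.matrix == GAP
    tool_gap = tool_cleaned.matrix == GAP
    tp = int((site & ref_gap & tool_gap).sum())
    fn = int((site & ref_gap & ~tool_gap).sum())
    fp = int((site & ~ref_gap & tool_gap).sum())
    tn = int((site & ~ref_gap & ~tool_gap).sum())
    counts = ConfusionCounts(tp, fp, fn, tn)
    return counts, MetricsReport.from_counts(counts)


def _reference_matches(
    reference: str, library: Sequence[tuple[str, str]], min_identity: float, k: int
) -> list[tuple[str, int, int, float]]:
    """Local matches of library sequences onto one reference sequence:
    ``(library_id, ref_start, ref_end, identity)``."""
    from .msa import reverse_complement

    out = []
    for lib_id, lib_seq in library:
        for oriented in (lib_seq, reverse_complement(lib_seq)):
            for qs, qe, ts, te, n_match in diagonal_matches(oriented, reference, k=k):
                seg_len = qe - qs
                identity = n_match / seg_len
                if seg_len >= k and identity > min_identity:
                    out.append((lib_id, ts, te, identity))
    return out


def _union_coverage(intervals: list[tuple[int, int]], length: int) -> float:
    if not intervals:
        return 0.0
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(s, 0) : min(e, length)] = True
    return mask.sum() / length


def library_benchmark(
    reference: Sequence[tuple[str, str]],
    denovo: Sequence[tuple[str, str]],
    high: float = 0.95,
    low: float = 0.80,
    k: int = 12,
) -> dict[str, str]:
    """Categorise every reference sequence by its recovery in ``denovo``.

    Both libraries are ``(id, sequence)`` lists.  Perfect: one de novo
    sequence alone matches with identity and reference coverage above
    ``high``.  Good: at least two matches, each above ``high`` identity,
    whose union covers more than ``high`` of the reference.  Present: the
    same with both thresholds lowered to ``low`` (any match count).  Else
    Not found.  Matches come from the internal seed-and-extend comparator.
    """
    if not reference or not denovo:
        raise ValueError("both libraries must be non-empty")
    categories: dict[str, str] = {}
    for ref_id, ref_seq in reference:
        matches = _reference_matches(ref_seq, denovo, min_identity=low, k=k)
        length = len(ref_seq)

        per_seq: dict[str, list[tuple[int, int, float]]] = {}
        for lib_id, ts, te, ident in matches:
            per_seq.setdefault(lib_id, []).append((ts, te, ident))

        def weighted_identity(segs: list[tuple[int, int, float]]) -> float:
            total = sum(e - s for s, e, _ in segs)
            return sum((e - s) * i for s, e, i in segs) / total if total else 0.0

        perfect = any(
            weighted_identity(segs) > high
            and _union_coverage([(s, e) for s, e, _ in segs], length) > high
            for segs in per_seq.values()
        )
        high_matches = [(s, e) for _l, s, e, i in matches if i > high]
        good = (
            len(high_matches) >= 2 and _union_coverage(high_matches, length) > high
        )
        low_matches = [(s, e) for _l, s, e, i in matches if i > low]
        present = _union_coverage(low_matches, length) > low

        if perfect:
            categories[ref_id] = "Perfect"
        elif good:
            categories[ref_id] = "Good"
        elif present:
            categories[ref_id] = "Present"
        else:
            categories[ref_id] = "Not found"
    return categories
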