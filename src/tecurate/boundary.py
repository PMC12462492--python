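"""TE boundary definition on the extended, cleaned alignment.

The extension step deliberately overshoots the element, so the final
alignment carries non-homologous flanking sequence at both ends.  Its
column consensus (``N`` at every column where the predominant nucleotide is
below 0.8 or fewer than five nucleotides are present) separates element
from flank: flanks are N-rich because unrelated loci disagree.  Boundaries
are then defined by a three-step cascade:

1. *terminal repeats* — an internal self-comparison of the consensus (both
   direct and against its reverse complement) looks for LTR (direct) or TIR
   (inverted) repeat pairs near the two ends; the element boundary is the
   distal edge of each repeat copy;
2. *poly tails* — when no terminal repeat is found and the classification
   hint contains LINE or SINE, configured poly-patterns (poly(A)/poly(T)
   runs, microsatellite units) define the 3' boundary;
3. *N-window trimming* — otherwise a 150 bp window slides inward from each
   end of the consensus until its N fraction drops below 0.2, and only the
   columns between (and including) the two stopping windows are kept.

Afterwards the divergence- and gap-based end croppers remove residual
divergent row ends, and the final ungapped consensus is emitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cleaning import (
    CropDivergenceParams,
    CropGapParams,
    crop_end_by_divergence,
    crop_end_by_gap,
)
from .extension import n_window_stop
from .genome import diagonal_matches
from .msa import (
    ConsensusParams,
    Msa,
    consensus_with_ambiguity,
    nucleotide_counts,
    reverse_complement,
    reverse_complement_msa,
)

__all__ = [
    "TerminalRepeat",
    "PolyTail",
    "BoundaryParams",
    "BoundaryResult",
    "ConsensusRecord",
    "NoTeRegionError",
    "detect_terminal_repeats",
    "detect_poly_tail",
    "define_boundaries",
    "finalize_consensus",
    "find_orfs",
    "Orf",
    "orient_consensus",
]


class NoTeRegionError(ValueError):
    """The alignment contains no credible TE region (boundaries collapse)."""


def _match_evalue(length: int, matches: int, seg_len: int) -> float:
    """Expected count of an equally strong ungapped self-match by chance.

    A simple word-count estimate for the relaxed significance gate of the
    self-comparison: an ungapped segment with ``matches`` matches and
    ``seg_len - matches`` mismatches is scored ``matches - 2 * mismatches``
    and its chance expectation over an ``length x length`` comparison is
    ``length^2 * 4^(-score)``.  Short perfect matches (10-12 bp) in a
    multi-kilobase consensus are expected by chance and rejected; genuine
    terminal repeats score far below any threshold.
    """
    score = matches - 2 * (seg_len - matches)
    return float(length) * float(length) * 4.0 ** (-score)


@dataclass(frozen=True)
class TerminalRepeat:
    """A pair of terminal repeat copies on the consensus.

    ``kind`` is ``"LTR"`` for direct repeats and ``"TIR"`` for inverted
    ones; intervals are half-open consensus coordinates.
    """

    kind: str
    left: tuple[int, int]
    right: tuple[int, int]
    identity: float

    @property
    def length(self) -> int:
        return self.left[1] - self.left[0]


@dataclass(frozen=True)
class PolyTail:
    kind: str  # "polyA", "polyT" or a motif unit
    interval: tuple[int, int]
    end: str  # "5p" or "3p"


@dataclass(frozen=True)
class BoundaryParams:
    consensus: ConsensusParams = field(
        default_factory=lambda: ConsensusParams(min_proportion=0.8, min_count=5)
    )
    n_window: int = 150
    n_stop_threshold: float = 0.2
    tr_min_len_ltr: int = 100
    tr_min_len_tir: int = 10
    tr_min_identity: float = 0.8
    tr_terminal_zone: float = 0.25
    tr_seed: int = 10
    tr_max_evalue: float = 0.05
    poly_min_run: int = 10
    poly_max_interruptions: int = 1
    poly_zone: int = 30
    poly_motifs: tuple[str, ...] = ()
    crop_divergence: CropDivergenceParams = field(default_factory=CropDivergenceParams)
    crop_gap: CropGapParams = field(default_factory=CropGapParams)


@dataclass
class BoundaryResult:
    start_col: int
    end_col: int
    terminal_repeat: TerminalRepeat | None
    tail: PolyTail | None
    msa: Msa  # end-cropped alignment, same column frame as the input


@dataclass
class ConsensusRecord:
    """A curated TE consensus with its supporting annotation."""

    name: str
    consensus: str
    classification: str = "Unknown"
    terminal_repeat: TerminalRepeat | None = None
    tail: PolyTail | None = None
    start_col: int = 0
    end_col: int = 0
    msa_size: int = 0
    left_ext: int = 0
    right_ext: int = 0
    reclassify: bool = False
    evaluation: str = ""
    input_id: str = ""
    cluster_index: int = 0

    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def classified(self) -> bool:
        cls = self.classification
        return bool(cls) and not cls.lower().startswith("unknown")


def detect_terminal_repeats(
    consensus: str, params: BoundaryParams | None = None
) -> TerminalRepeat | None:
    """Find the best LTR (direct) or TIR (inverted) terminal repeat pair.

    An internal seed-and-extend comparison of the consensus against itself
    (direct) and against its reverse complement (inverted) collects
    candidate repeat pairs; a candidate qualifies when the two copies are
    disjoint, one starts within the left terminal zone, the other ends
    within the right terminal zone, and the kind-specific length and
    identity minima are met.  When both a direct and an inverted candidate
    qualify, the longer repeat wins.  The trivial full-length self match is
    excluded.
    """
    params = params or BoundaryParams()
    length = len(consensus)
    if length < 2 * params.tr_min_len_tir:
        return None
    zone = params.tr_terminal_zone * length
    candidates: list[TerminalRepeat] = []

    for qs, qe, ts, te, n_match in diagonal_matches(
        consensus, consensus, k=params.tr_seed, skip_self=True
    ):
        if ts < qs:  # each pair appears twice; keep left copy first
            continue
        seg_len = qe - qs
        identity = n_match / seg_len
        if (
            qe <= ts
            and qs < zone
            and te > length - zone
            and seg_len >= params.tr_min_len_ltr
            and identity >= params.tr_min_identity
            and _match_evalue(length, n_match, seg_len) <= params.tr_max_evalue
        ):
            candidates.append(TerminalRepeat("LTR", (qs, qe), (ts, te), identity))

    rc = reverse_complement(consensus)
    seen: set[tuple[int, int, int, int]] = set()
    for qs, qe, ts, te, n_match in diagonal_matches(consensus, rc, k=params.tr_seed):
        # a match against the reverse complement at [ts, te) corresponds to
        # the inverted copy [length-te, length-ts) of the forward sequence
        left = (qs, qe)
        right = (length - te, length - ts)
        if right[0] < left[0]:
            left, right = right, left
        if left[1] > right[0]:
            continue  # copies overlap
        key = (*left, *right)
        if key in seen:
            continue
        seen.add(key)
        seg_len = qe - qs
        identity = n_match / seg_len
        if (
            left[0] < zone
            and right[1] > length - zone
            and seg_len >= params.tr_min_len_tir
            and identity >= params.tr_min_identity
            and _match_evalue(length, n_match, seg_len) <= params.tr_max_evalue
        ):
            candidates.append(TerminalRepeat("TIR", left, right, identity))

    if not candidates:
        return None
    return max(candidates, key=lambda tr: (tr.length, tr.identity))


def _find_poly_run(
    segment: str, base: str, min_run: int, max_interruptions: int
) -> tuple[int, int] | None:
    """Longest stretch of ``base`` with at most ``max_interruptions``
    non-matching characters, trimmed to matching ends; None below
    ``min_run``.  Coordinates are relative to ``segment``."""
    best: tuple[int, int] | None = None
    positions = [i for i, ch in enumerate(segment) if ch == base]
    if not positions:
        return None
    # two-pointer over matching positions allowing limited interruptions
    lo = 0
    for hi in range(len(positions)):
        while positions[hi] - positions[lo] - (hi - lo) > max_interruptions:
            lo += 1
        start, end = positions[lo], positions[hi] + 1
        if end - start >= min_run and (best is None or end - start > best[1] - best[0]):
            best = (start, end)
    return best


def detect_poly_tail(
    consensus: str,
    classification_hint: str,
    params: BoundaryParams | None = None,
) -> PolyTail | None:
    """Look for a poly(A)/poly(T) run or configured motif at the termini.

    Only meaningful for LINE/SINE-like elements (the caller gates on the
    classification hint); a poly(A) run in the 3' terminal zone defines the
    3' boundary, a poly(T) run at the 5' start signals a minus-orientation
    element.
    """
    params = params or BoundaryParams()
    hint = (classification_hint or "").upper()
    if "LINE" not in hint and "SINE" not in hint:
        return None
    # terminal N runs carry no sequence; the terminal zones start at the
    # first/last unambiguous base
    first = next((i for i, ch in enumerate(consensus) if ch != "N"), 0)
    last = next((i for i in range(len(consensus), 0, -1) if consensus[i - 1] != "N"), 0)
    if last <= first:
        return None
    zone = min(params.poly_zone, last - first)

    tail_seg = consensus[last - zone : last]
    run = _find_poly_run(tail_seg, "A", params.poly_min_run, params.poly_max_interruptions)
    if run:
        return PolyTail("polyA", (last - zone + run[0], last - zone + run[1]), "3p")

    head_seg = consensus[first : first + zone]
    run = _find_poly_run(head_seg, "T", params.poly_min_run, params.poly_max_interruptions)
    if run:
        return PolyTail("polyT", (first + run[0], first + run[1]), "5p")

    for unit in params.poly_motifs:
        if not (2 <= len(unit) <= 6):
            continue
        pattern = re.compile(f"(?:{re.escape(unit)}){{4,}}")
        matches = list(pattern.finditer(tail_seg))
        if matches:
            m = matches[-1]
            return PolyTail(unit, (last - zone + m.start(), last - zone + m.end()), "3p")
    return None


def define_boundaries(
    msa: Msa,
    classification_hint: str = "",
    params: BoundaryParams | None = None,
) -> BoundaryResult:
    """Locate element boundaries on a cleaned, extended alignment.

    The N-consensus first delimits a credible (low-ambiguity) region via
    the sliding N windows; terminal-repeat and poly-tail detection then
    operate within it, following the cascade described in the module
    docstring.  The divergence- and gap-based end croppers are applied to
    the alignment afterwards (columns are preserved, so the returned
    boundary columns stay valid).
    """
    params = params or BoundaryParams()
    consensus = consensus_with_ambiguity(msa, params.consensus)
    width = msa.width

    left = n_window_stop(consensus, "left", params.n_window, params.n_stop_threshold)
    right_dist = n_window_stop(consensus, "right", params.n_window, params.n_stop_threshold)
    region_start, region_end = left, width - right_dist
    if region_start >= region_end:
        raise NoTeRegionError("no credible TE region: ambiguity never falls below threshold")

    tr = detect_terminal_repeats(consensus[region_start:region_end], params)
    tail = None
    if tr is not None:
        tr = TerminalRepeat(
            tr.kind,
            (tr.left[0] + region_start, tr.left[1] + region_start),
            (tr.right[0] + region_start, tr.right[1] + region_start),
            tr.identity,
        )
        start_col, end_col = tr.left[0], tr.right[1]
    else:
        tail = detect_poly_tail(
            consensus[region_start:region_end], classification_hint, params
        )
        if tail is not None:
            iv = (tail.interval[0] + region_start, tail.interval[1] + region_start)
            tail = replace(tail, interval=iv)
            if tail.end == "3p":
                start_col, end_col = region_start, iv[1]
            else:
                start_col, end_col = iv[0], region_end
        else:
            start_col, end_col = region_start, region_end

    if start_col >= end_col:
        raise NoTeRegionError("boundaries collapsed")

    if tr is None and tail is None:
        # boundaries rest on the coarse N windows alone: scrub residual
        # divergent row ends.  A terminal repeat or poly tail pins the
        # boundary exactly, and the columns inside it are element sequence;
        # eroding them (the polish pass gaps columns lacking a perfectly
        # conserved neighbourhood) would only shorten the consensus.
        cropped, _ = crop_end_by_divergence(msa, params.crop_divergence)
        cropped, _ = crop_end_by_gap(cropped, params.crop_gap)
    else:
        cropped = msa
    return BoundaryResult(start_col, end_col, tr, tail, cropped)


def finalize_consensus(
    msa: Msa,
    start_col: int,
    end_col: int,
    params: BoundaryParams | None = None,
    *,
    name: str = "consensus",
    classification: str = "Unknown",
    terminal_repeat: TerminalRepeat | None = None,
    tail: PolyTail | None = None,
    left_ext: int = 0,
    right_ext: int = 0,
    input_id: str = "",
    cluster_index: int = 0,
    reclassify_threshold: int = 4000,
) -> ConsensusRecord:
    """Crop the alignment to the boundary columns and emit the consensus.

    The consensus keeps ``N`` at ambiguous columns but contains no gaps
    (all-gap columns are dropped).  The record is flagged for
    reclassification when the total extension exceeds
    ``reclassify_threshold`` (default 4000 bp), since heavily extended
    elements may have outgrown their original classification.
    """
    params = params or BoundaryParams()
    if not (0 <= start_col < end_col <= msa.width):
        raise ValueError("invalid boundary columns")
    sub = msa.take_columns(range(start_col, end_col))
    raw = consensus_with_ambiguity(sub, params.consensus)
    nongap = nucleotide_counts(sub).sum(axis=0) + (sub.matrix == 4).sum(axis=0)
    kept = nongap > 0
    consensus = "".join(ch for ch, k in zip(raw, kept) if k)
    # map column coordinates into consensus-string coordinates (all-gap
    # columns are dropped from the string)
    prefix = np.concatenate([[0], np.cumsum(kept)])

    def to_string_coord(col: int) -> int:
        return int(prefix[min(max(col - start_col, 0), end_col - start_col)])

    if terminal_repeat is not None:
        terminal_repeat = TerminalRepeat(
            terminal_repeat.kind,
            (to_string_coord(terminal_repeat.left[0]), to_string_coord(terminal_repeat.left[1])),
            (to_string_coord(terminal_repeat.right[0]), to_string_coord(terminal_repeat.right[1])),
            terminal_repeat.identity,
        )
    if tail is not None:
        tail = replace(
            tail,
            interval=(to_string_coord(tail.interval[0]), to_string_coord(tail.interval[1])),
        )
    return ConsensusRecord(
        name=name,
        consensus=consensus,
        classification=classification,
        terminal_repeat=terminal_repeat,
        tail=tail,
        start_col=start_col,
        end_col=end_col,
        msa_size=msa.n_rows,
        left_ext=left_ext,
        right_ext=right_ext,
        reclassify=(left_ext + right_ext) > reclassify_threshold,
        input_id=input_id,
        cluster_index=cluster_index,
    )


@dataclass(frozen=True)
class Orf:
    start: int  # half-open nucleotide coordinates on the forward sequence
    end: int
    strand: str
    frame: int

    @property
    def length(self) -> int:
        return self.end - self.start


_STOPS = {"TAA", "TAG", "TGA"}


def _scan_frames(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    out = []
    n = len(seq)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                if pos + 3 - start >= min_len:
                    out.append((start, pos + 3, frame))
                start = None
    return out


def find_orfs(consensus: str, min_len: int = 300) -> list[Orf]:
    """Open reading frames (ATG to stop, stop included) on all six frames.

    Coordinates are half-open on the forward sequence; codons containing
    ``N`` never act as start or stop.
    """
    seq = consensus.upper()
    orfs = [Orf(s, e, "+", f) for s, e, f in _scan_frames(seq, min_len)]
    rc = reverse_complement(seq)
    n = len(seq)
    orfs += [Orf(n - e, n - s, "-", f) for s, e, f in _scan_frames(rc, min_len)]
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def orient_consensus(
    record: ConsensusRecord,
    msa: Msa,
    domain_hits: Sequence[tuple[tuple[int, int], str, int]] | None = None,
    orf_min_len: int = 300,
) -> tuple[ConsensusRecord, Msa]:
    """Reverse complement the record and alignment if the evidence is on
    the minus strand.

    Protein-domain hits (``((start, end), strand, length)``) decide by the
    majority of summed lengths; without a domain table the summed ORF
    lengths per strand decide.  Ties, or the absence of any evidence, keep
    the current orientation.
    """
    plus = minus = 0
    if domain_hits:
        for _iv, strand, hit_len in domain_hits:
            if strand == "-":
                minus += hit_len
            else:
                plus += hit_len
    else:
        for orf in find_orfs(record.consensus, min_len=orf_min_len):
            if orf.strand == "-":
                minus += orf.length
            else:
                plus += orf.length
    if minus <= plus:
        return record, msa

    length = len(record.consensus)
    flipped = replace_record_orientation(record, length)
    return flipped, reverse_complement_msa(msa)


def replace_record_orientation(record: ConsensusRecord, length: int) -> ConsensusRecord:
    """Mirror a record's consensus and annotations onto the minus strand."""

    def mirror(iv: tuple[int, int]) -> tuple[int, int]:
        return (length - iv[1], length - iv[0])

    tr = record.terminal_repeat
    if tr is not None:
        tr = TerminalRepeat(tr.kind, mirror(tr.right), mirror(tr.left), tr.identity)
    tail = record.tail
    if tail is not None:
        tail = PolyTail(
            tail.kind, mirror(tail.interval), "5p" if tail.end == "3p" else "3p"
        )
    return replace(
        record,
        consensus=reverse_complement(record.consensus),
        terminal_repeat=tr,
        tail=tail,
    )
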