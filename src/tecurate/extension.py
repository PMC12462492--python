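"""Iterative boundary-seeking extension of a clustered alignment.

De novo TE consensus sequences are frequently truncated.  To recover the
full element, every sequence of a clustered alignment is extended into the
genome, one end at a time, in steps (default 1000 bp per end per round, at
most 7000 bp per end).  After each round only the newly added flanks are
aligned and cleaned; each sequence whose new flank is almost entirely
cropped by the gap-based end cropper (more than 90%) has reached unrelated
flanking genome and drops out of later rounds.  The round consensus (with
``N`` marking ambiguous columns at the 0.7 / 5 rule) is scanned with a
sliding window from the extending end: once the first window whose ``N``
fraction falls below 0.3 sits more than 300 bp from that end, the flank is
dominated by non-homologous sequence and the end is complete.  Finally the
fully extended sequences are re-extracted, realigned and gap-column
cleaned.

Alignment is pluggable.  The internal *coordinate stacker* places rows by
their stack anchor (query-coordinate offset of the originating hit), which
is exact for fixtures whose copies differ only by substitutions; a callable
hook accepts raw sequences and returns an :class:`~tecurate.msa.Msa` for
external aligners.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .cleaning import (
    CropGapParams,
    GapColumnParams,
    crop_end_by_gap,
    remove_gap_columns,
)
from .genome import Genome, GenomeInterval
from .msa import GAP, ConsensusParams, Msa, consensus_with_ambiguity, encode

__all__ = [
    "ExtensionParams",
    "SequenceState",
    "ExtensionState",
    "ExtensionResult",
    "AlignerError",
    "stack_by_anchor",
    "n_window_stop",
    "extend_and_extract",
    "run_extension",
]

Aligner = Callable[[Mapping[str, str]], Msa]


class AlignerError(RuntimeError):
    """The alignment hook failed during an extension round."""


@dataclass(frozen=True)
class ExtensionParams:
    step: int = 1000
    max_total: int = 7000
    exclusion_fraction: float = 0.90
    n_window: int = 150
    n_threshold: float = 0.3
    stop_margin: int = 300
    consensus: ConsensusParams = field(
        default_factory=lambda: ConsensusParams(min_proportion=0.7, min_count=5)
    )
    gap_column: GapColumnParams = field(default_factory=GapColumnParams)
    crop_gap: CropGapParams = field(default_factory=CropGapParams)

    def __post_init__(self) -> None:
        if self.step < 1 or self.max_total < self.step:
            raise ValueError("require step >= 1 and max_total >= step")


@dataclass
class SequenceState:
    """Per-sequence extension bookkeeping.

    ``anchor`` is the row's stack offset (query coordinate of its hit) and
    ``core_len`` the length of the originally extracted sequence, so the
    row occupies stack span ``[anchor - left_ext, anchor + core_len +
    right_ext)``.
    """

    interval: GenomeInterval
    anchor: int
    core_len: int
    left_ext: int = 0
    right_ext: int = 0
    active_left: bool = True
    active_right: bool = True

    def active(self, end: str) -> bool:
        return self.active_left if end == "left" else self.active_right

    def deactivate(self, end: str) -> None:
        if end == "left":
            self.active_left = False
        else:
            self.active_right = False

    def extension(self, end: str) -> int:
        return self.left_ext if end == "left" else self.right_ext


ExtensionState = dict[str, SequenceState]


@dataclass
class ExtensionResult:
    msa: Msa
    state: ExtensionState
    left_total: int
    right_total: int
    rounds: dict[str, int]


def stack_by_anchor(spans: Mapping[str, tuple[int, int]], seqs: Mapping[str, str]) -> Msa:
    """Place sequences on a common coordinate frame, padding with gaps.

    ``spans[sid] = (lo, hi)`` gives each sequence's half-open span in stack
    coordinates; ``len(seqs[sid])`` must equal ``hi - lo``.
    """
    lo = min(s[0] for s in spans.values())
    hi = max(s[1] for s in spans.values())
    width = hi - lo
    ids = list(spans)
    mat = np.full((len(ids), width), GAP, dtype=np.uint8)
    for r, sid in enumerate(ids):
        s_lo, s_hi = spans[sid]
        seq = seqs[sid]
        if len(seq) != s_hi - s_lo:
            raise ValueError(f"sequence {sid!r} does not fill its span")
        mat[r, s_lo - lo : s_hi - lo] = encode(seq)
    return Msa(ids, mat)


def n_window_stop(consensus: str, end: str, window: int, threshold: float) -> int:
    """Distance from ``end`` to the first window whose N fraction is below
    ``threshold``; the full length when no window qualifies."""
    width = len(consensus)
    if width == 0:
        return 0
    window = min(window, width)
    n_mask = np.frombuffer(consensus.encode(), dtype=np.uint8) == ord("N")
    csum = np.concatenate([[0], np.cumsum(n_mask)])
    placements = range(width - window + 1)
    if end == "right":
        placements = reversed(placements)
    for s in placements:
        frac = (csum[s + window] - csum[s]) / window
        if frac < threshold:
            return s if end == "left" else width - (s + window)
    return width


def _grow(genome: Genome, st: SequenceState, end: str, step: int, cap: int) -> tuple[str, bool]:
    """Grow one sequence's interval by up to ``step`` on the requested
    element end (strand-aware).  Returns the newly added oriented flank and
    whether the growth was clipped by the chromosome bound."""
    step = min(step, cap - st.extension(end))
    if step <= 0:
        return "", False
    iv = st.interval
    genomic_left = (end == "left") == (iv.strand == "+")
    chrom_len = genome.lengths[iv.chrom]
    if genomic_left:
        new_start = max(0, iv.start - step)
        added = iv.start - new_start
        flank_iv = GenomeInterval(iv.chrom, new_start, iv.start, iv.strand) if added else None
        st.interval = replace(iv, start=new_start)
    else:
        new_end = min(chrom_len, iv.end + step)
        added = new_end - iv.end
        flank_iv = GenomeInterval(iv.chrom, iv.end, new_end, iv.strand) if added else None
        st.interval = replace(iv, end=new_end)
    if end == "left":
        st.left_ext += added
    else:
        st.right_ext += added
    return (genome.fetch(flank_iv) if flank_iv else ""), added < step


def extend_and_extract(
    state: ExtensionState, end: str, step: int, genome: Genome, max_total: int = 7000
) -> dict[str, str]:
    """Extend every active sequence by ``step`` on ``end`` and return the
    newly added oriented flank sequences.  Sequences whose interval cannot
    grow (chromosome edge or extension cap) are deactivated for that end.
    """
    if end not in ("left", "right"):
        raise ValueError("end must be 'left' or 'right'")
    flanks: dict[str, str] = {}
    for sid, st in state.items():
        if not st.active(end):
            continue
        flank, clipped = _grow(genome, st, end, step, max_total)
        if not flank:
            st.deactivate(end)
            continue
        flanks[sid] = flank
        if clipped or st.extension(end) >= max_total:
            st.deactivate(end)
    return flanks


def _round_spans(state: ExtensionState, end: str, flanks: Mapping[str, str]):
    """Stack spans for this round's flanks, anchored in stack coordinates."""
    spans = {}
    for sid, flank in flanks.items():
        st = state[sid]
        if end == "left":
            hi = st.anchor - (st.left_ext - len(flank))
            spans[sid] = (hi - len(flank), hi)
        else:
            lo = st.anchor + st.core_len + (st.right_ext - len(flank))
            spans[sid] = (lo, lo + len(flank))
    return spans


def run_extension(
    msa: Msa,
    genome: Genome,
    params: ExtensionParams | None = None,
    anchors: Mapping[str, int] | None = None,
    aligner: Aligner | None = None,
) -> ExtensionResult:
    """Run the per-end iterative extension on a clustered alignment.

    Every row must carry provenance (its genome interval of origin).
    ``anchors`` gives each row's stack offset for the internal coordinate
    stacker (default 0 for all rows, correct when every row spans the same
    query region); supplying ``aligner`` replaces the stacker with an
    external alignment hook for both the per-round flank alignments and
    the final realignment.
    """
    params = params or ExtensionParams()
    missing = [sid for sid in msa.ids if sid not in msa.provenance]
    if missing:
        raise ValueError(f"rows without provenance cannot be extended: {missing[:3]}")
    anchors = dict(anchors or {})
    state: ExtensionState = {
        sid: SequenceState(
            interval=msa.provenance[sid],
            anchor=int(anchors.get(sid, 0)),
            core_len=msa.provenance[sid].length,
        )
        for sid in msa.ids
    }

    rounds = {"left": 0, "right": 0}
    for end in ("left", "right"):
        while True:
            if not any(st.active(end) for st in state.values()):
                break
            flanks = extend_and_extract(state, end, params.step, genome, params.max_total)
            if not flanks:
                break
            rounds[end] += 1
            try:
                if aligner is not None:
                    round_msa = aligner(flanks)
                else:
                    round_msa = stack_by_anchor(_round_spans(state, end, flanks), flanks)
            except Exception as exc:  # noqa: BLE001 - reported with context
                raise AlignerError(
                    f"alignment failed in round {rounds[end]} of {end}-end extension"
                ) from exc
            cleaned, _ = remove_gap_columns(round_msa, params.gap_column)
            if cleaned.width == 0:
                # nothing alignable in the new flanks: the end is done
                for st in state.values():
                    st.deactivate(end)
                break
            cropped, crop_counts = crop_end_by_gap(cleaned, params.crop_gap)
            for row, sid in enumerate(cropped.ids):
                if crop_counts[row] > params.exclusion_fraction * cropped.width:
                    state[sid].deactivate(end)
            consensus = consensus_with_ambiguity(cropped, params.consensus)
            distance = n_window_stop(consensus, end, params.n_window, params.n_threshold)
            if distance > params.stop_margin:
                for st in state.values():
                    st.deactivate(end)
                break

    # re-extract the fully extended sequences and realign
    seqs = {sid: genome.fetch(st.interval) for sid, st in state.items()}
    if aligner is not None:
        final = aligner(seqs)
    else:
        spans = {
            sid: (
                st.anchor - st.left_ext,
                st.anchor + st.core_len + st.right_ext,
            )
            for sid, st in state.items()
        }
        final = stack_by_anchor(spans, seqs)
    final.provenance = {sid: st.interval for sid, st in state.items()}
    final, _ = remove_gap_columns(final, params.gap_column)
    left_total = max((st.left_ext for st in state.values()), default=0)
    right_total = max((st.right_ext for st in state.values()), default=0)
    return ExtensionResult(
        msa=final, state=state, left_total=left_total, right_total=right_total, rounds=rounds
    )
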