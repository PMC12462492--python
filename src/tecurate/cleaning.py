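"""MSA cleaning: gap-column removal and the two sliding-window row croppers.

Three operators clean a raw alignment of TE copies:

``remove_gap_columns``
    Deletes alignment columns dominated by gaps, in two passes: a hard rule
    (gap fraction above 0.8 or fewer than five nucleotides) and a soft rule
    (gap fraction between 0.4 and 0.8 with a weak predominant nucleotide).

``crop_end_by_divergence``
    Converts divergent row ends to gaps.  The alignment is first turned into
    a proportion matrix (each nucleotide replaced by its column frequency,
    gaps and thin columns zeroed); a window slides inward from each row end
    and stops at the first placement whose mean proportion reaches the
    threshold.  Everything outside the stopping windows becomes gaps.  A
    second polish pass repeats this with a small window and threshold 1.0.

``crop_end_by_gap``
    Same sliding mechanics, but the statistic is the row's gap fraction
    inside the window and the window stops when that fraction drops below
    the threshold.

Cropping converts characters to ``-`` rather than deleting them, so row
length, row count and column count are all preserved; this keeps the three
alignments of a cleaning benchmark positionally comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .msa import GAP, Msa, column_stats

__all__ = [
    "GapColumnParams",
    "CropDivergenceParams",
    "CropGapParams",
    "remove_gap_columns",
    "build_proportion_matrix",
    "crop_end_by_divergence",
    "crop_end_by_gap",
]


@dataclass(frozen=True)
class GapColumnParams:
    hard_gap_fraction: float = 0.80
    min_nucleotides: int = 5
    soft_gap_low: float = 0.40
    soft_gap_high: float = 0.80
    soft_predominance: float = 0.70

    def __post_init__(self) -> None:
        if not (0 <= self.soft_gap_low <= self.soft_gap_high <= self.hard_gap_fraction <= 1):
            raise ValueError("gap-fraction thresholds must be ordered in [0, 1]")


@dataclass(frozen=True)
class CropDivergenceParams:
    window: int = 40
    threshold: float = 0.7
    polish_window: int = 4
    polish_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.polish_window < 1:
            raise ValueError("window sizes must be >= 1")


@dataclass(frozen=True)
class CropGapParams:
    window: int = 250
    gap_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window size must be >= 1")


def remove_gap_columns(
    msa: Msa, params: GapColumnParams | None = None
) -> tuple[Msa, list[int]]:
    """Delete gappy columns in two sequential passes.

    Pass 1 removes columns whose gap fraction exceeds ``hard_gap_fraction``
    or whose nucleotide count is below ``min_nucleotides``.  Pass 2, run on
    the survivors, removes columns whose gap fraction lies in
    ``(soft_gap_low, soft_gap_high]`` and whose predominant nucleotide makes
    up less than ``soft_predominance`` of the column's nucleotides.

    Returns the cleaned alignment plus the sorted original indices of every
    removed column.  If all columns are removed the result is an empty-width
    alignment (no error).
    """
    params = params or GapColumnParams()
    counts, nongap, gap_fraction = column_stats(msa)

    hard = (gap_fraction > params.hard_gap_fraction) | (nongap < params.min_nucleotides)

    # the soft rule is evaluated on the hard-pass survivors; both rules are
    # column-local, so the survivors' statistics are unchanged by pass 1
    base_totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        predominance = np.where(
            base_totals > 0, counts.max(axis=0) / np.maximum(base_totals, 1), 0.0
        )
    soft = (
        (gap_fraction > params.soft_gap_low)
        & (gap_fraction <= params.soft_gap_high)
        & (predominance < params.soft_predominance)
    )
    removed = hard | soft

    keep = np.flatnonzero(~removed)
    cleaned = Msa(list(msa.ids), msa.matrix[:, keep].copy(), dict(msa.provenance))
    return cleaned, [int(i) for i in np.flatnonzero(removed)]


def build_proportion_matrix(msa: Msa) -> np.ndarray:
    """Replace every nucleotide by its gap-excluded column proportion.

    Gap positions become 0, as do all entries of columns holding fewer than
    five nucleotides.  ``N`` carries no base identity: its own entries are 0
    and it is excluded from the proportion denominator, but it does count
    toward the five-nucleotide column minimum.
    """
    counts, nongap, _ = column_stats(msa)
    base_totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        col_prop = np.where(base_totals > 0, counts / np.maximum(base_totals, 1), 0.0)
    # look up each cell's own-base proportion; N and gap rows of the lookup are 0
    lookup = np.vstack([col_prop, np.zeros((2, msa.width))])
    values = np.take_along_axis(lookup, msa.matrix.astype(np.intp), axis=0)
    values[:, nongap < 5] = 0.0
    return values


def _window_stops(stat_rows: np.ndarray, window: int, stop: str, threshold: float):
    """First stopping window per row end over a per-row statistic matrix.

    ``stop`` is ``">="`` (mean reaches threshold) or ``"<"`` (mean drops
    below it).  Returns ``(keep_from, keep_to)`` arrays per row: the kept
    span is ``[keep_from, keep_to)`` (the stopping windows themselves are
    retained).  A row with no qualifying window gets an empty span.
    """
    n_rows, width = stat_rows.shape
    window = min(window, width)
    means = sliding_window_view(stat_rows, window, axis=1).mean(axis=2)
    qualifies = means >= threshold if stop == ">=" else means < threshold

    keep_from = np.zeros(n_rows, dtype=np.int64)
    keep_to = np.full(n_rows, width, dtype=np.int64)
    any_q = qualifies.any(axis=1)
    n_pl = qualifies.shape[1]
    # left scan: first qualifying placement; right scan: last placement,
    # i.e. first when sliding from the right end inward
    first = np.where(any_q, qualifies.argmax(axis=1), 0)
    last = np.where(any_q, n_pl - 1 - qualifies[:, ::-1].argmax(axis=1), 0)
    keep_from = np.where(any_q, first, 0)
    keep_to = np.where(any_q, last + window, 0)
    return keep_from, keep_to, any_q


def _apply_crop(matrix: np.ndarray, keep_from, keep_to, found) -> np.ndarray:
    """Gap all columns outside ``[keep_from, keep_to)`` per row; rows with no
    stopping window are gapped entirely.  Returns per-row cropped counts
    (number of columns in the cropped spans, capped at the width)."""
    width = matrix.shape[1]
    cols = np.arange(width)
    keep = (cols >= keep_from[:, None]) & (cols < keep_to[:, None])
    keep &= found[:, None]
    matrix[~keep] = GAP
    cropped = np.where(found, (width - (keep_to - keep_from)).clip(0, width), width)
    return cropped


def crop_end_by_divergence(
    msa: Msa, params: CropDivergenceParams | None = None
) -> tuple[Msa, np.ndarray]:
    """Gap divergent row ends using the proportion-matrix sliding windows.

    Two passes: the main window/threshold, then a polish pass with the small
    window and its (higher) threshold.  The proportion matrix is recomputed
    for the polish pass because the first pass changes column proportions.
    Returns the cropped alignment and the per-row cropped-column counts:
    the columns outside the final stopping windows, both ends combined
    (the polish pass's kept span nests inside the first pass's, so the
    last pass measures the total cropped extent).
    """
    params = params or CropDivergenceParams()
    out = msa.copy()
    totals = np.zeros(msa.n_rows, dtype=np.int64)
    for window, threshold in (
        (params.window, params.threshold),
        (params.polish_window, params.polish_threshold),
    ):
        prop = build_proportion_matrix(out)
        keep_from, keep_to, found = _window_stops(prop, window, ">=", threshold)
        totals = _apply_crop(out.matrix, keep_from, keep_to, found)
    return out, totals


def crop_end_by_gap(
    msa: Msa, params: CropGapParams | None = None
) -> tuple[Msa, np.ndarray]:
    """Gap row ends until a window's gap fraction drops below the threshold.

    Single pass; the window statistic is the row's own gap fraction within
    the window, and the stop condition is strict (< threshold).
    """
    params = params or CropGapParams()
    out = msa.copy()
    gap_rows = (out.matrix == GAP).astype(np.float64)
    keep_from, keep_to, found = _window_stops(
        gap_rows, params.window, "<", params.gap_threshold
    )
    cropped = _apply_crop(out.matrix, keep_from, keep_to, found)
    return out, cropped
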