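"""Alignment data model and column statistics.

The central container is :class:`Msa`, a rectangular nucleotide alignment
over the alphabet ``{A, C, G, T, N, -}``.  Rows carry an optional provenance
map back to the genome interval each sequence was extracted from, which the
extension controller relies on.  Columns are summarised by
:class:`ColumnProfile`: per-column nucleotide counts and proportions with
gaps excluded from the denominator, the statistic every cleaning and
clustering step is built on.

Internally rows are stored as a ``uint8`` matrix (one code per character) so
that column-wise statistics and the sliding-window operators vectorise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "GAP",
    "Msa",
    "ColumnProfile",
    "ConsensusParams",
    "MsaError",
    "RaggedAlignmentError",
    "read_msa",
    "write_msa",
    "column_profile",
    "consensus_with_ambiguity",
    "reverse_complement",
    "reverse_complement_msa",
    "boundary_report",
]

ALPHABET = "ACGTN-"
#: integer codes for A, C, G, T, N, gap
A_, C_, G_, T_, N_, GAP = range(6)

_CHAR_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _CHAR_TO_CODE[ord(_c)] = _i
    _CHAR_TO_CODE[ord(_c.lower())] = _i
_CHAR_TO_CODE[ord("U")] = T_
_CHAR_TO_CODE[ord("u")] = T_
_CODE_TO_CHAR = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# complement of each code; N and gap map to themselves
_COMPLEMENT = np.array([T_, G_, C_, A_, N_, GAP], dtype=np.uint8)

_REVCOMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (gaps preserved)."""
    return seq.translate(_REVCOMP_TABLE)[::-1]


class MsaError(ValueError):
    """Structural problem with an alignment."""


class RaggedAlignmentError(MsaError):
    """Input records do not all have the same aligned length."""


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into the internal uint8 code row."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CHAR_TO_CODE[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise MsaError(f"illegal alignment character {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _CODE_TO_CHAR[codes].tobytes().decode("ascii")


@dataclass
class Msa:
    """Rectangular nucleotide alignment with per-row provenance.

    Parameters
    ----------
    ids:
        Unique sequence identifiers, one per row.
    matrix:
        ``(n_rows, width)`` uint8 matrix of character codes.
    provenance:
        Optional map ``sequence_id -> GenomeInterval`` recording where each
        row was extracted from.
    """

    ids: list[str]
    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise MsaError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise MsaError("number of ids does not match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise MsaError("sequence ids must be unique")

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]], provenance=None) -> "Msa":
        ids, mats = [], []
        width = None
        for sid, seq in rows:
            codes = encode(seq)
            if width is None:
                width = codes.size
            elif codes.size != width:
                raise RaggedAlignmentError(
                    f"record {sid!r} has length {codes.size}, expected {width}"
                )
            ids.append(sid)
            mats.append(codes)
        if not ids:
            raise MsaError("alignment has no records")
        return cls(ids, np.vstack(mats), dict(provenance or {}))

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def row_str(self, i: int) -> str:
        return decode(self.matrix[i])

    def rows(self) -> Iterable[tuple[str, str]]:
        for i, sid in enumerate(self.ids):
            yield sid, self.row_str(i)

    def copy(self) -> "Msa":
        return Msa(list(self.ids), self.matrix.copy(), dict(self.provenance))

    def take_rows(self, indices: Sequence[int]) -> "Msa":
        ids = [self.ids[i] for i in indices]
        prov = {sid: self.provenance[sid] for sid in ids if sid in self.provenance}
        return Msa(ids, self.matrix[list(indices)].copy(), prov)

    def take_columns(self, cols: Sequence[int]) -> "Msa":
        return Msa(list(self.ids), self.matrix[:, list(cols)].copy(), dict(self.provenance))

    def gap_mask(self) -> np.ndarray:
        return self.matrix == GAP


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column nucleotide counts and gap-excluded proportions."""

    counts: dict[str, int]
    nongap_total: int
    gap_fraction: float
    proportions: dict[str, float]


@dataclass(frozen=True)
class ConsensusParams:
    """Ambiguity rule for column-wise consensus generation.

    A column emits its predominant nucleotide only when that nucleotide's
    gap-excluded proportion reaches ``min_proportion`` and the column holds
    at least ``min_count`` nucleotides; otherwise it emits ``N``.
    """

    min_proportion: float = 0.8
    min_count: int = 5
    tie_break_order: str = "ACGT"

    def __post_init__(self) -> None:
        if not (0.0 < self.min_proportion <= 1.0):
            raise ValueError("min_proportion must be in (0, 1]")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    Lowercase is normalised to upper, ``U`` is mapped to ``T``, and the
    sequence id is the header up to the first whitespace.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    sid: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if sid is not None:
                    rows.append((sid, "".join(chunks)))
                sid = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                chunks.append(line)
    if sid is not None:
        rows.append((sid, "".join(chunks)))
    if not rows:
        raise MsaError(f"no FASTA records in {path}")
    return Msa.from_rows(rows)


def write_msa(msa: Msa, path: str | Path, wrap: int = 60) -> None:
    """Write an alignment as FASTA, line-wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for sid, seq in msa.rows():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def nucleotide_counts(msa: Msa) -> np.ndarray:
    """``(4, width)`` matrix of A/C/G/T counts per column."""
    out = np.empty((4, msa.width), dtype=np.int64)
    for code in range(4):
        out[code] = (msa.matrix == code).sum(axis=0)
    return out


def column_stats(msa: Msa) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-column statistics.

    Returns ``(counts, nongap_totals, gap_fractions)`` where ``counts`` is
    the ``(4, width)`` A/C/G/T count matrix and ``nongap_totals`` counts
    nucleotides including ``N`` (an ``N`` is sequence, not gap, but carries
    no base identity so it is excluded from ``counts``).
    """
    counts = nucleotide_counts(msa)
    gaps = (msa.matrix == GAP).sum(axis=0)
    nongap = msa.n_rows - gaps
    gap_fraction = gaps / msa.n_rows
    return counts, nongap, gap_fraction


def column_profile(msa: Msa, col: int) -> ColumnProfile:
    """Profile of one alignment column; gaps excluded from proportions."""
    if not (0 <= col < msa.width):
        raise IndexError(f"column {col} out of range for width {msa.width}")
    column = msa.matrix[:, col]
    gaps = int((column == GAP).sum())
    nongap = msa.n_rows - gaps
    counts = {b: int((column == code).sum()) for code, b in enumerate("ACGT")}
    base_total = sum(counts.values())  # excludes N
    if base_total > 0:
        proportions = {b: counts[b] / base_total for b in "ACGT"}
    else:
        proportions = {b: 0.0 for b in "ACGT"}
    return ColumnProfile(
        counts=counts,
        nongap_total=nongap,
        gap_fraction=gaps / msa.n_rows,
        proportions=proportions,
    )


def consensus_with_ambiguity(msa: Msa, params: ConsensusParams | None = None) -> str:
    """Column-wise consensus with ``N`` at every ambiguous column.

    A column is ambiguous when the predominant nucleotide's gap-excluded
    proportion is below ``min_proportion`` or the nucleotide count is below
    ``min_count``.  Ties between equally frequent nucleotides are broken by
    ``tie_break_order``.  An all-gap column is maximally ambiguous and
    emits ``N``.
    """
    params = params or ConsensusParams()
    counts, nongap, _ = column_stats(msa)
    base_totals = counts.sum(axis=0)
    order = [("ACGT".index(b)) for b in params.tie_break_order]
    # reorder rows so that argmax resolves ties by the configured order
    reordered = counts[order]
    best_pos = reordered.argmax(axis=0)
    best_code = np.array(order)[best_pos]
    best_count = reordered.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(base_totals > 0, best_count / np.maximum(base_totals, 1), 0.0)
    ok = (prop >= params.min_proportion) & (nongap >= params.min_count) & (base_totals > 0)
    out = np.where(ok, best_code, N_).astype(np.uint8)
    return decode(out)


def reverse_complement_msa(msa: Msa) -> Msa:
    """Column-reversed, complemented alignment (gaps and N preserved)."""
    mat = _COMPLEMENT[msa.matrix][:, ::-1].copy()
    return Msa(list(msa.ids), mat, dict(msa.provenance))


def boundary_report(
    msa: Msa,
    start_col: int,
    end_col: int,
    flank: int = 50,
    joiner: str = "-" * 10,
) -> Msa:
    """Text report slice around the two element boundaries.

    Per row, ``flank`` columns on each side of ``start_col`` are joined to
    ``flank`` columns on each side of ``end_col`` by the ``joiner`` string;
    flanks are clipped at the alignment edges and padded with gaps so the
    report stays rectangular.
    """
    if start_col > end_col:
        raise ValueError("start_col must not exceed end_col")
    if not (0 <= start_col <= msa.width and 0 <= end_col <= msa.width):
        raise ValueError("boundary columns outside alignment width")

    def window(center: int) -> np.ndarray:
        lo, hi = center - flank, center + flank
        clo, chi = max(lo, 0), min(hi, msa.width)
        body = msa.matrix[:, clo:chi]
        left_pad = np.full((msa.n_rows, clo - lo), GAP, dtype=np.uint8)
        right_pad = np.full((msa.n_rows, hi - chi), GAP, dtype=np.uint8)
        return np.hstack([left_pad, body, right_pad])

    join = np.tile(encode(joiner), (msa.n_rows, 1)) if joiner else np.empty(
        (msa.n_rows, 0), dtype=np.uint8
    )
    mat = np.hstack([window(start_col), join, window(end_col)])
    return Msa(list(msa.ids), mat, dict(msa.provenance))


def report_to_tsv(report: Msa, path: str | Path) -> None:
    """Write a boundary-report slice as two-column TSV (id, slice)."""
    with open(path, "w") as fh:
        fh.write("sequence_id\treport\n")
        for sid, seq in report.rows():
            fh.write(f"{sid}\t{seq}\n")
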