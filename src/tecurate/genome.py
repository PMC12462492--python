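"""Genome container, intervals, hit tables and the internal search.

Intervals follow BED semantics: 0-based, half-open, strand-aware.  Hits can
come from a precomputed 12-column tabular local-alignment file (the common
``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore`` layout) or from :func:`naive_search`, an internal exact
k-mer seeded, ungapped X-drop extender that finds copies of a query in a
genome without any external search tool.  The search interface is
pluggable: anything producing :class:`HitRecord` lists works downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .msa import encode, reverse_complement

__all__ = [
    "GenomeInterval",
    "HitRecord",
    "Genome",
    "HitTableError",
    "parse_hit_table",
    "naive_search",
    "sample_hits",
    "extract_interval_sequences",
    "interval_id",
    "diagonal_matches",
]


@dataclass(frozen=True)
class GenomeInterval:
    """Strand-aware half-open interval on a named genome sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HitRecord:
    """One local-alignment hit of a query against the genome."""

    query_id: str
    interval: GenomeInterval
    identity: float  # percent, [0, 100]
    length: int  # aligned length, bp
    evalue: float
    coverage: float  # query coverage fraction; nan when unknown
    q_start: int = 0  # half-open query coordinates of the matched span
    q_end: int = 0


class Genome:
    """In-memory genome assembly with uppercase sequences."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}
        self._kmer_index: dict[int, dict[str, dict[str, list[int]]]] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, interval: GenomeInterval) -> str:
        """Oriented subsequence; minus-strand intervals are reverse
        complemented."""
        seq = self.sequences[interval.chrom][interval.start : interval.end]
        return reverse_complement(seq) if interval.strand == "-" else seq

    def clamp(self, interval: GenomeInterval) -> GenomeInterval:
        length = self.lengths[interval.chrom]
        start, end = max(interval.start, 0), min(interval.end, length)
        if (start, end) != (interval.start, interval.end):
            warnings.warn(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"clamped to chromosome bounds [0, {length})",
                stacklevel=2,
            )
        return replace(interval, start=start, end=end)

    def kmer_index(self, chrom: str, k: int, max_positions: int = 100) -> dict:
        """Exact k-mer position index per chromosome, built lazily and
        cached; k-mers occurring more than ``max_positions`` times are
        dropped as low-complexity."""
        per_k = self._kmer_index.setdefault(k, {})
        if chrom not in per_k:
            seq = self.sequences[chrom]
            index: dict[str, list[int]] = {}
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append(i)
            per_k[chrom] = {
                kmer: pos for kmer, pos in index.items() if len(pos) <= max_positions
            }
        return per_k[chrom]


class HitTableError(ValueError):
    """Malformed line in a tabular hit file."""


def parse_hit_table(
    path: str | Path,
    max_evalue: float = 1e-40,
    min_qcov: float = 0.15,
    query_lengths: Mapping[str, int] | None = None,
) -> list[HitRecord]:
    """Parse a 12-column tabular hit file into gated :class:`HitRecord` s.

    Subject coordinates are 1-based inclusive; descending coordinates mean
    a minus-strand hit.  Hits are kept when their e-value is at most
    ``max_evalue`` and, when ``query_lengths`` provides the query length,
    their query coverage is at least ``min_qcov``; without query lengths
    the coverage is recorded as ``nan`` and the coverage gate is skipped.
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 12:
                raise HitTableError(f"line {lineno}: expected 12 columns, got {len(fields)}")
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
            except ValueError as exc:
                raise HitTableError(f"line {lineno}: {exc}") from exc
            strand = "+" if send >= sstart else "-"
            lo, hi = (sstart, send) if strand == "+" else (send, sstart)
            interval = GenomeInterval(sid, lo - 1, hi, strand)
            if query_lengths and qid in query_lengths:
                coverage = (abs(qend - qstart) + 1) / query_lengths[qid]
            else:
                coverage = float("nan")
            if evalue > max_evalue:
                continue
            if coverage == coverage and coverage < min_qcov:  # nan-safe
                continue
            records.append(
                HitRecord(
                    query_id=qid,
                    interval=interval,
                    identity=pident,
                    length=length,
                    evalue=evalue,
                    coverage=coverage,
                    q_start=min(qstart, qend) - 1,
                    q_end=max(qstart, qend),
                )
            )
    return records


def _xdrop_segment(score: np.ndarray, seed_lo: int, seed_hi: int, xdrop: int) -> tuple[int, int]:
    """Extend an exact seed ``[seed_lo, seed_hi)`` over a +1/-1 score array
    in both directions, stopping when the running score drops ``xdrop``
    below its maximum; returns the half-open extent ending at the maxima."""

    def extend(sc: np.ndarray) -> int:
        if sc.size == 0:
            return 0
        cs = np.cumsum(sc)
        run_max = np.maximum.accumulate(cs)
        dropped = np.flatnonzero(run_max - cs > xdrop)
        stop = dropped[0] if dropped.size else sc.size - 1
        best = int(np.argmax(cs[: stop + 1]))
        return best + 1 if cs[best] > 0 else 0

    right = extend(score[seed_hi:])
    left = extend(score[:seed_lo][::-1])
    return seed_lo - left, seed_hi + right


def diagonal_matches(
    query: str,
    target: str,
    k: int = 15,
    xdrop: int = 20,
    target_index: dict | None = None,
    skip_self: bool = False,
) -> list[tuple[int, int, int, int, int]]:
    """Ungapped local matches between two sequences by exact k-mer seeding.

    Seeds on each diagonal are extended with an X-drop rule (match +1,
    mismatch -1, ambiguous bases mismatch).  Returns tuples
    ``(q_start, q_end, t_start, t_end, n_matches)`` with half-open
    coordinates, at most one merged run of segments per diagonal region.
    ``skip_self`` drops the zero-offset diagonal — the trivial full-length
    match of a sequence against itself.
    """
    lq, lt = len(query), len(target)
    if lq < k or lt < k:
        return []
    if target_index is None:
        target_index = {}
        for i in range(lt - k + 1):
            target_index.setdefault(target[i : i + k], []).append(i)
    qcodes = encode(query)
    tcodes = encode(target)

    diagonals: dict[int, list[int]] = {}
    for i in range(lq - k + 1):
        for j in target_index.get(query[i : i + k], ()):
            diagonals.setdefault(j - i, []).append(i)

    if skip_self:
        diagonals.pop(0, None)
    out: list[tuple[int, int, int, int, int]] = []
    for diag in sorted(diagonals):
        q0 = max(0, -diag)
        q1 = min(lq, lt - diag)
        qs = qcodes[q0:q1]
        ts = tcodes[q0 + diag : q1 + diag]
        match = (qs == ts) & (qs < 4) & (ts < 4)
        score = np.where(match, 1, -1).astype(np.int64)
        covered_until = -1
        for seed in sorted(diagonals[diag]):
            s = seed - q0
            if s <= covered_until:
                continue
            lo, hi = _xdrop_segment(score, s, s + k, xdrop)
            covered_until = hi
            n_match = int(match[lo:hi].sum())
            out.append((lo + q0, hi + q0, lo + q0 + diag, hi + q0 + diag, n_match))
    return _merge_overlapping(out)


def _merge_overlapping(segments: list[tuple[int, int, int, int, int]]):
    """Drop segments mostly contained (>= 80%) in a better segment on the
    target, keeping the one with more matches."""
    kept: list[tuple[int, int, int, int, int]] = []
    for seg in sorted(segments, key=lambda s: -s[4]):
        redundant = False
        for other in kept:
            ov = min(seg[3], other[3]) - max(seg[2], other[2])
            if ov > 0 and ov >= 0.8 * (seg[3] - seg[2]):
                redundant = True
                break
        if not redundant:
            kept.append(seg)
    kept.sort(key=lambda s: (s[2], s[0]))
    return kept


def naive_search(
    query: str,
    genome: Genome,
    query_id: str = "query",
    k: int = 15,
    min_identity: float = 0.8,
    min_length: int = 30,
    xdrop: int = 20,
) -> list[HitRecord]:
    """Find copies of ``query`` in ``genome`` on both strands.

    Exact k-mer seeding with ungapped X-drop extension; identity and query
    coverage are computed per merged hit.  Intended for desk-scale genomes
    and substitution-level divergence (finds planted copies at up to ~20%
    divergence with the default word size).
    """
    if len(query) < k:
        raise ValueError(f"query shorter than word size {k}")
    query = query.upper()
    hits: list[HitRecord] = []
    for chrom in genome.sequences:
        index = genome.kmer_index(chrom, k)
        target = genome.sequences[chrom]
        for strand in "+-":
            q = query if strand == "+" else reverse_complement(query)
            for qs, qe, ts, te, n_match in diagonal_matches(
                q, target, k=k, xdrop=xdrop, target_index=index
            ):
                seg_len = qe - qs
                if seg_len < min_length:
                    continue
                identity = n_match / seg_len
                if identity < min_identity:
                    continue
                if strand == "-":
                    qs, qe = len(query) - qe, len(query) - qs
                hits.append(
                    HitRecord(
                        query_id=query_id,
                        interval=GenomeInterval(chrom, ts, te, strand),
                        identity=100.0 * identity,
                        length=seg_len,
                        evalue=0.0,
                        coverage=seg_len / len(query),
                        q_start=qs,
                        q_end=qe,
                    )
                )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return hits


def sample_hits(
    hits: Sequence[HitRecord],
    cap: int = 100,
    n_longest: int = 70,
    n_random: int = 30,
    seed: int | np.random.Generator = 0,
) -> list[HitRecord]:
    """Cap a hit list at ``cap`` records.

    When more hits exist, the ``n_longest`` longest (ties by genomic
    position) are always kept and ``n_random`` more are drawn uniformly
    without replacement from the remainder; deterministic for a fixed seed.
    Selected hits are returned in their original order.
    """
    hits = list(hits)
    if len(hits) <= cap:
        return hits
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = sorted(
        range(len(hits)),
        key=lambda i: (
            -hits[i].length,
            hits[i].interval.chrom,
            hits[i].interval.start,
            hits[i].interval.end,
        ),
    )
    longest = set(order[:n_longest])
    remainder = [i for i in order[n_longest:]]
    chosen = rng.choice(len(remainder), size=min(n_random, len(remainder)), replace=False)
    selected = longest | {remainder[int(c)] for c in chosen}
    return [hits[i] for i in sorted(selected)]


def interval_id(interval: GenomeInterval) -> str:
    return f"{interval.chrom}:{interval.start}-{interval.end}({interval.strand})"


def extract_interval_sequences(
    genome: Genome, intervals: Iterable[GenomeInterval]
) -> dict[str, str]:
    """Oriented subsequences per interval, keyed by ``chrom:start-end(strand)``.

    Intervals reaching past the chromosome are clamped with a warning.
    """
    out: dict[str, str] = {}
    for interval in intervals:
        clamped = genome.clamp(interval)
        out[interval_id(clamped)] = genome.fetch(clamped)
    return out
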