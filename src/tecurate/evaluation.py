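"""Output evaluation, low-copy gating and library de-duplication.

Every curated consensus is assigned one of five levels — Perfect, Good,
Reco_check, Need_check, Low_copy — from a configurable rule table over five
predicates: terminal repeat present, classification known, alignment size,
full-length genomic hit count, and coding evidence (protein-domain hits or
long ORFs).  A full-length hit covers more than 90% of the consensus at
more than 85% identity.  Elements recovered from fewer than ten genomic
copies pass a stricter gate: they are kept (as ``Low_copy``) only with a
terminal repeat and at least two full-length hits.

De-duplication runs in two rounds of greedy incremental clustering (the
CD-HIT convention: sequences sorted by length join the first cluster whose
representative they match).  Round one groups at 90% identity / 90%
coverage of the shorter sequence and keeps the longest Perfect — or,
failing that, the longest Good — member of each cluster; everything from
clusters without a Perfect/Good member is re-clustered at 85% identity /
80% coverage of both sequences, keeping each cluster's longest sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from .boundary import ConsensusRecord
from .genome import HitRecord

__all__ = [
    "EvaluationRules",
    "DedupParams",
    "count_full_length_hits",
    "evaluate_record",
    "low_copy_gate",
    "pairwise_identity_coverage",
    "greedy_cluster",
    "dedup_library",
]


@dataclass(frozen=True)
class EvaluationRules:
    """Thresholds of the level rule table (defaults are the package's
    documented table; the predicate vocabulary is fixed, the cut-offs are
    configurable)."""

    full_length_min_coverage: float = 0.90
    full_length_min_identity: float = 85.0  # percent
    perfect_min_msa_size: int = 10
    perfect_min_fl_hits: int = 5
    good_min_msa_size: int = 10
    good_min_fl_hits: int = 5
    reco_min_fl_hits: int = 2
    low_copy_msa_size: int = 10
    low_copy_min_fl_hits: int = 2


@dataclass(frozen=True)
class DedupParams:
    round1_identity: float = 0.90
    round1_coverage: float = 0.90  # of the shorter sequence
    round2_identity: float = 0.85
    round2_coverage: float = 0.80  # of both sequences
    input_identity: float = 0.95
    input_coverage: float = 0.95


def count_full_length_hits(
    consensus: str, hits: Iterable[HitRecord], rules: EvaluationRules | None = None
) -> int:
    """Hits covering more than 90% of the consensus at more than 85%
    identity (both strict)."""
    rules = rules or EvaluationRules()
    length = len(consensus)
    n = 0
    for hit in hits:
        coverage = hit.length / length
        if coverage > rules.full_length_min_coverage and hit.identity > rules.full_length_min_identity:
            n += 1
    return n


def evaluate_record(
    record: ConsensusRecord,
    msa_size: int,
    fl_hits: int,
    rules: EvaluationRules | None = None,
    has_evidence: bool = False,
) -> str:
    """Assign Perfect / Good / Reco_check / Need_check.

    Perfect requires all five predicates; Good drops the terminal-repeat
    and coding-evidence requirements; Reco_check requires classification
    and at least two full-length hits; everything else is Need_check.
    The mapping is total and deterministic.
    """
    rules = rules or EvaluationRules()
    has_repeat = record.terminal_repeat is not None
    classified = record.classified
    if (
        has_repeat
        and classified
        and msa_size >= rules.perfect_min_msa_size
        and fl_hits >= rules.perfect_min_fl_hits
        and has_evidence
    ):
        return "Perfect"
    if classified and msa_size >= rules.good_min_msa_size and fl_hits >= rules.good_min_fl_hits:
        return "Good"
    if classified and fl_hits >= rules.reco_min_fl_hits:
        return "Reco_check"
    return "Need_check"


def low_copy_gate(
    msa_size: int,
    has_terminal_repeat: bool,
    fl_hits: int,
    rules: EvaluationRules | None = None,
) -> str:
    """Gate for elements with fewer than ten recovered copies: kept as
    ``Low_copy`` only with a terminal repeat and at least two full-length
    hits, otherwise ``discard``."""
    rules = rules or EvaluationRules()
    if msa_size > rules.low_copy_msa_size:
        raise ValueError("low-copy gate applies only to small alignments")
    if has_terminal_repeat and fl_hits >= rules.low_copy_min_fl_hits:
        return "Low_copy"
    return "discard"


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2
# free terminal gaps: local-like ends, global-like middle
_aligner.end_gap_score = 0


def pairwise_identity_coverage(a: str, b: str) -> tuple[float, float, float]:
    """Global alignment identity and per-sequence coverages.

    Scoring: match +1, mismatch -1, gap -2, terminal gaps free.  Identity
    is the number of identical aligned columns divided by the length of
    the shorter sequence; coverage of each sequence is the aligned span on
    that sequence divided by its length.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    identical = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        identical += sum(1 for i in range(ea - sa) if a[sa + i] == b[sb + i])
    if len(blocks_a):
        span_a = blocks_a[-1][1] - blocks_a[0][0]
        span_b = blocks_b[-1][1] - blocks_b[0][0]
    else:
        span_a = span_b = 0
    identity = identical / min(len(a), len(b))
    return identity, span_a / len(a), span_b / len(b)


def _pair_matches(
    a: str, b: str, min_identity: float, coverage_rule: str, min_coverage: float
) -> bool:
    identity, cov_a, cov_b = pairwise_identity_coverage(a, b)
    if identity <= min_identity:
        return False
    if coverage_rule == "shorter":
        cov_short = cov_a if len(a) <= len(b) else cov_b
        return cov_short > min_coverage
    if coverage_rule == "all":
        return cov_a > min_coverage and cov_b > min_coverage
    raise ValueError(f"unknown coverage rule {coverage_rule!r}")


def greedy_cluster(
    seqs: Sequence[str],
    min_identity: float,
    coverage_rule: str = "shorter",
    min_coverage: float = 0.9,
) -> list[list[int]]:
    """Greedy incremental clustering by identity/coverage thresholds.

    Sequences are visited by decreasing length (ties by input order); each
    joins the first existing cluster whose representative (founding,
    longest member) it matches, else founds a new cluster.  Returns
    clusters as lists of input indices, in founding order.
    """
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    clusters: list[list[int]] = []
    for idx in order:
        for cluster in clusters:
            rep = seqs[cluster[0]]
            if _pair_matches(seqs[idx], rep, min_identity, coverage_rule, min_coverage):
                cluster.append(idx)
                break
        else:
            clusters.append([idx])
    return clusters


def dedup_library(
    records: Sequence[ConsensusRecord], params: DedupParams | None = None
) -> list[ConsensusRecord]:
    """Two-round de-duplication of a curated consensus library.

    Round 1 clusters at ``round1_identity`` / coverage of the shorter
    sequence; each cluster holding a Perfect or Good member contributes its
    longest Perfect (else longest Good) sequence.  All members of the
    remaining clusters are re-clustered at ``round2_identity`` / coverage
    of both sequences, and each such cluster's longest member survives.
    Output order follows the input order of the surviving records.
    """
    params = params or DedupParams()
    if not records:
        return []
    seqs = [r.consensus for r in records]
    round1 = greedy_cluster(seqs, params.round1_identity, "shorter", params.round1_coverage)

    survivors: set[int] = set()
    leftover: list[int] = []
    for cluster in round1:
        perfect = [i for i in cluster if records[i].evaluation == "Perfect"]
        good = [i for i in cluster if records[i].evaluation == "Good"]
        if perfect:
            survivors.add(max(perfect, key=lambda i: (len(seqs[i]), -i)))
        elif good:
            survivors.add(max(good, key=lambda i: (len(seqs[i]), -i)))
        else:
            leftover.extend(cluster)

    if leftover:
        sub = [seqs[i] for i in leftover]
        round2 = greedy_cluster(sub, params.round2_identity, "all", params.round2_coverage)
        for cluster in round2:
            survivors.add(leftover[max(cluster, key=lambda j: (len(sub[j]), -j))])

    return [records[i] for i in sorted(survivors)]
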