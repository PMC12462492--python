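"""Separating TE variants within one alignment.

A single input consensus often recruits genomic copies of several related
but distinct TE variants, which must be curated separately.  The procedure:

1. select the *divergent columns* (no nucleotide reaches 80% of the column)
   and *gap blocks* (contiguous gap-bearing stretches with smoothly varying
   gap proportions, flanked by conserved columns);
2. concatenate the selected columns into a pseudo-alignment that carries
   only the discriminating signal;
3. compute pairwise Kimura two-parameter distances on the pseudo-alignment,
   build a neighbor-joining tree, and take patristic (path-length) distances
   normalised by the matrix maximum so they live on [0, 1];
4. run DBSCAN (epsilon 0.1, min_samples 2) on the precomputed distances;
5. keep the largest clusters (default top five); the noise set is processed
   as an additional cluster only when it is large both absolutely (> 15
   sequences) and relatively (> 60% of the alignment) and the number of
   normal clusters is below the cluster cap.

An externally computed Newick tree can be supplied in place of the internal
neighbor-joining step; clustering consumes only the pairwise path lengths.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj
from sklearn.cluster import DBSCAN

from .msa import Msa, column_stats

__all__ = [
    "NOISE",
    "K2P_MAX",
    "ClusteringParams",
    "DistanceMatrix",
    "ClusterAssignment",
    "UniformMsaError",
    "UndefinedDistanceError",
    "select_divergent_columns",
    "select_gap_blocks",
    "build_pseudo_msa",
    "k2p_distance",
    "tree_relative_distances",
    "nj_patristic",
    "patristic_from_newick",
    "dbscan_cluster",
    "noise_qualifies",
    "partition_msa",
]

#: label assigned to sequences in no cluster
NOISE = -1

#: cap applied to saturated Kimura distances (substitutions/site); pairs
#: whose corrected distance is undefined (log argument <= 0) are this far
K2P_MAX = 3.0


class UniformMsaError(ValueError):
    """The alignment has no divergent columns or gap blocks to cluster on."""


class UndefinedDistanceError(ValueError):
    """Two rows share no comparable (both-nucleotide) columns."""


@dataclass(frozen=True)
class ClusteringParams:
    divergence_threshold: float = 0.8
    gap_block_adjacent_delta: float = 0.10
    gap_block_flank_dominance: float = 0.80
    epsilon: float = 0.1
    min_samples: int = 2
    max_cluster_num: int = 5
    noise_min_size: int = 15
    noise_min_fraction: float = 0.60
    small_cluster_size: int = 10


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass
class ClusterAssignment:
    """Per-sequence labels plus clusters ordered by size.

    ``clusters`` holds row-index lists sorted by (size desc, first member
    asc); ``labels`` maps each row to its cluster id or :data:`NOISE`.
    """

    labels: np.ndarray
    clusters: list[list[int]] = field(default_factory=list)

    @property
    def noise_indices(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.labels == NOISE)]


def select_divergent_columns(msa: Msa, threshold: float = 0.8) -> list[int]:
    """Columns where every nucleotide's gap-excluded proportion is below
    ``threshold`` (ascending indices)."""
    counts, _, _ = column_stats(msa)
    base_totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        top = np.where(base_totals > 0, counts.max(axis=0) / np.maximum(base_totals, 1), 0.0)
    divergent = (top < threshold) & (base_totals > 0)
    return [int(i) for i in np.flatnonzero(divergent)]


def select_gap_blocks(
    msa: Msa, params: ClusteringParams | None = None
) -> list[tuple[int, int]]:
    """Half-open column ranges of qualifying gap blocks.

    A gap block is a maximal contiguous run of gap-bearing columns in which
    adjacent columns' gap proportions differ by at most
    ``gap_block_adjacent_delta``, flanked on both immediate outside columns
    by a dominant nucleotide above ``gap_block_flank_dominance``.
    """
    params = params or ClusteringParams()
    counts, _, gap_fraction = column_stats(msa)
    base_totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dominance = np.where(
            base_totals > 0, counts.max(axis=0) / np.maximum(base_totals, 1), 0.0
        )

    blocks: list[tuple[int, int]] = []
    width = msa.width
    i = 0
    while i < width:
        if gap_fraction[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < width and gap_fraction[j + 1] > 0:
            j += 1
        run = (i, j + 1)  # half-open
        deltas_ok = all(
            abs(gap_fraction[c + 1] - gap_fraction[c]) <= params.gap_block_adjacent_delta
            for c in range(run[0], run[1] - 1)
        )
        flanks_ok = (
            run[0] > 0
            and run[1] < width
            and dominance[run[0] - 1] > params.gap_block_flank_dominance
            and dominance[run[1]] > params.gap_block_flank_dominance
        )
        if deltas_ok and flanks_ok:
            blocks.append(run)
        i = j + 1
    return blocks


def build_pseudo_msa(
    msa: Msa, divergent_cols: list[int], gap_blocks: list[tuple[int, int]]
) -> Msa:
    """Concatenate selected columns (ascending, de-duplicated) per row."""
    cols = set(divergent_cols)
    for start, end in gap_blocks:
        cols.update(range(start, end))
    if not cols:
        raise UniformMsaError("MSA too uniform to cluster: no divergent columns or gap blocks")
    return msa.take_columns(sorted(cols))


_TRANSITION_PAIRS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def k2p_distance(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Kimura two-parameter distance between two aligned rows.

    Only columns where both rows carry an unambiguous nucleotide are
    compared.  With transition fraction P and transversion fraction Q,
    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``; saturated arguments are
    capped at :data:`K2P_MAX`.
    """
    from .msa import encode

    ca = encode(a) if isinstance(a, str) else np.asarray(a)
    cb = encode(b) if isinstance(b, str) else np.asarray(b)
    if ca.size != cb.size:
        raise ValueError("rows must have equal aligned length")
    mask = (ca < 4) & (cb < 4)
    n = int(mask.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites between rows")
    xa, xb = ca[mask], cb[mask]
    diff = xa != xb
    transitions = diff & ((xa ^ xb) == 2)  # codes: A=0,C=1,G=2,T=3; A^G=2, C^T=2
    p = float(transitions.sum()) / n
    q = float(diff.sum() - transitions.sum()) / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return K2P_MAX
    return min(-0.5 * math.log(arg1) - 0.25 * math.log(arg2), K2P_MAX)


def _pairwise_k2p(msa: Msa) -> np.ndarray:
    """Pairwise Kimura distance matrix over a (pseudo-)alignment.

    Rows with no comparable sites — possible when truncated copies select
    disjoint divergent columns — share no signal and are assigned the
    saturation cap :data:`K2P_MAX` rather than failing the clustering.
    """
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = k2p_distance(msa.matrix[i], msa.matrix[j])
            except UndefinedDistanceError:
                d[i, j] = d[j, i] = K2P_MAX
    return d


def nj_patristic(d: np.ndarray, ids: list[str]) -> np.ndarray:
    """Patristic distances from a neighbor-joining tree over ``d``.

    Negative NJ branch lengths are clamped to zero before path sums.
    """
    dm = SkbioDM(d, ids)
    tree = nj(dm, neg_as_zero=True)
    tip_d = tree.tip_tip_distances(endpoints=list(ids))
    # reorder to the input id order
    order = [list(tip_d.ids).index(i) for i in ids]
    return np.asarray(tip_d.data)[np.ix_(order, order)]


def patristic_from_newick(newick: str, ids: list[str]) -> np.ndarray:
    """Patristic distances for ``ids`` from an externally computed tree."""
    tree = TreeNode.read(io.StringIO(newick))
    tip_d = tree.tip_tip_distances(endpoints=list(ids))
    order = [list(tip_d.ids).index(i) for i in ids]
    return np.asarray(tip_d.data)[np.ix_(order, order)]


def tree_relative_distances(pseudo: Msa, newick: str | None = None) -> DistanceMatrix:
    """Relative (max-normalised) patristic distances between rows.

    By default an unrooted neighbor-joining tree is built over pairwise
    Kimura distances; an externally computed Newick tree may be supplied
    instead.  Path lengths are divided by the matrix maximum so entries lie
    on [0, 1]; an all-identical alignment yields all zeros.
    """
    ids = list(pseudo.ids)
    n = len(ids)
    if newick is not None:
        pat = patristic_from_newick(newick, ids)
    elif n == 1:
        pat = np.zeros((1, 1))
    elif n == 2:
        pat = _pairwise_k2p(pseudo)
    else:
        pat = nj_patristic(_pairwise_k2p(pseudo), ids)
    m = pat.max()
    rel = pat / m if m > 0 else np.zeros_like(pat)
    np.fill_diagonal(rel, 0.0)
    rel = (rel + rel.T) / 2.0
    return DistanceMatrix(ids, rel)


def dbscan_cluster(
    dm: DistanceMatrix, epsilon: float = 0.1, min_samples: int = 2
) -> ClusterAssignment:
    """DBSCAN over precomputed distances.

    A core point has at least ``min_samples`` points (itself included)
    within ``epsilon``; clusters are connected core points plus their
    border points; everything else is :data:`NOISE`.  Deterministic for a
    fixed row order.
    """
    labels = DBSCAN(eps=epsilon, min_samples=min_samples, metric="precomputed").fit(
        dm.d
    ).labels_
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab != NOISE:
            clusters.setdefault(int(lab), []).append(i)
    ordered = sorted(clusters.values(), key=lambda m: (-len(m), m[0]))
    return ClusterAssignment(labels=np.asarray(labels), clusters=ordered)


def noise_qualifies(assignment: ClusterAssignment, total: int, params: ClusteringParams) -> bool:
    """Whether the noise set is processed as an additional cluster.

    Requires all three conditions: more than ``noise_min_size`` sequences,
    more than ``noise_min_fraction`` of the alignment, and fewer normal
    clusters than ``max_cluster_num``.
    """
    noise = assignment.noise_indices
    return (
        len(noise) > params.noise_min_size
        and (len(noise) / total) > params.noise_min_fraction
        and len(assignment.clusters) < params.max_cluster_num
    )


def partition_msa(
    msa: Msa,
    params: ClusteringParams | None = None,
    newick: str | None = None,
) -> list[Msa]:
    """Split an alignment into per-variant sub-alignments.

    Full orchestration: divergent columns and gap blocks feed a
    pseudo-alignment; tree-relative distances feed DBSCAN; up to
    ``max_cluster_num`` clusters are returned in size order (ties by first
    member), followed by the noise set when :func:`noise_qualifies`.  An
    alignment with nothing to cluster on is returned whole as one cluster.
    """
    params = params or ClusteringParams()
    if msa.n_rows < 2:
        return [msa.copy()]
    divergent = select_divergent_columns(msa, params.divergence_threshold)
    blocks = select_gap_blocks(msa, params)
    try:
        pseudo = build_pseudo_msa(msa, divergent, blocks)
    except UniformMsaError:
        return [msa.copy()]
    dm = tree_relative_distances(pseudo, newick=newick)
    assignment = dbscan_cluster(dm, params.epsilon, params.min_samples)
    selected = assignment.clusters[: params.max_cluster_num]
    if noise_qualifies(assignment, msa.n_rows, params):
        selected = selected + [assignment.noise_indices]
    return [msa.take_rows(members) for members in selected]
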