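"""Seeded generators of TE families, planted genomes and noisy alignments.

These fixtures provide exact ground truth for every curation stage at desk
scale: TE families with the defining structural features (LTR elements
with identical terminal direct repeats, TIR elements with terminal
inverted repeats, LINE-like elements with a 3' poly(A) tail), genomes with
planted copies that can be diverged, 5'-truncated, fragmented or nested,
and alignments with a conserved core flanked by unalignable noise — the
situation the sliding-window croppers exist for.

Divergence is substitution-only by default (transitions favoured 2:1),
which keeps the coordinate-stacking aligner exact on fixtures; an indel
mode is not provided here because every downstream operator is benchmarked
positionally.  All generators are deterministic per seed (numpy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome, GenomeInterval
from .msa import Msa, encode, reverse_complement

__all__ = [
    "TeFamilySpec",
    "PlantSpec",
    "TeFamily",
    "PlantedCopy",
    "GenomeFixture",
    "make_te_family",
    "mutate_sequence",
    "plant_genome",
    "make_noisy_msa",
    "random_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_sequence(length: int, seed, gc: float = 0.5) -> str:
    """I.i.d. random nucleotide sequence with the requested GC content."""
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


@dataclass(frozen=True)
class TeFamilySpec:
    kind: str  # LTR, TIR or LINE
    length: int = 3000
    repeat_length: int = 300  # terminal repeat, LTR/TIR only
    tail_length: int = 15  # poly(A), LINE only
    gc: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("LTR", "TIR", "LINE"):
            raise ValueError(f"unknown family kind {self.kind!r}")
        if self.length < 50:
            raise ValueError("element length must be >= 50 bp")
        if self.kind in ("LTR", "TIR") and not (0 < self.repeat_length < self.length / 2):
            raise ValueError("repeat length must be below half the element length")


@dataclass(frozen=True)
class TeFamily:
    name: str
    spec: TeFamilySpec
    consensus: str
    repeats: tuple[tuple[int, int], ...] = ()  # terminal repeat coordinates
    tail: tuple[int, int] | None = None  # poly tail coordinates

    @property
    def classification(self) -> str:
        return {"LTR": "LTR/Unknown", "TIR": "DNA/TIR", "LINE": "LINE/Unknown"}[
            self.spec.kind
        ]


def make_te_family(spec: TeFamilySpec, seed, name: str = "family") -> TeFamily:
    """Random element with the planted structural feature of its kind."""
    rng = _rng(seed)
    body = random_sequence(spec.length, rng, spec.gc)
    if spec.kind == "LTR":
        r = spec.repeat_length
        consensus = body[:r] + body[r : spec.length - r] + body[:r]
        return TeFamily(
            name, spec, consensus, repeats=((0, r), (spec.length - r, spec.length))
        )
    if spec.kind == "TIR":
        r = spec.repeat_length
        consensus = body[: spec.length - r] + reverse_complement(body[:r])
        return TeFamily(
            name, spec, consensus, repeats=((0, r), (spec.length - r, spec.length))
        )
    t = spec.tail_length
    consensus = body[: spec.length - t] + "A" * t
    return TeFamily(name, spec, consensus, tail=(spec.length - t, spec.length))


_TRANSITION = np.array([2, 3, 0, 1])  # A->G, C->T, G->A, T->C (codes)


def mutate_sequence(seq: str, rate: float, seed, transition_bias: float = 2.0) -> str:
    """Per-base substitution at ``rate`` with transitions favoured.

    Among substitutions, the transition is chosen with probability
    ``bias / (bias + 1)``; the two transversions split the rest evenly.
    """
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    rng = _rng(seed)
    codes = encode(seq).copy()
    nuc = codes < 4
    hit = nuc & (rng.random(codes.size) < rate)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return seq
    p_transition = transition_bias / (transition_bias + 1.0)
    u = rng.random(idx.size)
    old = codes[idx]
    new = _TRANSITION[old].copy()
    # transversions: the two bases that are neither the original nor its
    # transition partner
    tv = u >= p_transition
    pick_second = u > (p_transition + (1 - p_transition) / 2)
    for j in np.flatnonzero(tv):
        options = [b for b in range(4) if b != old[j] and b != _TRANSITION[old[j]]]
        new[j] = options[1] if pick_second[j] else options[0]
    codes[idx] = new
    from .msa import decode

    return decode(codes)


@dataclass(frozen=True)
class PlantSpec:
    copies: int = 20
    divergence: float = 0.02
    truncate_5prime_prob: float = 0.0
    fragment_prob: float = 0.0
    nest_prob: float = 0.0
    tsd: int = 5
    minus_strand_prob: float = 0.5


@dataclass(frozen=True)
class PlantedCopy:
    family: str
    interval: GenomeInterval
    intact: bool
    nested_in: str | None = None


@dataclass
class GenomeFixture:
    genome: Genome
    copies: list[PlantedCopy]
    families: list[TeFamily]

    def truth_bed(self) -> list[tuple[str, int, int, str, str, str]]:
        """Truth annotation rows: (chrom, start, end, family, intactness,
        strand)."""
        return [
            (
                c.interval.chrom,
                c.interval.start,
                c.interval.end,
                c.family,
                "intact" if c.intact else "partial",
                c.interval.strand,
            )
            for c in self.copies
        ]

    def library(self) -> list[tuple[str, str]]:
        return [(f"{f.name}#{f.classification}", f.consensus) for f in self.families]


def _make_copy(family: TeFamily, spec: PlantSpec, rng) -> tuple[str, bool]:
    seq = mutate_sequence(family.consensus, spec.divergence, rng)
    intact = True
    if spec.fragment_prob > 0 and rng.random() < spec.fragment_prob:
        frac = rng.uniform(0.3, 0.7)
        keep = max(50, int(len(seq) * frac))
        start = int(rng.integers(0, len(seq) - keep + 1))
        seq = seq[start : start + keep]
        intact = False
    elif spec.truncate_5prime_prob > 0 and rng.random() < spec.truncate_5prime_prob:
        cut = int(len(seq) * rng.uniform(0.1, 0.6))
        seq = seq[cut:]
        intact = False
    return seq, intact


def plant_genome(
    families: list[tuple[TeFamily, PlantSpec]],
    genome_length: int,
    seed,
    chrom: str = "chr1",
    gc: float = 0.42,
) -> GenomeFixture:
    """Plant mutated TE copies into a random background genome.

    Copies are inserted at distinct random positions of the background
    (with target-site duplication of ``tsd`` bases); with ``nest_prob`` a
    copy is instead inserted inside a previously placed copy of another
    family.  The truth annotation records every copy's final coordinates,
    strand and intactness.
    """
    rng = _rng(seed)
    planted: list[dict] = []  # {family, seq(oriented genomic), strand, intact, host}
    total = 0
    for family, spec in families:
        for _ in range(spec.copies):
            seq, intact = _make_copy(family, spec, rng)
            strand = "-" if rng.random() < spec.minus_strand_prob else "+"
            planted.append(
                {
                    "family": family.name,
                    "seq": reverse_complement(seq) if strand == "-" else seq,
                    "strand": strand,
                    "intact": intact,
                    "tsd": spec.tsd,
                    "nest": spec.nest_prob > 0 and rng.random() < spec.nest_prob,
                }
            )
            total += len(seq) + spec.tsd
    if total >= genome_length:
        raise ValueError("planted sequence exceeds genome length: infeasible packing")

    background = random_sequence(genome_length - total, rng, gc)

    # nested copies go inside a host copy of a different family when one exists
    hosts = [p for p in planted if not p["nest"]]
    nested = [p for p in planted if p["nest"]]
    for p in nested:
        choices = [h for h in hosts if h["family"] != p["family"]]
        if not choices:
            hosts.append(p)
            continue
        host = choices[int(rng.integers(0, len(choices)))]
        host.setdefault("children", []).append(p)

    # assemble: choose insertion offsets in the background for each host
    offsets = np.sort(rng.choice(len(background), size=len(hosts), replace=False))
    pieces: list[str] = []
    copies: list[PlantedCopy] = []
    cursor = 0
    genome_pos = 0

    def emit(piece: str) -> None:
        nonlocal genome_pos
        pieces.append(piece)
        genome_pos += len(piece)

    for host, offset in zip(hosts, offsets):
        emit(background[cursor:offset])
        cursor = offset
        tsd_seq = background[max(0, offset - host["tsd"]) : offset]
        seq = host["seq"]
        children = host.get("children", [])
        if children:
            child = children[0]
            point = int(rng.integers(len(seq) // 4, 3 * len(seq) // 4))
            child_tsd = seq[max(0, point - child["tsd"]) : point]
            host_start = genome_pos
            emit(seq[:point])
            child_start = genome_pos
            emit(child["seq"])
            copies.append(
                PlantedCopy(
                    child["family"],
                    GenomeInterval(
                        chrom, child_start, genome_pos, child["strand"]
                    ),
                    child["intact"],
                    nested_in=host["family"],
                )
            )
            emit(child_tsd)
            emit(seq[point:])
            copies.append(
                PlantedCopy(
                    host["family"],
                    GenomeInterval(chrom, host_start, genome_pos, host["strand"]),
                    host["intact"],
                )
            )
        else:
            start = genome_pos
            emit(seq)
            copies.append(
                PlantedCopy(
                    host["family"],
                    GenomeInterval(chrom, start, genome_pos, host["strand"]),
                    host["intact"],
                )
            )
        emit(tsd_seq)
    emit(background[cursor:])

    genome = Genome({chrom: "".join(pieces)})
    copies.sort(key=lambda c: c.interval.start)
    return GenomeFixture(genome=genome, copies=copies, families=[f for f, _ in families])


def make_noisy_msa(
    core_length: int = 800,
    n_rows: int = 20,
    flank_length: int = 150,
    divergence: float = 0.01,
    seed=0,
) -> tuple[Msa, np.ndarray]:
    """Alignment of a shared mutated core between unalignable random flanks.

    Each row is an independent random left flank, an independent mutation
    of the same core, and an independent random right flank.  The returned
    boolean mask marks the flank (noise) positions a perfect cleaning
    would convert to gaps; it is the reference for the cleaning benchmark.
    """
    if min(core_length, n_rows) < 1 or flank_length < 0:
        raise ValueError("parameters must be positive")
    rng = _rng(seed)
    core = random_sequence(core_length, rng)
    rows = []
    for i in range(n_rows):
        left = random_sequence(flank_length, rng)
        right = random_sequence(flank_length, rng)
        rows.append((f"seq{i}", left + mutate_sequence(core, divergence, rng) + right))
    msa = Msa.from_rows(rows)
    mask = np.zeros((n_rows, msa.width), dtype=bool)
    if flank_length:
        mask[:, :flank_length] = True
        mask[:, -flank_length:] = True
    return msa, mask
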