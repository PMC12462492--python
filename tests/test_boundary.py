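"""Terminal repeats, poly tails, the boundary cascade, ORFs, orientation."""

import pytest

from tecurate.boundary import (
    BoundaryParams,
    ConsensusRecord,
    NoTeRegionError,
    define_boundaries,
    detect_poly_tail,
    detect_terminal_repeats,
    finalize_consensus,
    find_orfs,
    orient_consensus,
)
from tecurate.msa import Msa, reverse_complement
from tecurate.synthetic import (
    TeFamilySpec,
    make_te_family,
    mutate_sequence,
    random_sequence,
)

from conftest import msa_from


class TestTerminalRepeats:
    def test_planted_identical_ltr_arms_exact(self, rng):
        fam = make_te_family(TeFamilySpec("LTR", 5000, 300), rng, "f")
        tr = detect_terminal_repeats(fam.consensus)
        assert tr is not None and tr.kind == "LTR"
        assert (tr.left, tr.right) == ((0, 300), (4700, 5000))
        assert tr.identity == 1.0

    def test_planted_inverted_repeat_is_tir(self, rng):
        fam = make_te_family(TeFamilySpec("TIR", 2000, 20), rng, "f")
        tr = detect_terminal_repeats(fam.consensus)
        assert tr is not None and tr.kind == "TIR"
        # seed-and-extend may overrun the arm by a few chance matches
        assert tr.left[0] == 0 and tr.right[1] == 2000
        assert abs(tr.left[1] - 20) <= 3 and abs(tr.right[0] - 1980) <= 3

    def test_random_sequence_has_no_terminal_repeat(self, rng):
        # chance short matches are rejected by the self-search significance
        # gate; a long high-identity terminal repeat in i.i.d. sequence is
        # vanishingly unlikely
        for _ in range(5):
            assert detect_terminal_repeats(random_sequence(5000, rng)) is None

    def test_longer_repeat_wins_when_both_kinds_qualify(self, rng):
        core = random_sequence(2000, rng)
        arm = random_sequence(150, rng)
        tir = random_sequence(20, rng)
        seq = arm + tir + core + reverse_complement(tir) + arm
        tr = detect_terminal_repeats(seq)
        assert tr.kind == "LTR" and tr.length >= 150


class TestPolyTail:
    def test_poly_a_at_three_prime(self):
        cons = "GC" * 200 + "A" * 15
        tail = detect_poly_tail(cons, "LINE/L1")
        assert tail.kind == "polyA" and tail.end == "3p"
        assert tail.interval == (400, 415)

    def test_poly_t_at_five_prime(self):
        cons = "T" * 15 + "GC" * 200
        tail = detect_poly_tail(cons, "SINE/tRNA")
        assert tail.kind == "polyT" and tail.end == "5p"
        assert tail.interval == (0, 15)

    def test_short_run_is_no_tail(self):
        assert detect_poly_tail("GC" * 200 + "A" * 6, "LINE/L1") is None

    def test_only_with_line_sine_hint(self):
        cons = "GC" * 200 + "A" * 15
        assert detect_poly_tail(cons, "LTR/Copia") is None

    def test_single_interruption_tolerated(self):
        cons = "GC" * 200 + "A" * 6 + "G" + "A" * 6
        tail = detect_poly_tail(cons, "LINE/L1")
        assert tail is not None and tail.interval[1] - tail.interval[0] == 13

    def test_terminal_n_run_ignored(self):
        cons = "GC" * 200 + "A" * 15 + "N" * 25
        tail = detect_poly_tail(cons, "LINE/L1")
        assert tail is not None and tail.interval == (400, 415)

    def test_microsatellite_motif(self):
        cons = "GC" * 200 + "TA" * 8
        params = BoundaryParams(poly_motifs=("TA",))
        tail = detect_poly_tail(cons, "LINE/L1", params)
        assert tail is not None and tail.kind == "TA"


def noisy_edge_msa(rng, core_len=2000, n_rows=12, noise=200, divergence=0.01):
    """Shared core flanked by per-row random sequence (consensus N there)."""
    core = random_sequence(core_len, rng)
    rows = []
    for i in range(n_rows):
        rows.append(
            (
                f"s{i}",
                random_sequence(noise, rng)
                + mutate_sequence(core, divergence, rng)
                + random_sequence(noise, rng),
            )
        )
    return Msa.from_rows(rows), core


class TestDefineBoundaries:
    def test_n_window_trimming_drops_flanking_noise(self, rng):
        msa, core = noisy_edge_msa(rng)
        res = define_boundaries(msa, "Unknown")
        assert res.terminal_repeat is None and res.tail is None
        # boundaries within one window of the true core edges
        assert abs(res.start_col - 200) <= 150
        assert abs(res.end_col - 2200) <= 150

    def test_all_n_consensus_raises(self):
        rows = [(f"s{i}", "ACGT"[i % 4] * 300) for i in range(8)]
        msa = Msa.from_rows(rows)  # every column is 8 different? no: uniform rows
        # build truly ambiguous alignment: each row a different base repeated
        with pytest.raises(NoTeRegionError):
            define_boundaries(msa, "Unknown", BoundaryParams(n_window=50))

    def test_cascade_prefers_terminal_repeat_over_tail(self, rng):
        # element with both LTR arms and a poly(A) ending: repeat wins
        arm = random_sequence(200, rng)
        inner = random_sequence(1500, rng)
        element = arm + inner + "A" * 15 + arm
        rows = [(f"s{i}", random_sequence(150, rng) + mutate_sequence(element, 0.005, rng) + random_sequence(150, rng)) for i in range(10)]
        res = define_boundaries(Msa.from_rows(rows), "LINE/L1")
        assert res.terminal_repeat is not None
        assert res.tail is None

    def test_tail_sets_three_prime_boundary(self, rng):
        body = random_sequence(1800, rng)
        element = body + "A" * 15
        rows = [(f"s{i}", random_sequence(150, rng) + mutate_sequence(element, 0.005, rng) + random_sequence(150, rng)) for i in range(10)]
        res = define_boundaries(Msa.from_rows(rows), "LINE/L1")
        assert res.tail is not None and res.tail.end == "3p"
        assert res.end_col == res.tail.interval[1]


class TestFinalizeConsensus:
    def test_no_gaps_and_reclassify_flag(self, rng):
        msa, core = noisy_edge_msa(rng, core_len=500, noise=0)
        rec = finalize_consensus(
            msa, 0, msa.width, name="x", left_ext=3000, right_ext=2500
        )
        assert "-" not in rec.consensus
        assert rec.reclassify  # 5500 > 4000
        assert len(rec.consensus) <= msa.width

    def test_consensus_matches_planted_core(self, rng):
        msa, core = noisy_edge_msa(rng, core_len=800, noise=0, divergence=0.01)
        rec = finalize_consensus(msa, 0, msa.width, name="x")
        matches = sum(a == b for a, b in zip(rec.consensus, core))
        assert matches / len(core) >= 0.99

    def test_extension_at_threshold_not_flagged(self, rng):
        msa, _ = noisy_edge_msa(rng, core_len=300, noise=0)
        rec = finalize_consensus(msa, 0, msa.width, name="x", left_ext=2000, right_ext=2000)
        assert not rec.reclassify  # 4000 is not larger than 4000


class TestFindOrfs:
    def test_embedded_orf_with_coordinates(self):
        seq = "C" * 10 + "ATG" + "GCA" * 40 + "TAA" + "C" * 10
        orfs = find_orfs(seq, min_len=100)
        assert any((o.start, o.end, o.strand) == (10, 136, "+") for o in orfs)

    def test_reverse_strand_symmetric(self):
        seq = "C" * 10 + "ATG" + "GCA" * 40 + "TAA" + "C" * 10
        rc = reverse_complement(seq)
        orfs = find_orfs(rc, min_len=100)
        L = len(rc)
        assert any((o.start, o.end, o.strand) == (L - 136, L - 10, "-") for o in orfs)

    def test_poly_n_has_none(self):
        assert find_orfs("N" * 600, min_len=100) == []

    def test_n_codons_never_start_or_stop(self):
        seq = "ANG" + "GCA" * 40 + "TNA" + "TAA"
        assert find_orfs(seq, min_len=30) == []


class TestOrientation:
    def make_record(self, seq):
        return ConsensusRecord(name="r", consensus=seq)

    def test_minus_majority_flips(self, rng):
        seq = random_sequence(600, rng)
        rec = self.make_record(seq)
        msa = msa_from(seq)
        hits = [((0, 300), "-", 900), ((300, 400), "+", 100)]
        out, out_msa = orient_consensus(rec, msa, domain_hits=hits)
        assert out.consensus == reverse_complement(seq)
        assert out_msa.row_str(0) == reverse_complement(seq)

    def test_plus_hits_unchanged(self, rng):
        seq = random_sequence(600, rng)
        rec = self.make_record(seq)
        out, _ = orient_consensus(rec, msa_from(seq), domain_hits=[((0, 100), "+", 100)])
        assert out.consensus == seq

    def test_tie_keeps_orientation(self, rng):
        seq = random_sequence(600, rng)
        hits = [((0, 100), "+", 100), ((100, 200), "-", 100)]
        out, _ = orient_consensus(self.make_record(seq), msa_from(seq), domain_hits=hits)
        assert out.consensus == seq

    def test_orf_fallback_flips_minus_orf(self):
        core = "ATG" + "GCA" * 150 + "TAA"
        seq = reverse_complement("C" * 20 + core + "C" * 20)
        out, _ = orient_consensus(self.make_record(seq), msa_from(seq))
        assert out.consensus == reverse_complement(seq)

    def test_no_evidence_unchanged(self, rng):
        seq = "N" * 400
        out, _ = orient_consensus(self.make_record(seq), msa_from(seq))
        assert out.consensus == seq
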