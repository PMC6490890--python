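"""PWM parsing, allelic scoring, background percentiles, and the 60% rule."""

import itertools
import math

import numpy as np
import pytest

from esnp.motif import (PWM, AlleleScore, MotifError, call_allele_specific,
                        load_jaspar, revcomp, score_alleles, score_percentile,
                        write_jaspar)


@pytest.fixture()
def toy4():
    """4-column matrix with consensus TTCC and moderate information."""
    counts = np.array([
        [5, 5, 10, 10],
        [10, 10, 60, 70],
        [5, 5, 20, 10],
        [80, 80, 10, 10],
    ], dtype=float)
    return PWM("TOY", "T0001", counts)


def test_single_column_all_A_closed_form():
    pwm = PWM("M", "M1", np.array([[10.0], [0.0], [0.0], [0.0]]), pseudocount=0.0)
    assert pwm.consensus == "A"
    assert pwm.log_odds[0, 0] == pytest.approx(math.log2(1 / 0.25))


def test_log_odds_match_hand_computation_with_pseudocount():
    counts = np.array([[8.0], [1.0], [1.0], [0.0]])
    pwm = PWM("M", "M1", counts, pseudocount=0.8)
    # frequency of A = (8 + 0.8*0.25) / (10 + 0.8)
    f_a = (8 + 0.2) / 10.8
    f_t = (0 + 0.2) / 10.8
    assert pwm.log_odds[0, 0] == pytest.approx(math.log2(f_a / 0.25))
    assert pwm.log_odds[3, 0] == pytest.approx(math.log2(f_t / 0.25))


def test_jaspar_roundtrip_preserves_counts(tmp_path, toy4):
    write_jaspar([toy4], tmp_path / "m.jaspar")
    (back,) = load_jaspar(tmp_path / "m.jaspar")
    assert np.array_equal(back.counts, toy4.counts)
    assert back.matrix_id == toy4.matrix_id and back.tf_name == toy4.tf_name


def test_jaspar_row_length_mismatch_raises(tmp_path):
    (tmp_path / "bad.jaspar").write_text(
        ">B0001 BAD\nA [ 1 2 3 ]\nC [ 1 2 ]\nG [ 1 2 3 ]\nT [ 1 2 3 ]\n")
    with pytest.raises(Exception):
        load_jaspar(tmp_path / "bad.jaspar")


def test_best_placement_matches_exhaustive_enumeration(toy4):
    seq = "ACGTTCCAGGTTACC"
    best = toy4.best_score_in(seq)
    # brute force over every offset and strand
    candidates = []
    for off in range(len(seq) - toy4.length + 1):
        candidates.append((toy4.score(seq[off:off + 4]), off, "+"))
    rc = revcomp(seq)
    for off in range(len(rc) - toy4.length + 1):
        fwd_off = len(seq) - toy4.length - off
        candidates.append((toy4.score(rc[off:off + 4]), fwd_off, "-"))
    assert best[0] == pytest.approx(max(c[0] for c in candidates), abs=1e-12)


def test_palindromic_pwm_is_strand_symmetric():
    # consensus ACGT == its own reverse complement, symmetric counts
    counts = np.array([
        [70, 10, 10, 10],
        [10, 70, 10, 10],
        [10, 10, 70, 10],
        [10, 10, 10, 70],
    ], dtype=float)
    pal = PWM("PAL", "P1", counts)
    seq = "GGACGTAGCTTAAGG"
    s_fwd = max(pal.score(seq[o:o + 4]) for o in range(len(seq) - 3))
    rc = revcomp(seq)
    s_rev = max(pal.score(rc[o:o + 4]) for o in range(len(rc) - 3))
    assert s_fwd == pytest.approx(s_rev, abs=1e-12)


# ---------------------------------------------------------------------------
# Percentiles
# ---------------------------------------------------------------------------

def test_exact_percentile_equals_direct_enumeration(toy4):
    for score in (-6.0, -2.0, 0.0, 1.5, toy4.max_score):
        pct, _ = score_percentile(toy4, score, mode="exact")
        count = sum(1 for kmer in itertools.product("ACGT", repeat=4)
                    if toy4.score("".join(kmer)) <= score + 1e-12)
        assert pct == pytest.approx(100 * count / 256, abs=1e-9)


def test_percentile_boundary_values(toy4):
    assert score_percentile(toy4, toy4.max_score, mode="exact")[0] == pytest.approx(100.0)
    assert score_percentile(toy4, toy4.min_score - 1, mode="exact")[0] == 0.0


def test_sampled_percentile_within_three_mc_se(toy4):
    for score in (-3.0, 0.5, 2.0):
        exact, _ = score_percentile(toy4, score, mode="exact")
        sampled, se = score_percentile(toy4, score, mode="sampled", seed=9)
        assert abs(sampled - exact) <= 3 * se


def test_percentile_monotone_in_score(toy4):
    scores = np.linspace(toy4.min_score, toy4.max_score, 25)
    pcts = [score_percentile(toy4, s, mode="exact")[0] for s in scores]
    assert all(b >= a for a, b in zip(pcts, pcts[1:]))


def test_exact_mode_refused_for_long_motifs():
    counts = np.ones((4, 12))
    pwm = PWM("L", "L1", counts)
    with pytest.raises(MotifError):
        score_percentile(pwm, 0.0, mode="exact")


# ---------------------------------------------------------------------------
# Allelic scoring
# ---------------------------------------------------------------------------

def test_consensus_completing_allele_reaches_matrix_max(toy4):
    # genome: flanks + TTCC site with SNP at site column 0 (T high, G low)
    left, right = "ACAGAGA", "AGACAGACA"
    genome = {"chr1": left + "TTCC" + right}
    pos = len(left) + 1  # 1-based SNP position at the T
    (s_ref, _, _), (s_alt, _, _) = score_alleles(toy4, genome, "chr1", pos, "T", "G")
    assert s_ref == pytest.approx(toy4.max_score, abs=1e-12)
    assert s_ref > s_alt


def test_reference_allele_mismatch_is_a_validation_error(toy4):
    genome = {"chr1": "ACAGATTCCAGACAGACA"}
    with pytest.raises(MotifError):
        score_alleles(toy4, genome, "chr1", 6, "C", "G")


def test_snp_needs_seven_bp_flanks(toy4):
    genome = {"chr1": "ACGTACGTACGT"}
    with pytest.raises(MotifError):
        score_alleles(toy4, genome, "chr1", 2, "C", "G")


def test_strand_symmetry_of_allelic_scores(toy4):
    genome = {"chr1": "GGGGATTCCAGGTTACCAAA"}
    pos = 9
    ref, alt = genome["chr1"][pos - 1], "A"
    fwd = score_alleles(toy4, genome, "chr1", pos, ref, alt)
    # reverse-complement the genome; SNP lands at mirrored position
    rc_genome = {"chr1": revcomp(genome["chr1"])}
    rc_pos = len(genome["chr1"]) - pos + 1
    rev = score_alleles(toy4, rc_genome, "chr1", rc_pos, revcomp(ref), revcomp(alt))
    assert fwd[0][0] == pytest.approx(rev[0][0], abs=1e-12)
    assert fwd[1][0] == pytest.approx(rev[1][0], abs=1e-12)


# ---------------------------------------------------------------------------
# The 60th-percentile rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p1, p2, verdict, preferred", [
    (75.0, 40.0, "allele_specific", "A"),
    (40.0, 75.0, "allele_specific", "G"),
    (75.0, 70.0, "shared", None),
    (61.0, 61.0, "shared", None),
    (60.0, 40.0, "none", None),    # exactly 60 never satisfies strict >
    (40.0, 60.0, "none", None),
    (60.0, 60.0, "none", None),
    (75.0, 60.0, "none", None),    # other allele not strictly below
    (50.0, 40.0, "none", None),
    (61.0, 59.0, "allele_specific", "A"),
])
def test_sixty_percentile_truth_table(toy4, p1, p2, verdict, preferred):
    a1 = AlleleScore("A", 1.0, p1, 0, "+")
    a2 = AlleleScore("G", 0.5, p2, 0, "+")
    call = call_allele_specific("snp", toy4, a1, a2)
    assert call.verdict == verdict
    assert call.preferred_allele == preferred
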