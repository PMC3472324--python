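"""PSPM/PWM construction, exact score thresholds, scanning, library I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonkit.motif_core import (
    PSPM,
    Background,
    ScoreDistribution,
    build_pspm,
    information_content,
    make_library_entry,
    pspm_to_pwm,
    read_motif_library,
    scan,
    score_threshold,
    write_motif_library,
)
from regulonkit.sequence_io import reverse_complement
from tests.conftest import random_dna

CODY_SITES = ["AATTTTCAGAAAATT", "AATTTTCTGAAAATT"]  # W expanded to A/T


def enum_all_word_scores(sd: ScoreDistribution, bg: Background, w: int):
    """Enumerate integer scores and probabilities of all 4^w words."""
    scores = np.zeros(1, dtype=np.int64)
    probs = np.ones(1)
    for j in range(w):
        scores = (scores[:, None] + sd.int_matrix[j][None, :]).ravel()
        probs = (probs[:, None] * bg.freqs[None, :]).ravel()
    return scores, probs


def enum_threshold(scores, probs, p):
    """Smallest enumerated score whose upper-tail mass is <= p."""
    uniq, inv = np.unique(scores, return_inverse=True)
    mass = np.bincount(inv, weights=probs)
    tail = mass[::-1].cumsum()[::-1]
    ok = np.nonzero(tail <= p)[0]
    return int(uniq[ok[0]]) if len(ok) else int(uniq[-1]) + 1


class TestBuildPspm:
    def test_identical_sites_give_unit_columns(self):
        pspm = build_pspm(["ACGT"] * 4, pseudocount=0)
        assert np.allclose(pspm.matrix, np.eye(4))
        assert pspm.site_count == 4

    def test_counting(self):
        pspm = build_pspm(["AA", "AT"], pseudocount=0)
        assert np.allclose(pspm.matrix[1], [0.5, 0, 0, 0.5])

    def test_degenerate_consensus_expansion(self):
        pspm = build_pspm(CODY_SITES, pseudocount=0)
        assert np.allclose(pspm.matrix[7], [0.5, 0, 0, 0.5])
        unit_rows = [j for j in range(pspm.width) if j != 7]
        assert np.allclose(pspm.matrix[unit_rows].max(axis=1), 1.0)

    def test_ragged_and_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_pspm(["ACGT", "ACG"])
        with pytest.raises(ValueError):
            build_pspm([])


@st.composite
def site_sets(draw):
    w = draw(st.integers(min_value=4, max_value=12))
    return draw(
        st.lists(
            st.text(alphabet="ACGT", min_size=w, max_size=w),
            min_size=1, max_size=10,
        )
    )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(sites=site_sets())
def test_pspm_probabilities_and_information_content_well_formed(sites):
    """Any site set yields a stochastic matrix with non-negative relative
    entropy against the uniform background."""
    pspm = build_pspm(sites, pseudocount=0.5)
    assert np.allclose(pspm.matrix.sum(axis=1), 1.0)
    assert (pspm.matrix > 0).all()
    _, total = information_content(pspm, Background.uniform())
    assert total >= -1e-9


class TestPspmToPwm:
    def test_uniform_pspm_uniform_background_is_zero(self, uniform_bg):
        pspm = PSPM(np.full((5, 4), 0.25))
        pwm = pspm_to_pwm(pspm, uniform_bg, pseudocount=0)
        assert np.allclose(pwm.matrix, 0)
        assert pwm.min_score == pwm.max_score == 0

    def test_unit_column_regularization_arithmetic(self, uniform_bg):
        pspm = PSPM(np.array([[1.0, 0, 0, 0]]))
        pwm = pspm_to_pwm(pspm, uniform_bg, pseudocount=0.01)
        expected_a = math.log2(((1 + 0.01 * 0.25) / 1.01) / 0.25)
        expected_other = math.log2(((0.01 * 0.25) / 1.01) / 0.25)
        assert pwm.matrix[0, 0] == pytest.approx(expected_a)
        assert np.allclose(pwm.matrix[0, 1:], expected_other)
        assert pwm.matrix[0, 1] < -5

    def test_doubling_background_base_shifts_entries_one_bit(self):
        pspm = build_pspm(["ACGT", "AAGT", "ACTT", "GCGA"], pseudocount=1)
        bg1 = Background([0.2, 0.3, 0.3, 0.2])
        bg2 = Background([0.4, 0.2, 0.2, 0.2])
        pwm1 = pspm_to_pwm(pspm, bg1, pseudocount=0)
        pwm2 = pspm_to_pwm(pspm, bg2, pseudocount=0)
        assert np.allclose(pwm1.matrix[:, 0] - pwm2.matrix[:, 0], 1.0)

    def test_zero_probability_without_pseudocount_rejected(self, uniform_bg):
        pspm = PSPM(np.array([[1.0, 0, 0, 0]]))
        with pytest.raises(ValueError):
            pspm_to_pwm(pspm, uniform_bg, pseudocount=0)

    def test_consensus_word_scores_max_score(self, rng, uniform_bg):
        pspm = PSPM(rng.dirichlet(np.ones(4), size=8))
        pwm = pspm_to_pwm(pspm, uniform_bg, pseudocount=0.01)
        # per-column argmax of the PWM defines its best word
        best = "".join("ACGT"[i] for i in pwm.matrix.argmax(axis=1))
        assert pwm.score_word(best) == pytest.approx(pwm.max_score)


class TestScoreThreshold:
    def test_pvalue_one_returns_min_score(self, uniform_bg):
        pspm = build_pspm(["ACGTAC", "ACGTAT", "ACGAAC"], pseudocount=0.5)
        pwm = pspm_to_pwm(pspm, uniform_bg, pseudocount=0)
        t = score_threshold(pwm, 1.0, uniform_bg)
        assert t == pytest.approx(pwm.min_score, abs=pwm.width * 1e-3)

    def test_width2_example_matches_dinucleotide_enumeration(self, uniform_bg):
        pspm = PSPM(np.array([[1.0, 0, 0, 0], [0.5, 0, 0, 0.5]]))
        pwm = pspm_to_pwm(pspm, uniform_bg, pseudocount=0.01)
        sd = ScoreDistribution(pwm, uniform_bg)
        scores, probs = enum_all_word_scores(sd, uniform_bg, 2)
        assert sd.threshold_int(0.125) == enum_threshold(scores, probs, 0.125)

    def test_monotone_in_pvalue(self, rng, uniform_bg):
        pspm = PSPM(rng.dirichlet(np.ones(4), size=7))
        pwm = pspm_to_pwm(pspm, uniform_bg, pseudocount=0.01)
        ps = [1.0, 0.5, 1e-1, 1e-2, 1e-3, 1e-4]
        ts = [score_threshold(pwm, p, uniform_bg) for p in ps]
        assert all(a <= b + 1e-12 for a, b in zip(ts, ts[1:]))

    def test_nonpositive_pvalue_rejected(self, uniform_bg):
        pspm = PSPM(np.full((4, 4), 0.25))
        pwm = pspm_to_pwm(pspm, uniform_bg, pseudocount=0.01)
        with pytest.raises(ValueError):
            score_threshold(pwm, 0.0, uniform_bg)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        w = int(rng.integers(4, 9))
        pspm = PSPM(rng.dirichlet(np.ones(4) * 0.5, size=w))
        bg = Background(rng.dirichlet(np.ones(4) * 5))
        pwm = pspm_to_pwm(pspm, bg, pseudocount=0.01)
        sd = ScoreDistribution(pwm, bg)
        scores, probs = enum_all_word_scores(sd, bg, w)
        for p in (1e-2, 1e-3, 1e-4):
            assert sd.threshold_int(p) == enum_threshold(scores, probs, p)

    def test_pvalues_match_enumeration(self, rng):
        w = 6
        pspm = PSPM(rng.dirichlet(np.ones(4) * 0.5, size=w))
        bg = Background(rng.dirichlet(np.ones(4) * 5))
        pwm = pspm_to_pwm(pspm, bg, pseudocount=0.01)
        sd = ScoreDistribution(pwm, bg)
        scores, probs = enum_all_word_scores(sd, bg, w)
        for s in rng.choice(scores, size=30):
            assert sd.pvalue(int(s)) == pytest.approx(
                probs[scores >= s].sum(), abs=1e-12
            )


def naive_scan(seq, entry, bg):
    """Per-window loop with the same discretized comparison rule."""
    sd = ScoreDistribution(entry.pwm, bg, entry.granularity)
    cutoff = sd.threshold_int(entry.cutoff_pvalue)
    hits = []
    w = entry.width
    for i in range(len(seq) - w + 1):
        for strand in "+-":
            word = seq[i : i + w]
            if strand == "-":
                word = reverse_complement(word)
            enc = np.array(["ACGTN".index(c) for c in word])
            si = sd.word_int_score(enc)
            if si >= cutoff:
                hits.append((i, strand, si))
    return hits


class TestScan:
    def test_sequence_shorter_than_motif_gives_no_hits(self, uniform_bg):
        e = make_library_entry("X", ["ACGTAC"] * 5, uniform_bg)
        assert scan("ACG", e, uniform_bg) == []

    def test_walr_style_planted_site_attains_max_score(self, rng, uniform_bg):
        spacer_sites = [
            "TGTAA" + random_dna(rng, 6) + "TGTAA" for _ in range(10)
        ]
        entry = make_library_entry("WalR", spacer_sites, uniform_bg,
                                   cutoff_pvalue=1e-4)
        background = random_dna(rng, 200)
        # plant the per-column best word so it attains max_score
        best = entry.pspm.consensus()
        seq = background[:90] + best + background[90:]
        hits = scan(seq, entry, uniform_bg, both_strands=False)
        top = max(hits, key=lambda h: h.score)
        assert top.start == 90
        assert top.score == pytest.approx(entry.pwm.max_score)

    def test_reverse_complement_symmetry(self, rng, uniform_bg):
        entry = make_library_entry("X", ["TTGACATT"] * 6 + ["TTGTCATT"] * 2,
                                   uniform_bg, cutoff_pvalue=1e-3)
        seq = random_dna(rng, 500)
        fwd = scan(seq, entry, uniform_bg, both_strands=True)
        rev = scan(reverse_complement(seq), entry, uniform_bg, both_strands=True)
        n, w = len(seq), entry.width
        mirrored = {
            (n - h.end, "-" if h.strand == "+" else "+",
             round(h.score, 9), h.matched_seq)
            for h in rev
        }
        got = {(h.start, h.strand, round(h.score, 9), h.matched_seq) for h in fwd}
        assert got == mirrored

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_naive_per_window_scorer(self, seed, uniform_bg):
        rng = np.random.default_rng(seed)
        w = int(rng.integers(6, 13))
        sites = [random_dna(rng, w) for _ in range(6)]
        entry = make_library_entry("X", sites, uniform_bg, cutoff_pvalue=1e-2)
        seq = random_dna(rng, 2000)
        got = {(h.start, h.strand) for h in scan(seq, entry, uniform_bg)}
        expected = {(i, s) for i, s, _ in naive_scan(seq, entry, uniform_bg)}
        assert got == expected

    def test_n_positions_score_as_background(self, uniform_bg):
        entry = make_library_entry("X", ["AAAAAA"] * 4, uniform_bg,
                                   cutoff_pvalue=1.0)
        hits = scan("ANAAAA", entry, uniform_bg, both_strands=False)
        h0 = [h for h in hits if h.start == 0][0]
        full = scan("AAAAAA", entry, uniform_bg, both_strands=False)[0]
        # the N column contributes exactly 0 bits
        per_col = full.score / 6
        assert h0.score == pytest.approx(full.score - per_col)


class TestInformationContent:
    def test_uniform_column_zero_bits(self, uniform_bg):
        per, total = information_content(PSPM(np.full((3, 4), 0.25)), uniform_bg)
        assert total == 0

    def test_unit_column_two_bits(self, uniform_bg):
        per, total = information_content(PSPM(np.array([[1.0, 0, 0, 0]])),
                                         uniform_bg)
        assert total == pytest.approx(2.0)

    def test_degenerate_consensus_total(self, uniform_bg):
        pspm = build_pspm(CODY_SITES, pseudocount=0)
        _, total = information_content(pspm, uniform_bg)
        assert total == pytest.approx(14 * 2 + 1 * 1)


class TestLibraryIO:
    def test_roundtrip_three_entries(self, tmp_path, uniform_bg, rng):
        entries = [
            make_library_entry(f"TF{i}", [random_dna(rng, 6 + 2 * i)
                                          for _ in range(8)],
                               uniform_bg, cutoff_pvalue=10 ** -(4 + i))
            for i in range(3)
        ]
        path = tmp_path / "lib.meme"
        write_motif_library(entries, path, uniform_bg)
        back = read_motif_library(path)
        assert [e.tf_name for e in back] == [e.tf_name for e in entries]
        for a, b in zip(entries, back):
            assert a.pspm.width == b.pspm.width
            assert a.pspm.site_count == b.pspm.site_count
            assert a.cutoff_pvalue == pytest.approx(b.cutoff_pvalue)
            assert np.allclose(a.pspm.matrix, b.pspm.matrix, atol=1e-5)
            assert a.cutoff_score == pytest.approx(b.cutoff_score, abs=0.05)

    def test_hand_written_minimal_file(self, tmp_path):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF toy\n"
            "letter-probability matrix: alength= 4 w= 6 nsites= 10 E= 0\n"
            + " 1.0 0.0 0.0 0.0\n" * 6
        )
        path = tmp_path / "toy.meme"
        path.write_text(text)
        (entry,) = read_motif_library(path)
        assert entry.pspm.width == 6
        assert entry.pspm.consensus() == "AAAAAA"

    def test_slightly_denormalized_row_renormalized_with_warning(self, tmp_path):
        text = (
            "MEME version 4\n\nBackground letter frequencies\n"
            "A 0.25 C 0.25 G 0.25 T 0.25\n\nMOTIF toy\n"
            "letter-probability matrix: alength= 4 w= 1 nsites= 4 E= 0\n"
            " 0.2504 0.2500 0.2500 0.2500\n"
        )
        path = tmp_path / "toy.meme"
        path.write_text(text)
        with pytest.warns(UserWarning, match="renormaliz"):
            (entry,) = read_motif_library(path)
        assert entry.pspm.matrix.sum() == pytest.approx(1.0)

    def test_badly_denormalized_row_rejected(self, tmp_path):
        text = (
            "MEME version 4\n\nBackground letter frequencies\n"
            "A 0.25 C 0.25 G 0.25 T 0.25\n\nMOTIF toy\n"
            "letter-probability matrix: alength= 4 w= 1 nsites= 4 E= 0\n"
            " 0.5 0.5 0.5 0.5\n"
        )
        path = tmp_path / "toy.meme"
        path.write_text(text)
        with pytest.raises(Exception):
            read_motif_library(path)

    def test_malformed_row_error_names_line(self, tmp_path):
        text = (
            "MEME version 4\n\nBackground letter frequencies\n"
            "A 0.25 C 0.25 G 0.25 T 0.25\n\nMOTIF toy\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 4 E= 0\n"
            " 0.25 0.25 0.25\n"
        )
        path = tmp_path / "toy.meme"
        path.write_text(text)
        with pytest.raises(Exception, match=":8"):
            read_motif_library(path)
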