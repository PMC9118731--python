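"""Repeat segmentation, element labels, composition, similarity."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given
from hypothesis import strategies as st

from ankylotherm.repeats import (
    CANONICAL_REPEATS,
    REPEAT_LENGTH,
    alignment_score,
    assign_elements,
    composition_profile,
    consensus_pwm,
    enrichment,
    percent_similarity,
    segment_repeats,
    template_labels,
)
from ankylotherm.structures import ResidueSequence, extract_sequence
from ankylotherm.synthetic import RepeatGeometrySpec, make_repeat_structure

from conftest import make_seq


class TestSegmentation:
    def test_empty_sequence_gives_zero_repeats(self):
        ann = segment_repeats(ResidueSequence("e", ""))
        assert ann.n_repeats == 0 and ann.residual == []

    def test_short_sequence_is_all_residual(self):
        ann = segment_repeats(make_seq("ACDEFGHIKL"))
        assert ann.n_repeats == 0
        assert len(ann.residual) == 10

    def test_consensus_triplet_found_at_expected_offsets(self):
        seq = make_seq(CANONICAL_REPEATS[0] * 3)
        ann = segment_repeats(seq)
        assert [r.span for r in ann.repeats] == [(1, 33), (34, 66), (67, 99)]
        assert ann.residual == []
        # brute-force oracle: the chosen offsets are the top-scoring
        # non-overlapping placement over all offset combinations
        pwm = consensus_pwm()
        letters = seq.letters
        idx = {aa: k for k, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}

        def window_score(off):
            return sum(pwm[p, idx[letters[off + p]]] for p in range(REPEAT_LENGTH))

        best = max(
            (
                (sum(map(window_score, offs)), offs)
                for offs in itertools.combinations(range(67), 3)
                if offs[1] >= offs[0] + 33 and offs[2] >= offs[1] + 33
            ),
            key=lambda t: t[0],
        )
        assert best[1] == (0, 33, 66)

    def test_repeats_disjoint_and_cover_plus_residual(self):
        letters = "G" * 7 + CANONICAL_REPEATS[0] + CANONICAL_REPEATS[1] + "G" * 4
        ann = segment_repeats(make_seq(letters))
        covered = sum(r.span[1] - r.span[0] + 1 for r in ann.repeats)
        assert covered + len(ann.residual) == len(letters)
        spans = [r.span for r in ann.repeats]
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def test_n_expected_caps_repeat_count(self):
        ann = segment_repeats(make_seq(CANONICAL_REPEATS[0] * 3), n_expected=2)
        assert ann.n_repeats == 2

    def test_malformed_consensus_rejected(self):
        with pytest.raises(ValueError):
            segment_repeats(make_seq("A" * 40), consensus=np.zeros((5, 20)))


class TestElements:
    def test_template_mode_is_the_fixed_template(self):
        ann = segment_repeats(make_seq(CANONICAL_REPEATS[0]))
        ann = assign_elements(ann)
        assert ann.repeats[0].element_labels == template_labels()
        labels = ann.repeats[0].element_labels
        assert [labels[p - 1] for p in range(5, 13)] == ["a1"] * 8
        assert [labels[p - 1] for p in range(15, 25)] == ["a2"] * 10
        assert [labels[p - 1] for p in range(25, 32)] == ["bhp"] * 7

    def test_structure_mode_recovers_planted_geometry(self, ideal_domain):
        seq = extract_sequence(ideal_domain, "A")
        ann = assign_elements(segment_repeats(seq), ideal_domain, "A")
        for rep in ann.repeats:
            labels = rep.element_labels
            # the two built helices and the built hairpin, at core positions
            assert all(labels[p - 1] == "a1" for p in range(5, 13))
            assert all(labels[p - 1] == "a2" for p in range(15, 25))
            assert all(labels[p - 1] == "bhp" for p in range(25, 32))

    def test_structure_mode_missing_residues_is_an_error(self, ideal_domain):
        seq = extract_sequence(ideal_domain, "A")
        ann = segment_repeats(seq)
        truncated = make_repeat_structure(
            RepeatGeometrySpec(n_repeats=1, start_number=1872)
        )
        with pytest.raises(ValueError):
            assign_elements(ann, truncated, "A")


class TestComposition:
    def test_pure_alanine_helix(self):
        prof = composition_profile(make_seq("AAAA"), ["a1"] * 4, "α-helix")
        assert prof.frequencies == {"A": 1.0}
        assert prof.n == 4

    def test_alternating_labels_hand_count(self):
        prof = composition_profile(
            make_seq("ADAD"), ["a1", "bhp", "a1", "bhp"], "α-helix"
        )
        assert prof.frequencies == {"A": 1.0}
        assert prof.n == 2

    def test_empty_selector_gives_empty_profile(self):
        prof = composition_profile(make_seq("AAAA"), ["loop"] * 4, "β-hairpin")
        assert prof.n == 0 and prof.frequencies == {}

    def test_frequencies_sum_to_one(self):
        letters = CANONICAL_REPEATS[0]
        prof = composition_profile(make_seq(letters), template_labels(), "all")
        assert abs(sum(prof.frequencies.values()) - 1.0) < 1e-9

    def test_alanine_enriched_helices_vs_reference(self):
        # an alanine-rich helical module vs a generic one: the helix-class
        # alanine frequency must be strictly higher in the enriched domain
        ala_rich = "DKDG" + "AAAALKAA" + "NT" + "AAHLAAKEGA" + "LEVVKDNGR"
        generic = CANONICAL_REPEATS[1]
        labels = template_labels()
        fa = composition_profile(make_seq(ala_rich), labels, "α-helix").frequencies
        fg = composition_profile(make_seq(generic), labels, "α-helix").frequencies
        assert fa.get("A", 0) > fg.get("A", 0)


class TestEnrichment:
    def test_self_enrichment_is_zero(self):
        prof = composition_profile(make_seq(CANONICAL_REPEATS[0]),
                                   template_labels(), "all")
        table = enrichment(prof, prof)
        assert all(v == 0.0 for v in table.entries.values())

    def test_hand_arithmetic_doubling(self):
        a = composition_profile(make_seq("AD"), ["a1", "a1"], "α-helix")
        b = composition_profile(make_seq("ADDD"), ["a1"] * 4, "α-helix")
        table = enrichment(a, b, pseudocount=0.0)
        assert table.entries["A"] == pytest.approx(1.0)  # 0.5 vs 0.25

    def test_class_mismatch_is_an_error(self):
        a = composition_profile(make_seq("AA"), ["a1", "a1"], "α-helix")
        b = composition_profile(make_seq("AA"), ["bhp", "bhp"], "β-hairpin")
        with pytest.raises(ValueError):
            enrichment(a, b)

    def test_acidic_enrichment_detected(self):
        acidic = composition_profile(make_seq("DDEEDDE"), ["bhp"] * 7, "β-hairpin")
        neutral = composition_profile(make_seq("GSTNQSA"), ["bhp"] * 7, "β-hairpin")
        table = enrichment(acidic, neutral)
        assert table.entries["D"] > 0 and table.entries["E"] > 0


class TestSimilarity:
    def test_identical_sequences_are_100(self):
        s = make_seq("ACDEFGHIKL")
        assert percent_similarity(s, s) == 100.0

    def test_hand_checked_three_quarters(self):
        # BLOSUM62: A-A, C-C, D-D positive; E-G negative -> 3/4 columns
        assert percent_similarity(make_seq("ACDE"), make_seq("ACDG")) == 75.0

    def test_symmetry(self):
        a, b = make_seq("MKVLAWQY"), make_seq("MKILAWEY")
        assert percent_similarity(a, b) == pytest.approx(percent_similarity(b, a))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            percent_similarity(ResidueSequence("e", ""), make_seq("ACD"))

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=6),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=6))
    def test_alignment_score_matches_enumeration(self, a, b):
        """With linear gaps (open == extend) the aligner's global score must
        equal exhaustive enumeration over all alignments."""
        gap = 4.0
        subst = substitution_matrices.load("BLOSUM62")

        def brute(i, j, memo={}):
            # fresh memo per example
            key = (a, b, i, j)
            if key in memo:
                return memo[key]
            if i == len(a) and j == len(b):
                return 0.0
            best = -np.inf
            if i < len(a) and j < len(b):
                best = max(best, subst[a[i], b[j]] + brute(i + 1, j + 1))
            if i < len(a):
                best = max(best, -gap + brute(i + 1, j))
            if j < len(b):
                best = max(best, -gap + brute(i, j + 1))
            memo[key] = best
            return best

        expected = brute(0, 0)
        got = alignment_score(a, b, gap_open=gap, gap_extend=gap)
        assert got == pytest.approx(expected)
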