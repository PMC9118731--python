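"""Boltzmann-inverted pair potential and disorder scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ankylotherm.disorder import (
    BENCHMARK_DISORDERED,
    BENCHMARK_ORDERED,
    PairPotential,
    charge_hydrophobicity,
    disorder_profile,
    domain_mean,
    estimate_pair_potential,
    read_potential_tsv,
    read_scores_tsv,
)
from ankylotherm.structures import ResidueSequence

from conftest import make_seq


def toy_potential(e_aa: float, e_bb: float, e_ab: float = 0.0) -> PairPotential:
    idx = pd.Index(["A", "C"])
    e = pd.DataFrame([[e_aa, e_ab], [e_ab, e_bb]], index=idx, columns=idx)
    ph = pd.DataFrame(0.25, index=idx, columns=idx)
    return PairPotential(e, ph, ph)


class TestPairPotential:
    def test_single_letter_corpus_energy_zero(self):
        # observed pairing equals the marginal product when only one letter
        pot = estimate_pair_potential([make_seq("AAAAAA")], 2)
        assert pot.energies.loc["A", "A"] == pytest.approx(0.0)

    def test_alternating_toy_corpus_hand_counted(self):
        # "ADAD", window 1: ordered pairs AD, DA, AD both directions ->
        # rho_AD = rho_DA = 0.5; marginals 0.5/0.5 -> rho* = 0.25
        pot = estimate_pair_potential([make_seq("ADAD")], 1)
        assert pot.energies.loc["A", "D"] == pytest.approx(-np.log(2))
        assert pot.energies.loc["D", "A"] == pytest.approx(-np.log(2))
        assert np.isnan(pot.energies.loc["A", "A"])  # never observed: flagged

    def test_symmetry_and_swap_antisymmetry(self):
        corpus = [make_seq(BENCHMARK_ORDERED), make_seq(BENCHMARK_DISORDERED)]
        pot = estimate_pair_potential(corpus, 3)
        e = pot.energies.values
        assert np.allclose(e, e.T, equal_nan=True)
        assert np.allclose(pot.swapped().energies.values, -e, equal_nan=True)

    def test_too_small_corpus_rejected(self):
        with pytest.raises(ValueError):
            estimate_pair_potential([make_seq("A")], 1)

    def test_unseen_cells_imputed_unfavourably(self):
        pot = estimate_pair_potential([make_seq("ADAD")], 1)
        imputed = pot.imputed()
        assert not imputed.isna().any().any()
        assert imputed.loc["A", "A"] > imputed.loc["A", "D"]


class TestDisorderProfile:
    def test_self_attraction_lowers_scores(self):
        attract = toy_potential(-2.0, +2.0)
        pa = disorder_profile(make_seq("A" * 12), attract, 5, midpoint=0, slope=1)
        pc = disorder_profile(make_seq("C" * 12), attract, 5, midpoint=0, slope=1)
        assert np.all(pa.scores < pc.scores)

    def test_scores_within_unit_interval(self):
        pot = estimate_pair_potential([make_seq(BENCHMARK_ORDERED)], 2)
        prof = disorder_profile(make_seq("MKVLILACLVAL"), pot, 5)
        assert np.all((prof.scores >= 0) & (prof.scores <= 1))

    def test_window_energy_matches_exhaustive_enumeration(self):
        """Tiny two-letter sequences: windowed energies recomputed by a
        separate brute-force loop over window members."""
        pot = toy_potential(-1.0, 0.5, 0.25)
        letters = "ACCAACCA"
        window = 5
        prof = disorder_profile(make_seq(letters), pot, window,
                                midpoint=0.0, slope=1.0)
        e = pot.energies
        half = window // 2
        for p in range(len(letters)):
            members = [
                e.loc[letters[p], letters[q]]
                for q in range(max(0, p - half), min(len(letters), p + half + 1))
                if q != p
            ]
            expected = 1 / (1 + np.exp(-np.mean(members)))
            assert prof.scores[p] == pytest.approx(expected)

    def test_reversal_invariance(self):
        pot = toy_potential(-1.0, 1.0, 0.3)
        s = "AACCCACCAA"
        f = disorder_profile(make_seq(s), pot, 3, midpoint=0, slope=1).scores
        r = disorder_profile(make_seq(s[::-1]), pot, 3, midpoint=0, slope=1).scores
        assert np.allclose(f, r[::-1])

    def test_uniform_downshift_never_raises_scores(self):
        pot = toy_potential(-0.5, 0.8, 0.1)
        s = make_seq("ACACCCAA")
        base = disorder_profile(s, pot, 3, midpoint=0, slope=1).scores
        shifted = disorder_profile(s, pot.shifted(-1.5), 3,
                                   midpoint=0, slope=1).scores
        assert np.all(shifted <= base + 1e-12)

    def test_benchmarks_straddle_half_under_default_potential(self):
        po = disorder_profile(make_seq(BENCHMARK_ORDERED))
        pd_ = disorder_profile(make_seq(BENCHMARK_DISORDERED))
        assert po.mean < 0.5 < pd_.mean

    def test_missing_letters_named_in_error(self):
        with pytest.raises(KeyError, match="W"):
            disorder_profile(make_seq("AWA"), toy_potential(-1, 1), 3)

    def test_even_or_tiny_window_rejected(self):
        for bad in (2, 4):
            with pytest.raises(ValueError):
                disorder_profile(make_seq("ACAC"), toy_potential(-1, 1), bad)


class TestDomainMean:
    def test_constant_profile(self):
        prof = disorder_profile(make_seq("A" * 10), toy_potential(-1, 1), 3,
                                midpoint=0, slope=1)
        prof.scores = np.full(10, 0.4)
        assert domain_mean(prof) == pytest.approx(0.4)

    def test_hand_mean_over_span(self):
        prof = disorder_profile(make_seq("AAA"), toy_potential(-1, 1), 3,
                                midpoint=0, slope=1)
        prof.scores = np.array([0.2, 0.4, 0.6])
        assert domain_mean(prof, (1, 3)) == pytest.approx(0.4)
        assert domain_mean(prof, (2, 2)) == pytest.approx(0.4)

    def test_empty_span_rejected(self):
        prof = disorder_profile(make_seq("AAA"), toy_potential(-1, 1), 3,
                                midpoint=0, slope=1)
        with pytest.raises(ValueError):
            domain_mean(prof, (100, 200))


class TestChargeHydrophobicity:
    def test_polyglycine_is_neutral(self):
        assert charge_hydrophobicity(make_seq("GGGG")).mean_net_charge == 0.0

    def test_balanced_charges_cancel(self):
        assert charge_hydrophobicity(make_seq("DEKR")).mean_net_charge == 0.0

    def test_polyaspartate_fully_charged_disordered_side(self):
        pt = charge_hydrophobicity(make_seq("DDDD"))
        assert pt.mean_net_charge == pytest.approx(1.0)
        # boundary by hand: H(D) = (-3.5 + 4.5)/9 = 1/9;
        # 2.785 * 1/9 - 1.151 = -0.8416 < 1.0 -> disordered side
        assert pt.mean_hydrophobicity == pytest.approx(1 / 9)
        assert pt.classification == "disordered-side"

    def test_hydrophobic_stretch_is_ordered_side(self):
        pt = charge_hydrophobicity(make_seq("LLLLVVVVIIII"))
        assert pt.classification == "ordered-side"

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_outputs_always_in_range(self, s):
        pt = charge_hydrophobicity(make_seq(s))
        assert 0 <= pt.mean_net_charge <= 1
        assert 0 <= pt.mean_hydrophobicity <= 1


class TestTsvIngestion:
    def test_external_scores_roundtrip(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("residue\tscore\n1872\t0.40\n1873\t0.34\n")
        prof = read_scores_tsv(p)
        assert domain_mean(prof, (1872, 1873)) == pytest.approx(0.37)

    def test_external_scores_validated(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("residue\tscore\n1\t1.40\n")
        with pytest.raises(ValueError):
            read_scores_tsv(p)

    def test_potential_tsv(self, tmp_path):
        p = tmp_path / "pot.tsv"
        p.write_text("\tA\tC\nA\t-1.0\t0.2\nC\t0.2\t0.5\n")
        pot = read_potential_tsv(p)
        assert pot.energies.loc["A", "C"] == pytest.approx(0.2)
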