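"""PWM algebra, information content, and palindromic motif discovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bifidoreg import motif_core as mc
from bifidoreg import synthetic_data as sd
from bifidoreg.genome_io import reverse_complement

from conftest import hamming_to_palindrome


def random_counts(draw_ints, L=6):
    return np.array(draw_ints, dtype=float).reshape(L, 4)


class TestSymmetrize:
    def test_single_site_AA_hand_example(self):
        # one site "AA": raw counts column A=1; symmetrized: A=0.5, T=0.5
        raw = np.array([[1, 0, 0, 0], [1, 0, 0, 0]], dtype=float)
        sym = mc.symmetrize_counts(raw)
        expected = np.array([[0.5, 0, 0, 0.5], [0.5, 0, 0, 0.5]])
        np.testing.assert_allclose(sym, expected)

    def test_palindromic_fixed_point(self):
        pal = np.array([[2, 1, 1, 0], [0, 1, 1, 2]], dtype=float)
        np.testing.assert_allclose(mc.symmetrize_counts(pal), pal)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            mc.symmetrize_counts(np.ones((3, 4)))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 20), min_size=24, max_size=24))
    def test_idempotent_and_sum_preserving(self, ints):
        raw = random_counts(ints)
        once = mc.symmetrize_counts(raw)
        np.testing.assert_allclose(mc.symmetrize_counts(once), once)
        np.testing.assert_allclose(once.sum(axis=1).sum(), raw.sum())
        assert mc.is_palindromic(once)


class TestWeights:
    def test_conserved_column_hand_value(self):
        # column (4,0,0,0): w(A) = 0.75 ln 9, others -0.25 ln 9
        counts = np.array([[4, 0, 0, 0], [0, 0, 0, 4]], dtype=float)
        w = mc.build_weights(counts)
        assert w[0, 0] == pytest.approx(0.75 * math.log(9), abs=1e-12)
        assert w[0, 1] == pytest.approx(-0.25 * math.log(9), abs=1e-12)

    def test_uniform_column_all_zero(self):
        w = mc.build_weights(np.ones((2, 4)))
        np.testing.assert_allclose(w, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 30), min_size=24, max_size=24))
    def test_columns_sum_to_zero(self, ints):
        w = mc.build_weights(random_counts(ints))
        np.testing.assert_allclose(w.sum(axis=1), 0.0, atol=1e-12)


class TestInformationContent:
    def test_uniform_is_zero(self):
        assert mc.information_content(np.ones((4, 4))) == pytest.approx(0.0)

    def test_bounded_by_two_bits_per_column(self):
        counts = np.zeros((4, 4))
        counts[:, 0] = 1000.0
        ic = mc.information_content(counts)
        assert 0.0 < ic < 8.0
        assert ic == pytest.approx(8.0, abs=0.1)  # near the n->inf limit

    def test_conserved_n4_frozen_value(self):
        # one column (4,0,0,0), pseudocount 0.5: f = (4.5/6, 0.5/6 x3)
        # IC = 0.75*log2(3) + 3*(1/12)*log2(1/3)  (computed independently)
        f1, f0 = 4.5 / 6, 0.5 / 6
        expected = f1 * math.log2(f1 / 0.25) + 3 * f0 * math.log2(f0 / 0.25)
        counts = np.array([[4, 0, 0, 0]], dtype=float)
        assert mc.information_content(counts) == pytest.approx(expected,
                                                               abs=1e-12)
        assert expected == pytest.approx(0.7925, abs=1e-3)


class TestCalibrateThresholds:
    def _model_with_scores(self, sites):
        aln = mc.SiteAlignment([mc.Site("g", f"s{i}", s)
                                for i, s in enumerate(sites)], len(sites[0]))
        return mc.from_sites("t", aln)

    def test_default_policy_min_and_ratio(self):
        model = self._model_with_scores(
            ["ACGCGT", "ACGCGT", "AAGCTT", "ACGCGT", "TCGCGA", "ACGCGT"])
        strong, weak = mc.calibrate_thresholds(model)
        scores = [model.score(s.sequence)
                  for s in model.training_sites.sites]
        assert strong == pytest.approx(min(scores))
        assert weak == pytest.approx(0.95 * strong)
        assert strong >= weak

    def test_global_regulon_preset_is_laxer(self):
        model = self._model_with_scores(["ACGCGT", "AAGCTT", "TCGCGA",
                                         "ACGCGT"])
        s1, w1 = mc.calibrate_thresholds(model)
        s2, w2 = mc.calibrate_thresholds(model,
                                         **mc.GLOBAL_REGULON_PRESET)
        assert s2 == pytest.approx(0.95 * s1)
        assert w2 == pytest.approx((4.5 / 4.75) * s2)
        assert s2 < s1 and w2 < w1

    def test_single_site_degenerates_with_warning(self, caplog):
        aln = mc.SiteAlignment([mc.Site("g", "s", "ACGCGT")], 6)
        model = mc.from_sites("t", aln)
        with caplog.at_level("WARNING"):
            strong, weak = mc.calibrate_thresholds(model)
        assert strong == weak == pytest.approx(model.score("ACGCGT"))
        assert any("single training site" in r.message
                   for r in caplog.records)


class TestDiscovery:
    def _regions_with_implants(self, n, consensus, seed, p=0.0):
        rng = np.random.default_rng(seed)
        regions = []
        truth = []
        for _ in range(n):
            bg = sd.random_background(400, 0.6, rng)
            pos = int(rng.integers(0, 400 - len(consensus)))
            region, site = sd.implant_site(bg, consensus, p, pos, rng)
            regions.append(region)
            truth.append(pos)
        return regions, truth

    def test_recovers_perfect_implants_and_positions(self):
        consensus = "TTAACGGCGCCGTTAA"
        regions, truth = self._regions_with_implants(10, consensus, 7)
        model = mc.discover_palindromic_motif(regions, 16, seed=3)
        assert hamming_to_palindrome(model.consensus, consensus) == 0
        found = sorted(s.offset for s in model.training_sites.sites)
        assert found == sorted(truth)

    def test_minus_strand_implants_equivalent(self):
        # implanting the reverse complement is a no-op for a palindrome
        consensus = "TTAACGGCGCCGTTAA"
        assert reverse_complement(consensus) == consensus
        regions, _ = self._regions_with_implants(8, consensus, 11)
        flipped = [reverse_complement(r) for r in regions]
        m1 = mc.discover_palindromic_motif(regions, 16, seed=5)
        m2 = mc.discover_palindromic_motif(flipped, 16, seed=5)
        assert hamming_to_palindrome(m1.consensus, m2.consensus) == 0

    def test_background_only_not_significant(self):
        rng = np.random.default_rng(13)
        regions = [sd.random_background(400, 0.6, rng) for _ in range(10)]
        model = mc.discover_palindromic_motif(regions, 16, seed=1)
        assert not mc.is_significant(model, regions, n_shuffles=15, seed=2)

    def test_implanted_motif_is_significant(self):
        consensus = "TTAACGGCGCCGTTAA"
        regions, _ = self._regions_with_implants(10, consensus, 7)
        model = mc.discover_palindromic_motif(regions, 16, seed=3)
        assert mc.is_significant(model, regions, n_shuffles=15, seed=2)

    def test_deterministic_given_seed(self):
        consensus = "TTAACGGCGCCGTTAA"
        regions, _ = self._regions_with_implants(8, consensus, 19, p=0.1)
        m1 = mc.discover_palindromic_motif(regions, 16, seed=9)
        m2 = mc.discover_palindromic_motif(regions, 16, seed=9)
        np.testing.assert_array_equal(m1.counts, m2.counts)

    def test_too_few_regions_rejected(self):
        with pytest.raises(mc.InsufficientDataError):
            mc.discover_palindromic_motif(["ACGT" * 100] * 3, 16, seed=0)


class TestModelInvariants:
    def test_score_equals_revcomp_score_exhaustive_L6(self):
        rng = np.random.default_rng(2)
        counts = mc.symmetrize_counts(rng.integers(0, 12, size=(6, 4)))
        model = mc.MotifModel("p", counts)
        bases = "ACGT"
        for i in range(4 ** 6):
            s = "".join(bases[(i // 4 ** j) % 4] for j in range(6))
            assert model.score(s) == pytest.approx(
                model.score(reverse_complement(s)), abs=1e-9)

    def test_consensus_scores_maximal(self):
        rng = np.random.default_rng(3)
        counts = mc.symmetrize_counts(rng.integers(0, 12, size=(8, 4)))
        model = mc.MotifModel("p", counts)
        assert model.score(model.consensus) == pytest.approx(model.max_score)

    def test_ambiguous_base_scores_nan(self):
        model = mc.MotifModel("p", np.ones((4, 4)))
        assert math.isnan(model.score("ACNT"))


class TestLengthScan:
    def test_best_length_prefers_true_motif_length(self):
        rng = np.random.default_rng(31)
        consensus = "TTAACGGCGCCGTTAA"
        regions = []
        for _ in range(8):
            bg = sd.random_background(300, 0.6, rng)
            pos = int(rng.integers(0, 300 - 16))
            region, _ = sd.implant_site(bg, consensus, 0.0, pos, rng)
            regions.append(region)
        model = mc.discover_best_length(regions, lengths=(14, 16),
                                        n_restarts=10, seed=5)
        # the 16-mer window carries more information per column than any
        # 14-mer sub-window of the same implant
        assert model.length == 16
        assert hamming_to_palindrome(model.consensus, consensus) == 0
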