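"""Dampened frequency matrix, discriminative scoring, and signature rules."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

import phosphosig as ps
from phosphosig.ngrams import ENRICHED


def table(species, counts, dataset=ENRICHED, n_min=6, n_max=21):
    return ps.NGramCountTable(species=species, dataset_id=dataset,
                              counts=Counter(counts), n_min=n_min, n_max=n_max)


def fm_from_normfreq(normfreq, species=None, ngrams=None):
    """A FrequencyMatrix wrapper around a hand-chosen normfreq matrix."""
    normfreq = np.asarray(normfreq, dtype=float)
    g, s = normfreq.shape
    species = species or [f"sp{i}" for i in range(s)]
    ngrams = ngrams or [f"g{i}" for i in range(g)]
    return ps.FrequencyMatrix(
        ngrams=ngrams, species=species,
        raw=(normfreq > 0).astype(np.int64), relfreq=normfreq,
        weights=np.ones(g), normfreq=normfreq,
        n_species_present=(normfreq > 0).sum(axis=1), n_min=6, n_max=21)


class TestEnrichedCounts:
    def test_counts_sum_over_datasets(self):
        t1 = table("A", {"GGGGGG": 2}, dataset="d1")
        t2 = table("A", {"GGGGGG": 3, "HHHHHH": 3}, dataset="d2")
        merged = ps.enriched_counts([t1, t2])
        assert merged.counts == Counter({"GGGGGG": 5, "HHHHHH": 3})
        assert merged.dataset_id == ENRICHED

    def test_single_table_is_identity(self):
        t = table("A", {"GGGGGG": 2})
        assert ps.enriched_counts([t]).counts == t.counts

    def test_species_mismatch_rejected(self):
        with pytest.raises(ps.UsageError):
            ps.enriched_counts([table("A", {"GGGGGG": 1}),
                                table("B", {"GGGGGG": 1})])


class TestDampeningWeight:
    def test_ubiquitous_ngram_gets_unit_weight(self):
        assert ps.dampening_weight(5, 5) == 1.0

    def test_species_exclusive_weight(self):
        assert ps.dampening_weight(1, 5) == pytest.approx(math.log2(5) + 1)

    def test_strictly_decreasing_in_s(self):
        weights = [ps.dampening_weight(s, 5) for s in range(1, 6)]
        assert weights == sorted(weights, reverse=True)
        assert len(set(weights)) == 5
        assert weights[1] == pytest.approx(math.log2(5 / 2) + 1)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ps.dampening_weight(0, 5)
        with pytest.raises(ValueError):
            ps.dampening_weight(6, 5)


class TestFrequencyMatrix:
    def test_two_exclusive_ngrams_give_scaled_identity(self):
        fm = ps.build_frequency_matrix({
            "A": table("A", {"GGGGGG": 5}),
            "B": table("B", {"HHHHHH": 7}),
        })
        assert fm.ngrams == ["GGGGGG", "HHHHHH"]  # lexicographic vocabulary
        np.testing.assert_allclose(fm.relfreq, np.eye(2))
        assert list(fm.n_species_present) == [1, 1]
        np.testing.assert_allclose(fm.weights, [2.0, 2.0])  # log2(2)+1
        np.testing.assert_allclose(fm.normfreq.sum(axis=0), [2.0, 2.0])

    def test_identical_tables_give_unit_weights_and_equal_columns(self):
        counts = {"GGGGGG": 3, "HHHHHH": 1}
        fm = ps.build_frequency_matrix(
            {sp: table(sp, counts) for sp in "ABC"})
        assert (fm.n_species_present == 3).all()
        np.testing.assert_allclose(fm.weights, 1.0)
        for j in range(1, 3):
            np.testing.assert_allclose(fm.normfreq[:, j], fm.normfreq[:, 0])

    def test_doubling_counts_leaves_column_unchanged(self):
        tables = {"A": table("A", {"GGGGGG": 2, "HHHHHH": 5}),
                  "B": table("B", {"GGGGGG": 1})}
        doubled = {"A": table("A", {"GGGGGG": 4, "HHHHHH": 10}),
                   "B": table("B", {"GGGGGG": 1})}
        fm1 = ps.build_frequency_matrix(tables)
        fm2 = ps.build_frequency_matrix(doubled)
        np.testing.assert_allclose(fm1.relfreq, fm2.relfreq)
        np.testing.assert_allclose(fm1.normfreq, fm2.normfreq)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_relfreq_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        vocab = [f"NGRAM{i:02d}" for i in range(rng.integers(2, 12))]
        tables = {}
        for sp in ("A", "B", "C"):
            counts = {g: int(rng.integers(0, 9)) for g in vocab}
            counts = {g: c for g, c in counts.items() if c}
            counts[vocab[0]] = max(counts.get(vocab[0], 0), 1)  # nonzero total
            tables[sp] = table(sp, counts)
        fm = ps.build_frequency_matrix(tables)
        np.testing.assert_allclose(fm.relfreq.sum(axis=0), 1.0, atol=1e-9)
        assert (fm.normfreq >= 0).all()
        # weights are a function of s(g) through the decided formula
        for i in range(len(fm.ngrams)):
            assert fm.weights[i] == pytest.approx(
                ps.dampening_weight(int(fm.n_species_present[i]), 3))

    def test_zero_total_species_rejected(self):
        with pytest.raises(ps.UsageError):
            ps.build_frequency_matrix({"A": table("A", {"GGGGGG": 1}),
                                       "B": table("B", {})})


class TestDiscriminativeScores:
    def test_hand_computed_five_species_rows(self):
        fm = fm_from_normfreq([[0.6, 0.2, 0.2, 0.0, 0.0],
                               [0.2, 0.2, 0.2, 0.2, 0.2],
                               [0.5, 0.0, 0.0, 0.0, 0.0]])
        ratio = ps.discriminative_scores(fm, mode="ratio")
        diff = ps.discriminative_scores(fm, mode="difference")
        assert ratio[0].score == pytest.approx(3.0)
        assert diff[0].score == pytest.approx(0.4)
        assert ratio[0].top_species == "sp0" and not ratio[0].tied
        assert ratio[1].score == pytest.approx(1.0)
        assert diff[1].score == pytest.approx(0.0)
        assert ratio[1].tied
        assert math.isinf(ratio[2].score)
        assert diff[2].score == pytest.approx(0.5)

    def test_invariant_under_permutation_of_non_top_species(self, rng):
        for _ in range(25):
            row = np.sort(rng.random(5))[::-1]
            base = ps.discriminative_scores(fm_from_normfreq([row]),
                                            mode="difference")[0]
            perm = np.concatenate([[row[0]], rng.permutation(row[1:])])
            shuffled = ps.discriminative_scores(fm_from_normfreq([perm]),
                                                mode="difference")[0]
            assert shuffled.score == pytest.approx(base.score)
            assert (shuffled.f1, shuffled.f2, shuffled.f3) == pytest.approx(
                (base.f1, base.f2, base.f3))

    def test_ties_break_by_species_order(self):
        fm = fm_from_normfreq([[0.3, 0.3, 0.2, 0.1, 0.1]])
        s = ps.discriminative_scores(fm, mode="difference")[0]
        assert s.top_species == "sp0" and s.tied

    def test_requires_three_species(self):
        with pytest.raises(ps.UsageError):
            ps.discriminative_scores(fm_from_normfreq([[0.5, 0.5]]))


class TestSelectDiscriminative:
    def test_strict_threshold(self):
        fm = fm_from_normfreq([[0.45, 0.05, 0.05, 0.0, 0.0],
                               [0.24, 0.2, 0.2, 0.18, 0.18]],
                              ngrams=["g", "h"])
        scores = ps.discriminative_scores(fm, mode="difference")
        assert scores["g"].score == pytest.approx(0.4)
        assert scores["h"].score == pytest.approx(0.04)
        kept = ps.select_discriminative(scores, 0.05)
        assert kept["sp0"] == {"g"}

    def test_exact_threshold_not_kept(self):
        fm = fm_from_normfreq([[0.15, 0.1, 0.1, 0.0, 0.0]])
        scores = ps.discriminative_scores(fm, mode="difference")
        assert scores[0].score == pytest.approx(0.05)
        assert ps.select_discriminative(scores, 0.05)["sp0"] == set()

    def test_infinite_ratio_always_kept(self):
        fm = fm_from_normfreq([[0.5, 0.0, 0.0, 0.0, 0.0]])
        scores = ps.discriminative_scores(fm, mode="ratio")
        assert ps.select_discriminative(scores, 1e9)["sp0"] == {"g0"}


def toy_design():
    return ps.StudyDesign(
        train_species=("A", "B", "C"), test_species=("a", "b", "c"),
        pairing={"a": "A", "b": "B", "c": "C"},
        kingdom_of={"A": "K1", "B": "K2", "C": "K3",
                    "a": "K1", "b": "K2", "c": "K3"},
        datasets_of={sp: ("d1",) for sp in "ABCabc"})


class TestBuildSignature:
    def setup_method(self):
        self.design = toy_design()
        self.tables = {
            "A": table("A", {"GGGGGG": 9, "HHHHHH": 1}),
            "B": table("B", {"IIIIII": 9, "HHHHHH": 1}),
            "C": table("C", {"KKKKKK": 9, "HHHHHH": 1}),
        }
        self.fm = ps.build_frequency_matrix(self.tables)
        self.scores = ps.discriminative_scores(self.fm, mode="difference")
        self.discr = ps.select_discriminative(self.scores, 0.05)

    def test_present_in_paired_test_included(self):
        test_tables = {"a": table("a", {"GGGGGG": 1}),
                       "b": table("b", {"IIIIII": 2}),
                       "c": table("c", {"KKKKKK": 3})}
        sig = ps.build_signature(self.discr, test_tables, self.design,
                                 self.fm, self.scores, 0.05)
        by_kingdom = {e.ngram: e.kingdom for e in sig.entries}
        assert by_kingdom["GGGGGG"] == "K1"
        assert by_kingdom["IIIIII"] == "K2"
        assert by_kingdom["KKKKKK"] == "K3"

    def test_absent_from_paired_test_excluded(self):
        test_tables = {"a": table("a", {"WWWWWW": 1}),
                       "b": table("b", {"IIIIII": 2}),
                       "c": table("c", {"KKKKKK": 3})}
        sig = ps.build_signature(self.discr, test_tables, self.design,
                                 self.fm, self.scores, 0.05)
        assert "GGGGGG" not in sig

    def test_non_discriminative_presence_not_enough(self):
        # HHHHHH is ubiquitous (difference score 0) and present in every
        # test species, but never discriminative for anyone
        test_tables = {"a": table("a", {"GGGGGG": 1, "HHHHHH": 5}),
                       "b": table("b", {"IIIIII": 2, "HHHHHH": 5}),
                       "c": table("c", {"KKKKKK": 3, "HHHHHH": 5})}
        sig = ps.build_signature(self.discr, test_tables, self.design,
                                 self.fm, self.scores, 0.05)
        assert "HHHHHH" not in sig

    def test_entries_carry_frozen_training_weights(self):
        test_tables = {"a": table("a", {"GGGGGG": 1}),
                       "b": table("b", {"IIIIII": 2}),
                       "c": table("c", {"KKKKKK": 3})}
        sig = ps.build_signature(self.discr, test_tables, self.design,
                                 self.fm, self.scores, 0.05)
        for e in sig.entries:
            assert e.weight == pytest.approx(
                self.fm.weights[self.fm.row(e.ngram)])


class TestProjectFrequencies:
    def make_signature(self):
        entries = [
            ps.SignatureEntry("GGGGGG", "A", "K1", math.inf, 2.0),
            ps.SignatureEntry("HHHHHH", "B", "K2", math.inf, 2.0),
            ps.SignatureEntry("IIIIII", "C", "K3", math.inf, 1.5),
        ]
        return ps.Signature(entries=entries, parameters=ps.SignatureParams(
            6, 21, 0.05, "ratio"))

    def test_projection_recomputes_relfreq_over_signature_vocab(self):
        sig = self.make_signature()
        proj = ps.project_frequencies(sig, {
            "X": table("X", {"GGGGGG": 3, "IIIIII": 1, "ZZZZZZ": 100})})
        # ZZZZZZ is outside the signature: denominators use only 3 + 1
        np.testing.assert_allclose(proj.relfreq[:, 0], [0.75, 0.0, 0.25])
        np.testing.assert_allclose(proj.normfreq[:, 0],
                                   [0.75 * 2.0, 0.0, 0.25 * 1.5])

    def test_weights_are_frozen_not_recomputed(self):
        sig = self.make_signature()
        proj = ps.project_frequencies(sig, {
            "X": table("X", {"GGGGGG": 1, "HHHHHH": 1, "IIIIII": 1}),
            "Y": table("Y", {"GGGGGG": 1, "HHHHHH": 1, "IIIIII": 1})})
        # all n-grams are in both species; recomputation would give weight 1
        np.testing.assert_allclose(proj.weights, [2.0, 2.0, 1.5])

    def test_scale_invariance_of_projected_column(self):
        sig = self.make_signature()
        p1 = ps.project_frequencies(sig, {"X": table("X", {"GGGGGG": 2,
                                                           "HHHHHH": 6})})
        p2 = ps.project_frequencies(sig, {"X": table("X", {"GGGGGG": 4,
                                                           "HHHHHH": 12})})
        np.testing.assert_allclose(p1.normfreq, p2.normfreq)

    def test_species_without_signature_ngrams_gets_zero_column(self, caplog):
        sig = self.make_signature()
        with caplog.at_level("WARNING"):
            proj = ps.project_frequencies(sig, {"X": table("X",
                                                           {"WWWWWW": 5})})
        np.testing.assert_allclose(proj.normfreq[:, 0], 0.0)
        assert any("no signature n-gram" in r.message for r in caplog.records)
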