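"""SVM kernel/classification and multiscale-bootstrap clustering."""

import numpy as np
import pytest

import phosphosig as ps
from phosphosig.classify import _probit_fit
from test_frequencies import fm_from_normfreq


class TestNormalizedPolynomialKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=(6, 4))
        k = ps.normalized_polynomial_kernel(x, x, degree=2)
        np.testing.assert_allclose(np.diag(k), 1.0)
        # and for the zero vector too, since K(0,0) = 1
        k0 = ps.normalized_polynomial_kernel(np.zeros((1, 4)),
                                             np.zeros((1, 4)))
        np.testing.assert_allclose(k0, 1.0)

    def test_hand_computed_value(self):
        # x=(1,0), y=(1,1), d=2: K=(x.y+1)^2=4, K(x,x)=4, K(y,y)=9 -> 4/6
        k = ps.normalized_polynomial_kernel([[1.0, 0.0]], [[1.0, 1.0]],
                                            degree=2)
        assert k[0, 0] == pytest.approx(4.0 / 6.0)

    def test_symmetry_and_bounds(self, rng):
        x = np.abs(rng.normal(size=(5, 7)))  # frequencies are non-negative
        k = ps.normalized_polynomial_kernel(x, x)
        np.testing.assert_allclose(k, k.T)
        assert (k <= 1.0 + 1e-12).all() and (k >= 0.0).all()


class TestTrainAndClassify:
    def make_fms(self):
        train = fm_from_normfreq(np.eye(3), species=["A", "B", "C"])
        test = fm_from_normfreq(np.eye(3)[:, [1, 0, 2]],
                                species=["b", "a", "c"])
        return train, test

    def test_exact_match_assigned_to_its_class(self):
        train, test = self.make_fms()
        labels = {sp: sp for sp in "ABC"}
        res = ps.train_and_classify(train, labels, test,
                                    pairing={"a": "A", "b": "B", "c": "C"})
        assert res.assigned == {"a": "A", "b": "B", "c": "C"}
        assert res.accuracy == 1.0
        assert (res.confusion.sum(axis=1) == 1).all()

    def test_training_vectors_classified_perfectly(self):
        # linear separability in kernel space: the training species
        # themselves must come back with a diagonal confusion
        train, _ = self.make_fms()
        labels = {sp: sp for sp in "ABC"}
        res = ps.train_and_classify(train, labels, train,
                                    pairing={sp: sp for sp in "ABC"})
        assert res.accuracy == 1.0

    def test_misaligned_vocabularies_rejected(self):
        train, test = self.make_fms()
        test.ngrams = list(reversed(test.ngrams))
        with pytest.raises(ps.UsageError):
            ps.train_and_classify(train, {sp: sp for sp in "ABC"}, test)

    def test_zero_test_column_warns_but_classifies(self, caplog):
        train, test = self.make_fms()
        test.normfreq[:, 0] = 0.0
        with caplog.at_level("WARNING"):
            res = ps.train_and_classify(train, {sp: sp for sp in "ABC"}, test)
        assert any("all-zero" in r.message for r in caplog.records)
        assert set(res.assigned) == {"a", "b", "c"}


class TestHierarchicalCluster:
    def test_identical_columns_merge_at_height_zero(self, rng):
        x = rng.random((30, 3))
        x[:, 1] = x[:, 0]
        fm = fm_from_normfreq(x, species=["A", "B", "C"])
        dendro = ps.hierarchical_cluster(fm, distance="euclidean")
        assert dendro.clades()[0] == frozenset({"A", "B"})
        assert dendro.merge[0, 2] == pytest.approx(0.0)

    def test_well_separated_pairs_merge_first(self, rng):
        base1, base2 = rng.random(40), rng.random(40)
        x = np.column_stack([base1, base1 + rng.normal(0, 1e-3, 40),
                             base2, base2 + rng.normal(0, 1e-3, 40)])
        fm = fm_from_normfreq(np.abs(x), species=list("ABCD"))
        clades = ps.hierarchical_cluster(fm).clades()
        assert {clades[0], clades[1]} == {frozenset("AB"), frozenset("CD")}

    def test_distance_matrix_symmetric_zero_diagonal(self, rng):
        from scipy.spatial.distance import squareform
        from phosphosig.classify import _column_distance
        x = rng.random((25, 4))
        d = squareform(_column_distance(x, "correlation", list("ABCD")))
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_constant_column_rejected_under_correlation(self, rng):
        x = rng.random((10, 3))
        x[:, 2] = 0.7
        fm = fm_from_normfreq(x, species=["A", "B", "C"])
        with pytest.raises(ps.UsageError, match="C"):
            ps.hierarchical_cluster(fm, distance="correlation")


class TestProbitFit:
    scales = np.round(np.arange(0.5, 1.41, 0.1), 1)

    def test_constant_half_bp_is_a_fixed_point(self):
        au, v, c = _probit_fit(np.full(10, 0.5), self.scales, 1000)
        assert v == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert au == pytest.approx(0.5)

    def test_always_present_edge_has_au_one(self):
        au, _, _ = _probit_fit(np.ones(10), self.scales, 1000)
        assert au == 1.0

    def test_never_present_edge_has_au_zero(self):
        au, _, _ = _probit_fit(np.zeros(10), self.scales, 1000)
        assert au == 0.0

    def test_au_in_unit_interval_for_random_profiles(self, rng):
        for _ in range(50):
            bp = rng.random(10)
            au, _, _ = _probit_fit(bp, self.scales, 1000)
            assert 0.0 <= au <= 1.0

    def test_true_cluster_profile_gives_au_above_bp(self):
        # BP rising with the resampling scale is the signature of a true
        # cluster; AU should exceed the plain BP at r=1
        bp = np.linspace(0.90, 0.99, 10)
        au, _, _ = _probit_fit(bp, self.scales, 1000)
        assert au > 0.95


class TestMultiscaleBootstrap:
    def paired_fm(self, rng, rows=60):
        base1, base2 = rng.random(rows), rng.random(rows)
        x = np.column_stack([base1, base1 + rng.normal(0, 1e-2, rows),
                             base2, base2 + rng.normal(0, 1e-2, rows)])
        return fm_from_normfreq(np.abs(x), species=list("ABCD"))

    def test_true_pairs_get_high_bp(self, rng):
        fm = self.paired_fm(rng)
        boot = ps.multiscale_bootstrap(fm, n_boot=200, seed=1)
        assert boot.edge({"A", "B"}).bp >= 0.95
        assert boot.edge({"C", "D"}).bp >= 0.95
        for e in boot.edges:
            assert 0.0 <= e.bp <= 1.0 and 0.0 <= e.au <= 1.0

    def test_reproducible_under_fixed_seed(self, rng):
        fm = self.paired_fm(rng)
        b1 = ps.multiscale_bootstrap(fm, n_boot=100, seed=42)
        b2 = ps.multiscale_bootstrap(fm, n_boot=100, seed=42)
        assert [(e.members, e.bp, e.au) for e in b1.edges] == \
               [(e.members, e.bp, e.au) for e in b2.edges]

    def test_bp_estimates_agree_across_seeds(self, rng):
        fm = self.paired_fm(rng)
        bps = [ps.multiscale_bootstrap(fm, n_boot=400, seed=s)
               .edge({"A", "B"}).bp for s in (1, 2)]
        assert abs(bps[0] - bps[1]) < 0.1

    def test_rejects_tiny_bootstrap(self, rng):
        fm = self.paired_fm(rng)
        with pytest.raises(ps.UsageError):
            ps.multiscale_bootstrap(fm, n_boot=10)
        with pytest.raises(ps.UsageError):
            ps.multiscale_bootstrap(fm, scales=[-0.5, 1.0], n_boot=100)

    def test_newick_carries_support_comments(self, rng):
        fm = self.paired_fm(rng)
        boot = ps.multiscale_bootstrap(fm, n_boot=100, seed=5)
        nwk = boot.to_newick()
        assert nwk.endswith(";") and "AU=" in nwk and "BP=" in nwk
        for sp in "ABCD":
            assert sp in nwk
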