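"""Alpha diversity, rarefaction, Bray-Curtis, PCoA and permutation tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import gutgroups as gg
from gutgroups.ecology import DistanceMatrix, alpha_diversity, rarefaction_curve


def _profile(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=samples, columns=[f"t{j}" for j in range(values.shape[1])])
    return gg.FeatureProfile(frame, level="genus", normalization="raw")


def _dm(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(pd.DataFrame(values, index=samples, columns=samples))


class TestAlphaDiversity:
    def test_uniform_composition_closed_forms(self):
        row = alpha_diversity([10, 10, 10, 10])
        assert row["shannon"] == pytest.approx(math.log(4), abs=1e-12)
        assert row["simpson"] == pytest.approx(0.75, abs=1e-12)

    def test_single_taxon_has_zero_diversity(self):
        row = alpha_diversity([42])
        assert row["shannon"] == 0.0
        assert row["simpson"] == 0.0

    def test_chao1_hand_example(self):
        # counts (5,3,1,1): S_obs=4, F1=2, F2=0 -> 4 + 2*1/2 = 5
        assert alpha_diversity([5, 3, 1, 1])["chao1"] == pytest.approx(5.0)

    def test_chao1_equals_observed_when_no_singletons(self):
        assert alpha_diversity([5, 3, 2, 2])["chao1"] == pytest.approx(4.0)

    def test_all_zero_is_an_error(self):
        with pytest.raises(gg.GutgroupsError):
            alpha_diversity([0, 0, 0])

    def test_matches_skbio_estimators(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(0, 30, size=12)
            if counts.sum() == 0 or (counts > 0).sum() < 2:
                continue
            row = alpha_diversity(counts)
            assert row["shannon"] == pytest.approx(
                float(skbio_alpha.shannon(counts, base=math.e)), abs=1e-9
            )
            assert row["simpson"] == pytest.approx(float(skbio_alpha.simpson(counts)), abs=1e-9)
            assert row["chao1"] == pytest.approx(
                float(skbio_alpha.chao1(counts, bias_corrected=True)), abs=1e-9
            )
            rare = counts[(counts > 0) & (counts <= 10)]
            if rare.size and (rare == 1).sum() < rare.sum():
                assert row["ace"] == pytest.approx(float(skbio_alpha.ace(counts)), abs=1e-9)


class TestRarefaction:
    def test_full_depth_recovers_observed_richness(self):
        counts = [4, 3, 2]
        assert rarefaction_curve(counts, [9]).iloc[0] == pytest.approx(3.0)

    def test_depth_one_gives_one(self):
        assert rarefaction_curve([4, 3, 2], [1]).iloc[0] == pytest.approx(1.0)

    def test_two_by_two_matches_exhaustive_enumeration(self):
        # counts (2,2), depth 2: enumerate all C(4,2)=6 subsamples
        assert rarefaction_curve([2, 2], [2]).iloc[0] == pytest.approx(5.0 / 3.0, abs=1e-12)

    def test_matches_enumeration_on_random_small_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            counts = rng.integers(1, 5, size=3)
            total = counts.sum()
            d = int(rng.integers(1, total + 1))
            items = np.repeat(np.arange(3), counts)
            oracle = np.mean(
                [len(set(c)) for c in itertools.combinations(items, d)]
            )
            assert rarefaction_curve(counts, [d]).iloc[0] == pytest.approx(oracle, abs=1e-9)

    def test_monotone_in_depth_and_bounds(self):
        curve = rarefaction_curve([10, 5, 3, 1], range(1, 20))
        assert (np.diff(curve.to_numpy()) >= -1e-12).all()
        assert curve.iloc[-1] <= 4.0

    def test_depth_beyond_total_is_an_error(self):
        with pytest.raises(gg.GutgroupsError):
            rarefaction_curve([2, 2], [5])


class TestBrayCurtis:
    def test_identical_rows_have_zero_distance(self):
        dm = gg.bray_curtis(_profile([[1, 2, 3], [1, 2, 3]]))
        assert dm.values()[0, 1] == 0.0

    def test_disjoint_supports_have_distance_one(self):
        dm = gg.bray_curtis(_profile([[1, 0], [0, 1]]))
        assert dm.values()[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        dm = gg.bray_curtis(_profile([[1, 1], [1, 0]]))
        assert dm.values()[0, 1] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_matches_direct_formula_on_random_profiles(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 5, size=(6, 8))
        dm = gg.bray_curtis(_profile(X))
        for i, j in itertools.combinations(range(6), 2):
            oracle = np.abs(X[i] - X[j]).sum() / (X[i] + X[j]).sum()
            assert dm.values()[i, j] == pytest.approx(oracle, abs=1e-12)


class TestPcoa:
    def test_euclidean_distances_are_reproduced_isometrically(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = gg.pcoa(_dm(D))
        C = res.coordinates.to_numpy()
        D2 = np.linalg.norm(C[:, None] - C[None, :], axis=2)
        np.testing.assert_allclose(D2, D, atol=1e-9)

    def test_three_equidistant_points_have_two_equal_eigenvalues(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = gg.pcoa(_dm(D))
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert pos.size == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_duplicated_sample_coordinates_coincide(self):
        X = np.array([[1, 2, 3], [1, 2, 3], [4, 1, 0], [0, 5, 2]], dtype=float)
        dm = gg.bray_curtis(_profile(X))
        res = gg.pcoa(dm)
        np.testing.assert_allclose(
            res.coordinates.iloc[0].to_numpy(), res.coordinates.iloc[1].to_numpy(), atol=1e-9
        )

    def test_matches_skbio_eigenvalues(self):
        skbio_stats = pytest.importorskip("skbio.stats.ordination")
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 3, size=(7, 5))
        dm = gg.bray_curtis(_profile(X))
        ours = gg.pcoa(dm)
        theirs = skbio_stats.pcoa(
            skbio_distance.DistanceMatrix(dm.values(), ids=list(dm.sample_ids)),
            method="eigh",
        )
        k = (ours.eigenvalues > 1e-10).sum()
        np.testing.assert_allclose(
            ours.eigenvalues[:k], theirs.eigvals.to_numpy()[:k], atol=1e-9
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(gg.GutgroupsError):
            gg.pcoa(_dm([[0.0, 1.0], [1.0, 0.0]]))


def _two_cluster_distance(n_per=6, gap=10.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.concatenate([rng.normal(0, 1, (n_per, 2)), rng.normal(gap, 1, (n_per, 2))])
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    labels = np.array(["a"] * n_per + ["b"] * n_per)
    return _dm(D), labels


class TestPermanova:
    def test_separated_clusters_reach_minimum_p(self):
        dm, labels = _two_cluster_distance()
        res = gg.permanova(dm, labels, permutations=999, seed=1)
        # the only permutations reaching the observed F are those that
        # recreate the same bipartition (prob 2/C(12,6) each), so p sits at
        # or within a few lattice steps of the 1/(B+1) minimum
        assert res.p_value <= 5.0 / 1000.0
        assert res.statistic > 10

    def test_statistic_invariant_under_sample_reordering(self):
        dm, labels = _two_cluster_distance(seed=3)
        perm = np.random.default_rng(0).permutation(len(labels))
        dm2 = _dm(dm.values()[np.ix_(perm, perm)])
        r1 = gg.permanova(dm, labels, permutations=99, seed=0)
        r2 = gg.permanova(dm2, labels[perm], permutations=99, seed=0)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_matches_skbio_pseudo_f(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        dm, labels = _two_cluster_distance(gap=2.0, seed=7)
        ours = gg.permanova(dm, labels, permutations=99, seed=0)
        theirs = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(dm.values(), ids=list(dm.sample_ids)),
            grouping=list(labels),
            permutations=0,
        )
        assert ours.statistic == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_single_group_rejected(self):
        dm, _ = _two_cluster_distance()
        with pytest.raises(gg.GutgroupsError):
            gg.permanova(dm, ["a"] * 12)


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        dm, labels = _two_cluster_distance(gap=50.0)
        res = gg.anosim(dm, labels, permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_four_sample_toy_matches_hand_rank_formula(self):
        # within distances 1, 2; between distances 3, 4, 5, 6
        D = np.array(
            [
                [0, 1, 3, 4],
                [1, 0, 5, 6],
                [3, 5, 0, 2],
                [4, 6, 2, 0],
            ],
            dtype=float,
        )
        res = gg.anosim(_dm(D), ["a", "a", "b", "b"], permutations=99, seed=0)
        # ranks: within {1,2}, between {3,4,5,6}; R = (4.5 - 1.5)/(6/2) = 1
        assert res.statistic == pytest.approx(1.0)

    def test_matches_skbio_r(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        dm, labels = _two_cluster_distance(gap=1.5, seed=13)
        ours = gg.anosim(dm, labels, permutations=99, seed=0)
        theirs = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(dm.values(), ids=list(dm.sample_ids)),
            grouping=list(labels),
            permutations=0,
        )
        assert ours.statistic == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_null_statistic_centred_near_zero(self):
        rng = np.random.default_rng(21)
        stats = []
        for _ in range(50):
            X = rng.uniform(0, 1, size=(10, 4))
            dm = gg.bray_curtis(_profile(X))
            labels = np.array(["a"] * 5 + ["b"] * 5)
            stats.append(gg.anosim(dm, labels, permutations=99, seed=0).statistic)
        assert abs(np.mean(stats)) < 0.1


class TestMultiGroupComparison:
    def test_obvious_difference_detected(self):
        values = np.r_[np.zeros(6), np.ones(6) * 5, np.ones(6) * 10]
        groups = np.repeat(["a", "b", "c"], 6)
        table = gg.multi_group_comparison(values + np.random.default_rng(0).normal(0, 0.1, 18), groups)
        assert (table["tukey_p"] < 0.01).all()
        assert table["anova_p"].iloc[0] < 1e-6
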