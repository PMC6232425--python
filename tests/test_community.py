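import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom

from ecoimpact import community
from ecoimpact.synthetic import random_tree

from oracles import (
    faith_pd_naive,
    unweighted_unifrac_naive,
    weighted_unifrac_naive,
)


class TestRarefaction:
    def test_saturated_sample_unchanged(self):
        out = community.rarefy_counts([2200], 2200, seed=0)
        assert out.tolist() == [2200]

    def test_depth_conserved_and_deterministic(self, rng):
        counts = rng.integers(0, 500, 40)
        counts[0] += 3000
        a = community.rarefy_counts(counts, 2200, seed=42)
        b = community.rarefy_counts(counts, 2200, seed=42)
        assert a.sum() == 2200
        assert np.array_equal(a, b)
        assert np.all(a <= counts)

    def test_mean_matches_hypergeometric(self):
        """{A:5000, B:5000} at depth 2200: per-draw counts of A follow
        Hypergeometric(10000, 5000, 2200), mean 1100."""
        draws = np.array(
            [community.rarefy_counts([5000, 5000], 2200, seed=s)[0]
             for s in range(400)]
        )
        mean, var = hypergeom.stats(10000, 5000, 2200, moments="mv")
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_below_depth_rejected(self):
        with pytest.raises(ValueError, match="below rarefaction depth"):
            community.rarefy_counts([10, 20], 2200, seed=0)

    def test_table_rarefaction_names_shallow_sample(self):
        table = pd.DataFrame(
            {"OTU_1": [3000, 5], "OTU_2": [0, 10]}, index=["deep", "shallow"]
        )
        with pytest.raises(ValueError, match="shallow"):
            community.rarefy_table(table, 100, seed=0)


class TestSingletons:
    def test_dataset_wide_definition(self):
        table = pd.DataFrame(
            {
                "once_total": [1, 0],   # dataset-wide singleton: dropped
                "twice_split": [1, 1],  # total 2: kept
                "common": [5, 9],
            },
            index=["s1", "s2"],
        )
        out = community.remove_singletons(table)
        assert list(out.columns) == ["twice_split", "common"]

    def test_no_singletons_identity(self):
        table = pd.DataFrame({"a": [2, 3], "b": [0, 4]}, index=["s1", "s2"])
        pd.testing.assert_frame_equal(community.remove_singletons(table), table)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts,expected", [([3, 0, 1], 2), ([1], 1), ([7, 7, 7], 3)]
    )
    def test_observed_species(self, counts, expected):
        assert community.observed_species(counts) == expected

    def test_observed_species_warns_on_empty(self):
        with pytest.warns(UserWarning):
            assert community.observed_species([0, 0]) == 0

    @pytest.mark.parametrize(
        "counts,expected",
        [([50, 50], 2.0), ([100], 1.0), ([30, 30, 30], 3.0)],
    )
    def test_simpson_reciprocal_equal_abundances(self, counts, expected):
        assert community.simpson_reciprocal(counts) == pytest.approx(expected)

    def test_simpson_zero_total_rejected(self):
        with pytest.raises(ValueError):
            community.simpson_reciprocal([0, 0])

    def test_faith_pd_hand_cases(self, small_tree):
        ids = ["A", "B", "C"]
        assert community.faith_pd([5, 0, 1], ids, small_tree) == pytest.approx(4.5)
        assert community.faith_pd([5, 0, 0], ids, small_tree) == pytest.approx(1.5)
        # full community spans every branch
        assert community.faith_pd([1, 1, 1], ids, small_tree) == pytest.approx(6.5)

    def test_faith_pd_missing_otu_named(self, small_tree):
        with pytest.raises(ValueError, match="'D'"):
            community.faith_pd([1, 1], ["A", "D"], small_tree)

    def test_observed_species_monotone_under_rarefaction(self, rng):
        counts = rng.integers(0, 50, 30)
        counts[0] += 500
        sub = community.rarefy_counts(counts, 200, seed=1)
        assert community.observed_species(sub) <= community.observed_species(counts)


class TestUniFrac:
    def test_identical_profiles_zero(self, small_tree):
        ids = ["A", "B", "C"]
        for kw in ({"weighted": True}, {"weighted": True, "normalized": True},
                   {"weighted": False}):
            assert community.unifrac([3, 1, 2], [3, 1, 2], ids, small_tree, **kw) == 0.0

    def test_two_leaf_hand_case(self, two_leaf_tree):
        ids = ["A", "B"]
        assert community.unifrac([10, 0], [0, 10], ids, two_leaf_tree) == pytest.approx(2.0)
        assert community.unifrac(
            [10, 0], [0, 10], ids, two_leaf_tree, normalized=True
        ) == pytest.approx(1.0)
        assert community.unifrac(
            [10, 0], [0, 10], ids, two_leaf_tree, weighted=False
        ) == pytest.approx(1.0)

    def test_both_empty_rejected(self, two_leaf_tree):
        with pytest.raises(ValueError, match="empty"):
            community.unifrac([0, 0], [0, 0], ["A", "B"], two_leaf_tree)

    def test_agrees_with_branch_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(40):
            n = int(rng.integers(2, 9))
            tree = random_tree(n, seed=trial)
            ids = [f"OTU_{i}" for i in range(1, n + 1)]
            a = rng.integers(0, 20, n)
            b = rng.integers(0, 20, n)
            if a.sum() == 0 or b.sum() == 0:
                continue
            da = dict(zip(ids, a))
            db = dict(zip(ids, b))
            assert community.unifrac(a, b, ids, tree) == pytest.approx(
                weighted_unifrac_naive(da, db, tree, normalized=False), abs=1e-9
            )
            assert community.unifrac(
                a, b, ids, tree, normalized=True
            ) == pytest.approx(
                weighted_unifrac_naive(da, db, tree, normalized=True), abs=1e-9
            )
            assert community.unifrac(
                a, b, ids, tree, weighted=False
            ) == pytest.approx(unweighted_unifrac_naive(da, db, tree), abs=1e-9)
            assert community.faith_pd(a, ids, tree) == pytest.approx(
                faith_pd_naive(da, tree), abs=1e-9
            ) or a.sum() == 0


class TestDistanceMatrixAndPcoa:
    def test_matrix_matches_per_pair_calls(self):
        tree = random_tree(6, seed=3)
        rng = np.random.default_rng(0)
        ids = [f"OTU_{i}" for i in range(1, 7)]
        table = pd.DataFrame(
            rng.integers(1, 30, (4, 6)), index=list("wxyz"), columns=ids
        )
        dm = community.distance_matrix(table, tree, "weighted_unifrac")
        arr = np.asarray(dm.data)
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        for i, si in enumerate(table.index):
            for j, sj in enumerate(table.index):
                if i < j:
                    direct = community.unifrac(
                        table.loc[si], table.loc[sj], ids, tree
                    )
                    assert arr[i, j] == pytest.approx(direct, abs=1e-9)

    def test_unknown_metric_lists_supported(self):
        table = pd.DataFrame({"OTU_1": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="unweighted_unifrac"):
            community.distance_matrix(table, random_tree(2, 0), "bray")

    def test_two_point_pcoa(self):
        dm = pd.DataFrame([[0, 2], [2, 0]], index=["a", "b"], columns=["a", "b"])
        coords, eigvals = community.pcoa(dm)
        assert eigvals[0] == pytest.approx(2.0)
        assert sorted(coords["PC1"]) == pytest.approx([-1.0, 1.0])

    def test_euclidean_round_trip(self, rng):
        pts = rng.normal(0, 1, (7, 2))
        d = squareform(pdist(pts))
        labels = [f"s{i}" for i in range(7)]
        coords, eigvals = community.pcoa(pd.DataFrame(d, index=labels, columns=labels))
        rebuilt = squareform(pdist(coords.to_numpy()))
        assert np.allclose(rebuilt, d, atol=1e-9)
        # 2-D configuration: only two meaningfully positive eigenvalues
        assert (eigvals > 1e-8).sum() == 2

    def test_all_zero_distances_give_no_variation(self):
        dm = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        coords, eigvals = community.pcoa(dm)
        assert np.allclose(coords.to_numpy(), 0) if coords.shape[1] else True
        assert np.allclose(eigvals, 0, atol=1e-12)

    def test_asymmetric_matrix_rejected(self):
        dm = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            community.pcoa(dm)

    def test_matches_reference_ordination(self, rng):
        """Cross-check coordinates against scikit-bio's PCoA up to sign."""
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(0, 1, (6, 3))
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(6)]
        coords, _ = community.pcoa(pd.DataFrame(d, index=ids, columns=ids))
        ref = skbio_pcoa(DistanceMatrix(d, ids), number_of_dimensions=3)
        for k in range(3):
            ours = coords.iloc[:, k].to_numpy()
            theirs = ref.samples.iloc[:, k].to_numpy()
            assert np.allclose(ours, theirs, atol=1e-8) or np.allclose(
                ours, -theirs, atol=1e-8
            )


class TestTreeIO(object):
    def test_newick_round_trip(self, tmp_path):
        tree = random_tree(6, seed=9)
        path = tmp_path / "tree.nwk"
        tree.write(str(path))
        back = community.read_tree(path)
        assert {t.name for t in back.tips()} == {f"OTU_{i}" for i in range(1, 7)}

    def test_otu_table_round_trip(self, tmp_path, rng):
        table = pd.DataFrame(
            rng.integers(0, 9, (3, 4)),
            index=["s1", "s2", "s3"],
            columns=[f"OTU_{i}" for i in range(1, 5)],
        )
        path = tmp_path / "otu.tsv"
        community.write_otu_table(table, path)
        back = community.read_otu_table(path)
        pd.testing.assert_frame_equal(back, table, check_names=False)
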