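"""Diversity metrics against hand-computed fixtures and brute-force oracles."""

import io

import numpy as np
import pytest
from skbio import TreeNode

import microqtl as mq
from microqtl import diversity as dv
from microqtl.diversity import DistanceMatrix, UndefinedSampleError

from conftest import random_count_table


def _table(counts, samples=None, asvs=None):
    counts = np.asarray(counts, dtype=np.int64)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    asvs = asvs or [f"t{j}" for j in range(counts.shape[1])]
    return mq.CountTable(samples, asvs, counts)


# ---------------------------------------------------------------------------
# brute-force UniFrac oracles: per-pair, O(n_taxa * n_branches), no sharing
# ---------------------------------------------------------------------------

def _branch_leafsets(tree):
    out = []
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} or {node.name}
        out.append((node.length, leaves))
    return out


def unifrac_oracle(tree, x, y, taxa, weighted=False, normalized=False):
    xs = {t for t, c in zip(taxa, x) if c > 0}
    ys = {t for t, c in zip(taxa, y) if c > 0}
    if not weighted:
        unique = shared = 0.0
        for length, leaves in _branch_leafsets(tree):
            in_x, in_y = bool(leaves & xs), bool(leaves & ys)
            if in_x or in_y:
                shared += length
                if in_x != in_y:
                    unique += length
        return unique / shared if shared > 0 else 0.0
    tx, ty = sum(x), sum(y)
    num = den = 0.0
    for length, leaves in _branch_leafsets(tree):
        a = sum(c for t, c in zip(taxa, x) if t in leaves) / tx
        b = sum(c for t, c in zip(taxa, y) if t in leaves) / ty
        num += length * abs(a - b)
        den += length * (a + b)
    return num / den if normalized else num


class TestRarefy:
    def test_exact_depth_boundary_kept(self):
        ct = _table([[3000, 1500], [10, 0]])
        out, dropped = dv.rarefy(ct, 4500, seed=0)
        assert dropped == ["s1"]
        assert out.counts.sum(axis=1).tolist() == [4500]
        np.testing.assert_array_equal(out.counts[0], [3000, 1500])

    def test_one_below_depth_dropped(self):
        """A 4,499-count sample is dropped at depth 4,500."""
        ct = _table([[4499, 0], [4500, 100]])
        out, dropped = dv.rarefy(ct, 4500, seed=0)
        assert dropped == ["s0"]

    def test_single_taxon_sample(self):
        ct = _table([[9000, 0, 0], [5000, 5000, 5000]])
        out, _ = dv.rarefy(ct, 4500, seed=1)
        np.testing.assert_array_equal(out.counts[0], [4500, 0, 0])

    def test_deterministic_and_observed_monotone(self):
        rng = np.random.default_rng(5)
        ct = random_count_table(rng, 5, 20, zero_fraction=0.2)
        a, _ = dv.rarefy(ct, 30, seed=9)
        b, _ = dv.rarefy(ct, 30, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)
        for i, s in enumerate(a.sample_ids):
            before = dv.observed_species(ct.counts[ct.sample_ids.index(s)])
            assert dv.observed_species(a.counts[i]) <= before

    def test_all_below_depth_errors(self):
        with pytest.raises(Exception, match="depth"):
            dv.rarefy(_table([[3, 1]]), 100, seed=0)


class TestAlpha:
    @pytest.mark.parametrize(
        "counts,expected",
        [([10, 0, 0], 0.0), ([5, 5], 1.0), ([2, 1, 1], 1.5)],
    )
    def test_shannon_fixtures_bits(self, counts, expected):
        assert dv.shannon(np.array(counts)) == pytest.approx(expected, abs=1e-12)

    def test_shannon_all_zero_errors(self):
        with pytest.raises(UndefinedSampleError):
            dv.shannon(np.array([0, 0]))

    @pytest.mark.parametrize("counts,expected", [([0, 0, 0], 0), ([1, 0, 7], 2)])
    def test_observed_species(self, counts, expected):
        assert dv.observed_species(np.array(counts)) == expected


class TestBetaFixtures:
    def test_bray_curtis_hand_value(self):
        D = dv.bray_curtis(_table([[1, 2, 3], [3, 2, 1]])).D
        assert D[0, 1] == pytest.approx(4 / 12, abs=1e-12)

    def test_jaccard_hand_value(self):
        D = dv.jaccard(_table([[1, 1, 1, 0], [0, 1, 1, 1]])).D
        assert D[0, 1] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("metric", [dv.bray_curtis, dv.jaccard])
    def test_identity_and_disjoint_extremes(self, metric):
        D = metric(_table([[2, 4, 0, 0], [2, 4, 0, 0], [0, 0, 1, 9]])).D
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert D[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_unweighted_unifrac_disjoint_pair(self, four_leaf_tree):
        ct = _table([[1, 0, 0, 0], [0, 0, 1, 0]], asvs=list("ABCD"))
        D = dv.unweighted_unifrac(ct, four_leaf_tree).D
        assert D[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_unweighted_unifrac_nested_pair(self, four_leaf_tree):
        ct = _table([[1, 1, 0, 0], [1, 0, 0, 0]], asvs=list("ABCD"))
        D = dv.unweighted_unifrac(ct, four_leaf_tree).D
        assert D[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_weighted_unifrac_two_leaf_fixture(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1);"))
        ct = _table([[5, 0], [0, 7]], asvs=list("AB"))
        assert dv.weighted_unifrac(ct, tree).D[0, 1] == pytest.approx(2.0, abs=1e-12)
        assert dv.weighted_unifrac(ct, tree, normalized=True).D[0, 1] == pytest.approx(
            1.0, abs=1e-12
        )

    def test_weighted_identical_profiles_zero(self, four_leaf_tree):
        ct = _table([[2, 4, 6, 0], [1, 2, 3, 0]], asvs=list("ABCD"))
        assert dv.weighted_unifrac(ct, four_leaf_tree).D[0, 1] == pytest.approx(0, abs=1e-12)

    def test_weighted_zero_total_sample_errors(self, four_leaf_tree):
        ct = _table([[1, 1, 0, 0], [0, 0, 0, 0]], asvs=list("ABCD"))
        with pytest.raises(UndefinedSampleError):
            dv.weighted_unifrac(ct, four_leaf_tree)

    def test_taxon_missing_from_tree_errors(self, four_leaf_tree):
        ct = _table([[1, 1], [1, 0]], asvs=["A", "Z"])
        with pytest.raises(Exception, match="tree"):
            dv.unweighted_unifrac(ct, four_leaf_tree)


class TestUnifracOracle:
    """Optimized implementation vs independent per-pair brute force."""

    @pytest.mark.parametrize("seed", range(5))
    def test_random_ten_leaf_trees(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{j}" for j in range(10)]
        tree = mq.simulate_tree(taxa, seed=seed + 100)
        ct = random_count_table(rng, 6, 10, zero_fraction=0.4)
        Du = dv.unweighted_unifrac(ct, tree).D
        Dw = dv.weighted_unifrac(ct, tree).D
        Dn = dv.weighted_unifrac(ct, tree, normalized=True).D
        for i in range(6):
            for j in range(i + 1, 6):
                x, y = ct.counts[i], ct.counts[j]
                assert Du[i, j] == pytest.approx(
                    unifrac_oracle(tree, x, y, taxa), abs=1e-12
                )
                assert Dw[i, j] == pytest.approx(
                    unifrac_oracle(tree, x, y, taxa, weighted=True), abs=1e-12
                )
                assert Dn[i, j] == pytest.approx(
                    unifrac_oracle(tree, x, y, taxa, weighted=True, normalized=True),
                    abs=1e-12,
                )

    @pytest.mark.parametrize("metric", [dv.bray_curtis, dv.jaccard])
    def test_metric_properties_random(self, metric):
        rng = np.random.default_rng(42)
        ct = random_count_table(rng, 8, 12)
        dm = metric(ct)  # symmetry/diagonal/positivity enforced in constructor
        assert (dm.D <= 1 + 1e-12).all()


class TestPcoa:
    def test_collinear_points_fixture(self):
        pts = np.array([-1.0, 0.0, 1.0])
        D = DistanceMatrix(["a", "b", "c"], np.abs(pts[:, None] - pts[None, :]), "bray_curtis")
        res = dv.pcoa(D)
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-10)
        assert res.coordinates.shape[1] == 1
        np.testing.assert_allclose(np.sort(res.coordinates[:, 0]), [-1, 0, 1], atol=1e-10)

    def test_all_zero_distances(self):
        D = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)), "jaccard")
        res = dv.pcoa(D)
        assert res.coordinates.shape[1] == 0
        np.testing.assert_allclose(res.eigenvalues, 0, atol=1e-12)

    def test_euclidean_distance_reconstruction(self):
        """Distances from embedded points are reproduced by the coordinates."""
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 4))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        res = dv.pcoa(DistanceMatrix([f"s{i}" for i in range(12)], D, "bray_curtis"))
        rec = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None], axis=-1
        )
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_proportion_explained_sums_to_one(self, small_bundle):
        rar, _ = dv.rarefy(small_bundle.counts, 500, seed=1)
        res = dv.pcoa(dv.bray_curtis(rar))
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_axis_truncation_warns_not_errors(self):
        pts = np.array([-1.0, 0.0, 1.0])
        D = DistanceMatrix(["a", "b", "c"], np.abs(pts[:, None] - pts[None, :]), "jaccard")
        with pytest.warns(UserWarning, match="truncating"):
            res = dv.pcoa(D, n_axes=5)
        assert res.coordinates.shape[1] == 1


class TestEigenvectorTraits:
    def test_trait_column_layout(self, small_bundle):
        rar, _ = dv.rarefy(small_bundle.counts, 500, seed=2)
        alpha = dv.alpha_diversity_table(rar)
        pcoas = {
            m: dv.pcoa(f(rar))
            for m, f in (("bray_curtis", dv.bray_curtis), ("jaccard", dv.jaccard))
        }
        pcoas["unweighted_unifrac"] = dv.pcoa(dv.unweighted_unifrac(rar, small_bundle.tree))
        pcoas["weighted_unifrac"] = dv.pcoa(dv.weighted_unifrac(rar, small_bundle.tree))
        traits = dv.eigenvector_traits(pcoas, [1, 2], alpha)
        assert traits.shape[1] == 4 * 2 + 2
        assert "bray_curtis_PCo2" in traits.columns and "shannon" in traits.columns

    def test_empty_axes_gives_alpha_only(self, small_bundle):
        rar, _ = dv.rarefy(small_bundle.counts, 500, seed=2)
        alpha = dv.alpha_diversity_table(rar)
        traits = dv.eigenvector_traits({}, [], alpha)
        assert list(traits.columns) == ["shannon", "observed_species"]

    def test_missing_axis_is_config_error(self, small_bundle):
        from microqtl.core import ConfigError

        rar, _ = dv.rarefy(small_bundle.counts, 500, seed=2)
        res = dv.pcoa(dv.bray_curtis(rar))
        with pytest.raises(ConfigError):
            dv.eigenvector_traits({"bray_curtis": res}, [res.coordinates.shape[1] + 1])
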