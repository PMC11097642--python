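"""clr pipeline: relative abundance, family filter, CZM, clr, distances,
centroids and phylum aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virosurvey import composition as comp


def _frame(rows, columns=None, index=None):
    arr = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(
        arr,
        index=index or [f"s{i}" for i in range(arr.shape[0])],
        columns=columns or [f"f{j}" for j in range(arr.shape[1])],
    )


class TestRelativeAbundance:
    def test_simple_normalisation(self):
        rel = comp.to_relative_abundance(_frame([2, 2, 4]))
        assert np.allclose(rel.to_numpy(), [[0.25, 0.25, 0.5]], atol=1e-15)

    def test_single_family(self):
        rel = comp.to_relative_abundance(_frame([0, 9, 0]))
        assert np.allclose(rel.to_numpy(), [[0, 1, 0]], atol=1e-15)

    def test_rows_sum_to_one_on_random_input(self, rng):
        counts = _frame(rng.integers(0, 50, size=(20, 8)) + 1)
        rel = comp.to_relative_abundance(counts)
        assert np.allclose(rel.sum(axis=1).to_numpy(), 1.0, atol=1e-12)

    def test_zero_row_lists_sample(self):
        with pytest.raises(ValueError, match="s1"):
            comp.to_relative_abundance(_frame([[1, 2], [0, 0]]))


class TestFamilyFilter:
    def test_boundary_application(self):
        rel = _frame([
            [0.00009, 0.0001, 0.99981],
            [0.00009, 0.0001, 0.99981],
        ])
        out = comp.filter_families(rel, min_mean=1e-4)
        assert list(out.columns) == ["f1", "f2"]  # 0.009% dropped, exactly 0.01% kept
        assert np.allclose(out.sum(axis=1).to_numpy(), 1.0, atol=1e-12)

    def test_threshold_is_column_mean(self):
        rel = _frame([[0.5, 0.5], [1e-6, 1.0 - 1e-6]])
        out = comp.filter_families(rel, min_mean=0.2)
        assert list(out.columns) == ["f0", "f1"]  # mean of f0 = 0.25 >= 0.2

    def test_all_dropped_is_error(self):
        with pytest.raises(ValueError):
            comp.filter_families(_frame([0.5, 0.5]), min_mean=0.9)


class TestCZM:
    def test_zero_free_row_unchanged(self):
        rel = _frame([0.2, 0.3, 0.5])
        out = comp.czm_replace_zeros(rel, np.array([100.0]))
        assert np.allclose(out.to_numpy(), rel.to_numpy(), atol=1e-15)

    def test_worked_example_depth_99(self):
        rel = _frame([0.5, 0.5, 0.0])
        out = comp.czm_replace_zeros(rel, np.array([99.0]))
        assert out.iloc[0, 2] == pytest.approx(0.0065, abs=1e-15)
        assert out.iloc[0, 0] == pytest.approx(0.49675, abs=1e-12)
        assert out.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_preserves_nonzero_ratios_and_simplex(self, rng):
        x = rng.dirichlet(np.ones(10), size=15)
        x[x < 0.05] = 0.0
        x = x / x.sum(axis=1, keepdims=True)
        rel = _frame(x)
        depths = rng.integers(1000, 100000, 15).astype(float)
        out = comp.czm_replace_zeros(rel, depths)
        assert (out.to_numpy() > 0).all()
        assert np.allclose(out.sum(axis=1).to_numpy(), 1.0, atol=1e-12)
        for i in range(15):
            nz = x[i] > 0
            before = x[i][nz] / x[i][nz].sum()
            after = out.to_numpy()[i][nz] / out.to_numpy()[i][nz].sum()
            assert np.allclose(before, after, atol=1e-12)

    def test_imputation_above_detection_limit_warns(self):
        rel = _frame([0.001, 0.999, 0.0])
        with pytest.warns(UserWarning, match="smallest observed"):
            comp.czm_replace_zeros(rel, np.array([50.0]))

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            comp.czm_replace_zeros(_frame([1.0]), np.array([10.0]), label=1.5)


class TestClr:
    def test_uniform_maps_to_zero(self):
        clr = comp.clr_transform(_frame([1 / 3, 1 / 3, 1 / 3]))
        assert np.allclose(clr.to_numpy(), 0.0, atol=1e-15)

    def test_geometric_example(self):
        clr = comp.clr_transform(_frame(np.array([1.0, 2.0, 4.0]) / 7.0))
        assert np.allclose(clr.to_numpy(),
                           [[-np.log(2), 0.0, np.log(2)]], atol=1e-12)

    def test_rows_sum_to_zero(self, rng):
        rel = _frame(rng.dirichlet(np.ones(12) * 2, size=25))
        clr = comp.clr_transform(rel)
        assert np.abs(clr.sum(axis=1).to_numpy()).max() < 1e-10

    def test_scale_invariance(self, rng):
        counts = rng.integers(1, 500, size=(6, 9)).astype(float)
        rel_a = comp.to_relative_abundance(_frame(counts))
        rel_b = comp.to_relative_abundance(_frame(counts * 37.0))
        assert np.allclose(comp.clr_transform(rel_a).to_numpy(),
                           comp.clr_transform(rel_b).to_numpy(), atol=1e-12)

    def test_nonpositive_entry_rejected(self):
        with pytest.raises(ValueError):
            comp.clr_transform(_frame([0.5, 0.5, 0.0]))


class TestDistances:
    def test_identical_rows_distance_zero(self):
        clr = _frame([[0.1, -0.1], [0.1, -0.1]])
        d = comp.aitchison_distances(clr)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_euclidean_example(self):
        clr = _frame([[0.0, 0.0], [3.0, -3.0]])
        d = comp.aitchison_distances(clr)
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(18), abs=1e-12)

    def test_symmetry_and_zero_diagonal(self, rng):
        clr = _frame(rng.normal(size=(10, 4)))
        d = comp.aitchison_distances(clr).to_numpy()
        assert np.allclose(d, d.T, atol=1e-15)
        assert np.allclose(np.diag(d), 0.0, atol=1e-15)

    def test_perturbation_invariance(self, rng):
        # Aitchison distance is unchanged when every sample is perturbed by
        # one common composition
        x = rng.dirichlet(np.ones(8) * 3, size=12)
        common = rng.dirichlet(np.ones(8))
        perturbed = x * common
        perturbed /= perturbed.sum(axis=1, keepdims=True)
        d1 = comp.aitchison_distances(comp.clr_transform(_frame(x))).to_numpy()
        d2 = comp.aitchison_distances(comp.clr_transform(_frame(perturbed))).to_numpy()
        assert np.allclose(d1, d2, atol=1e-10)


class TestCentroidDistances:
    def test_identical_samples_zero_distance(self):
        clr = _frame(np.tile([0.3, -0.3], (4, 1)))
        groups = pd.Series(["g"] * 4, index=clr.index)
        out = comp.centroid_distances(clr, groups)
        assert np.allclose(out["distance"].to_numpy(), 0.0, atol=1e-15)

    def test_two_samples_equidistant(self):
        clr = _frame([[1.0, -1.0], [3.0, -3.0]])
        groups = pd.Series(["g", "g"], index=clr.index)
        out = comp.centroid_distances(clr, groups)
        pair = np.linalg.norm(np.array([1.0, -1.0]) - np.array([3.0, -3.0]))
        assert np.allclose(out["distance"].to_numpy(), pair / 2, atol=1e-12)

    def test_matches_brute_force(self, rng):
        clr = _frame(rng.normal(size=(10, 5)))
        groups = pd.Series(rng.choice(["a", "b"], 10), index=clr.index)
        out = comp.centroid_distances(clr, groups).set_index("sample_id")
        for sid in clr.index:
            g = groups[sid]
            centroid = clr.loc[groups == g].mean(axis=0)
            expected = np.linalg.norm(clr.loc[sid] - centroid)
            assert out.loc[sid, "distance"] == pytest.approx(expected, abs=1e-12)

    def test_min_group_size_filters(self):
        clr = _frame(np.ones((5, 3)))
        groups = pd.Series(["big"] * 4 + ["small"], index=clr.index)
        out = comp.centroid_distances(clr, groups, min_group_size=2)
        assert set(out["group"]) == {"big"}


class TestAggregateByGroup:
    def test_identical_samples_reproduce_composition(self):
        rel = _frame(np.tile([0.2, 0.3, 0.5], (3, 1)))
        groups = pd.Series(["g"] * 3, index=rel.index)
        profiles, _, _ = comp.aggregate_by_group(rel, groups)
        expected = comp.clr_transform(_frame([0.2, 0.3, 0.5]))
        assert np.allclose(profiles.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_equal_weight_mean_property(self):
        rel = _frame([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]])
        groups = pd.Series(["g", "g"], index=rel.index)
        p1, _, _ = comp.aggregate_by_group(rel, groups)
        # adding a sample identical to the current mean does not move the profile
        mean = rel.mean(axis=0)
        rel3 = pd.concat([rel, mean.to_frame("s2").T])
        p2, _, _ = comp.aggregate_by_group(rel3, pd.Series(["g"] * 3, index=rel3.index))
        assert np.allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-12)
        # duplicating one sample does move it
        rel_dup = pd.concat([rel, rel.iloc[[0]].set_index(pd.Index(["dup"]))])
        p3, _, _ = comp.aggregate_by_group(rel_dup,
                                           pd.Series(["g"] * 3, index=rel_dup.index))
        assert not np.allclose(p1.to_numpy(), p3.to_numpy(), atol=1e-6)

    def test_disjoint_dominance_merges_last(self):
        # two groups dominated by disjoint families vs two similar groups:
        # the dendrogram's root split separates the odd one out
        eps = 1e-3
        rows = {
            "a1": [0.9, 0.05, eps, eps], "a2": [0.85, 0.1, eps, eps],
            "b1": [0.05, 0.9, eps, eps], "b2": [0.1, 0.85, eps, eps],
            "c1": [eps, eps, 0.9, 0.05], "c2": [eps, eps, 0.85, 0.1],
        }
        rel = _frame(list(rows.values()), index=list(rows))
        rel = rel.div(rel.sum(axis=1), axis=0)
        groups = pd.Series([k[0] for k in rows], index=rel.index)
        profiles, link, _ = comp.aggregate_by_group(rel, groups)
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(link, t=2, criterion="maxclust")
        clusters = dict(zip(profiles.index, two))
        assert clusters["a"] == clusters["b"]
        assert clusters["c"] != clusters["a"]

    def test_newick_round_trip_preserves_leaves(self, small_survey):
        counts, meta, _ = small_survey
        rel = comp.czm_replace_zeros(
            comp.filter_families(comp.to_relative_abundance(counts)),
            counts.sum(axis=1).to_numpy(),
        )
        profiles, link, _ = comp.aggregate_by_group(rel, meta["phylum"])
        nwk = comp.linkage_to_newick(link, list(profiles.index))
        import io
        from Bio import Phylo

        tree = Phylo.read(io.StringIO(nwk), "newick")
        leaves = sorted(t.name for t in tree.get_terminals())
        assert leaves == sorted(profiles.index)


class TestPipelineOrder:
    def test_filter_then_impute_then_clr(self, small_survey):
        counts, _, _ = small_survey
        clr = comp.clr_pipeline(counts)
        rel = comp.filter_families(comp.to_relative_abundance(counts))
        manual = comp.clr_transform(
            comp.czm_replace_zeros(rel, counts.sum(axis=1).to_numpy())
        )
        assert np.allclose(clr.to_numpy(), manual.to_numpy(), atol=1e-14)
        assert np.abs(clr.sum(axis=1).to_numpy()).max() < 1e-10
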