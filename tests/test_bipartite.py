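"""Bipartite network indices, Patefield nulls and z-tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from virosurvey import bipartite as bp


def nodf_bruteforce(binary: np.ndarray) -> float:
    """Independent literal evaluation of NODF: all pairs, both axes."""
    total = 0.0
    pairs = 0
    for axis in (0, 1):
        b = binary if axis == 0 else binary.T
        fills = b.sum(axis=1)
        for i, j in itertools.combinations(range(b.shape[0]), 2):
            pairs += 1
            hi, lo = (i, j) if fills[i] >= fills[j] else (j, i)
            if fills[hi] > fills[lo] and fills[lo] > 0:
                total += 100.0 * (b[hi] & b[lo]).sum() / fills[lo]
    return total / pairs


class TestBuild:
    def test_presence_fraction(self):
        rel = pd.DataFrame(
            {"famA": [0.1] * 3 + [0.0] * 12, "famB": [0.2] * 15},
            index=[f"s{i}" for i in range(15)],
        )
        groups = pd.Series(["P"] * 15, index=rel.index)
        m = bp.build_bipartite(rel, mode="presence_fraction", groups=groups)
        assert m.loc["P", "famA"] == pytest.approx(0.2, abs=1e-12)
        assert m.loc["P", "famB"] == pytest.approx(1.0, abs=1e-12)

    def test_abundance_single_sample_is_its_composition(self):
        rel = pd.DataFrame([[0.3, 0.7]], index=["s1"], columns=["a", "b"])
        m = bp.build_bipartite(rel)
        assert np.allclose(m.to_numpy(), [[0.3, 0.7]], atol=1e-15)

    def test_presence_filter_keeps_20pct_in_one_group(self):
        idx = [f"s{i}" for i in range(40)]
        rel = pd.DataFrame(0.1, index=idx, columns=["common", "rare"])
        rel.loc[idx[4:20], "rare"] = 0.0   # 4/20 in group A, 0/20 in group B
        rel.loc[idx[20:], "rare"] = 0.0
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=idx)
        kept = bp.presence_filter(rel, groups, min_fraction=0.2)
        assert "rare" in kept.columns
        rel.loc[idx[3], "rare"] = 0.0      # now 3/20 = 15% in the best group
        kept2 = bp.presence_filter(rel, groups, min_fraction=0.2)
        assert "rare" not in kept2.columns

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            bp.build_bipartite(pd.DataFrame())


class TestLinkageDensity:
    def test_single_link(self):
        assert bp.linkage_density([[3.0]]) == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_two_by_two(self):
        assert bp.linkage_density([[1.0, 0.0], [0.0, 1.0]]) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_uniform_complete_two_by_two(self):
        assert bp.linkage_density([[1.0, 1.0], [1.0, 1.0]]) == pytest.approx(
            2.0, abs=1e-12
        )


class TestH2Prime:
    def test_diagonal_equal_totals_fully_specialised(self):
        assert bp.h2_prime([[1.0, 0.0], [0.0, 1.0]]) == pytest.approx(1.0, abs=1e-12)

    def test_independence_table_fully_generalised(self):
        m = np.outer([0.2, 0.3, 0.5], [0.6, 0.4])
        assert bp.h2_prime(m) == pytest.approx(0.0, abs=1e-10)

    def test_always_in_unit_interval(self, rng):
        for _ in range(50):
            m = rng.random((rng.integers(2, 6), rng.integers(2, 6)))
            assert 0.0 <= bp.h2_prime(m) <= 1.0

    def test_scale_invariance(self, rng):
        m = rng.random((4, 5))
        assert bp.h2_prime(m) == pytest.approx(bp.h2_prime(m * 123.4), abs=1e-12)

    def test_degenerate_single_cell_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert bp.h2_prime([[2.0]]) == 0.0


class TestNodf:
    def test_perfect_staircase(self):
        assert bp.nodf([[1, 1, 1], [1, 1, 0], [1, 0, 0]]) == pytest.approx(100.0)

    def test_identity_has_no_overlap(self):
        assert bp.nodf(np.eye(3)) == pytest.approx(0.0)

    def test_equal_fill_pairs_contribute_zero(self):
        # both rows have fill 2 with full overlap: still 0 by decreasing-fill
        m = np.array([[1, 1, 0], [1, 1, 0]])
        row_only = bp.nodf(m)
        brute = nodf_bruteforce(m > 0)
        assert row_only == pytest.approx(brute, abs=1e-12)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(100):
            m = (rng.random((5, 5)) < 0.5).astype(int)
            if m.sum() == 0:
                continue
            assert bp.nodf(m) == pytest.approx(nodf_bruteforce(m > 0), abs=1e-10)

    def test_binarisation_ignores_weights(self, rng):
        binary = (rng.random((6, 4)) < 0.5).astype(float)
        if binary.sum() == 0:
            binary[0, 0] = 1.0
        weighted = binary * rng.uniform(0.5, 9.0, size=binary.shape)
        assert bp.nodf(weighted) == pytest.approx(bp.nodf(binary), abs=1e-12)


class TestModularity:
    def test_two_disconnected_equal_blocks(self):
        q, assign = bp.q_modularity([[1.0, 0.0], [0.0, 1.0]], seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert assign[("row", 0)] == assign[("col", 0)]
        assert assign[("row", 0)] != assign[("row", 1)]

    def test_uniform_matrix_has_no_structure(self):
        q, _ = bp.q_modularity(np.ones((4, 4)), seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_never_below_one_module_baseline(self, rng):
        for i in range(20):
            m = rng.random((5, 6))
            q, _ = bp.q_modularity(m, seed=i)
            assert q >= 0.0

    def test_deterministic_under_seed(self, rng):
        m = rng.random((8, 10))
        a = bp.q_modularity(m, seed=42)
        b = bp.q_modularity(m, seed=42)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_recovers_planted_blocks(self):
        m = np.zeros((6, 6))
        m[:3, :3] = 1.0
        m[3:, 3:] = 1.0
        q, assign = bp.q_modularity(m, seed=1)
        assert q == pytest.approx(0.5, abs=1e-12)
        rows = [assign[("row", i)] for i in range(6)]
        assert len({*rows[:3]}) == 1 and len({*rows[3:]}) == 1
        assert rows[0] != rows[3]


class TestDPrime:
    def test_proportional_node_is_generalist(self):
        m = np.outer([0.3, 0.7], [0.4, 0.6])
        d = bp.d_prime(m, "rows")
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_all_weight_on_rarest_feasible_partner_is_specialist(self):
        # column totals (1, 5, 5): row 0 packs its whole unit onto the
        # rarest partner, which is exactly the d_max packing
        m = np.array([[1.0, 0.0, 0.0], [0.0, 5.0, 5.0]])
        d = bp.d_prime(m, "rows")
        assert d[0] == pytest.approx(1.0, abs=1e-12)

    def test_always_in_unit_interval(self, rng):
        for _ in range(30):
            m = rng.random((4, 6))
            for margin in ("rows", "columns"):
                d = bp.d_prime(m, margin)
                assert np.all((d >= 0) & (d <= 1))

    def test_scale_invariance(self, rng):
        m = rng.random((3, 5))
        assert np.allclose(bp.d_prime(m), bp.d_prime(m * 55.5), atol=1e-12)

    def test_zero_weight_node_flagged(self):
        m = np.array([[1.0, 1.0], [0.0, 0.0], [2.0, 1.0]])
        with pytest.warns(UserWarning, match="zero weight"):
            d = bp.d_prime(m, "rows")
        assert np.isnan(d[1])


class TestPatefield:
    def test_marginals_preserved_exactly(self, rng):
        m = rng.integers(0, 20, size=(5, 7)).astype(float)
        m[0, 0] += 1  # ensure nonzero
        null = bp.patefield_null(m, rng, scale=1.0)
        assert np.allclose(null.sum(axis=1), m.sum(axis=1), atol=1e-12)
        assert np.allclose(null.sum(axis=0), m.sum(axis=0), atol=1e-12)

    def test_two_by_two_hypergeometric_law(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        rng = np.random.default_rng(123)
        hits = sum(bp.patefield_null(m, rng, scale=1.0)[0, 0] == 1.0
                   for _ in range(1000))
        assert abs(hits / 1000 - 0.5) < 0.05

    def test_single_row_forced(self, rng):
        m = np.array([[3.0, 1.0, 2.0]])
        null = bp.patefield_null(m, rng, scale=1.0)
        assert np.allclose(null, m, atol=1e-12)

    def test_cell_means_approach_independence(self):
        m = np.array([[4.0, 2.0], [2.0, 4.0]])
        rng = np.random.default_rng(9)
        draws = np.stack([bp.patefield_null(m, rng, scale=1.0)
                          for _ in range(4000)])
        r = m.sum(axis=1, keepdims=True)
        c = m.sum(axis=0, keepdims=True)
        expected = r * c / m.sum()
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9)

    def test_continuous_weights_scaled_and_rescaled(self, rng):
        m = rng.dirichlet(np.ones(4), size=3)
        null = bp.patefield_null(m, rng, scale=1e4)
        assert np.allclose(null.sum(axis=1), np.rint(m * 1e4).sum(axis=1) / 1e4,
                           atol=1e-12)


class TestNullZtest:
    def test_observed_at_null_mean(self, rng):
        nulls = rng.normal(10.0, 2.0, size=500)
        z, p = bp.null_ztest(float(nulls.mean()), nulls)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_1p96_sd_gives_p05(self, rng):
        nulls = rng.normal(0.0, 1.0, size=1000)
        obs = nulls.mean() + 1.96 * nulls.std(ddof=1)
        _, p = bp.null_ztest(float(obs), nulls)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_boundary_warning(self, rng):
        nulls = rng.normal(size=200)
        nulls = (nulls - nulls.mean()) / nulls.std(ddof=1) * 0.03 + 0.95
        with pytest.warns(UserWarning, match="boundary"):
            bp.null_ztest(0.999, nulls, bounds=(0.0, 1.0))

    def test_zero_sd_is_error(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            bp.null_ztest(1.0, np.full(100, 3.0))

    def test_too_few_nulls_rejected(self, rng):
        with pytest.raises(ValueError, match="30"):
            bp.null_ztest(0.0, rng.normal(size=10))


class TestDprimeAnova:
    def test_shifted_phylum_isolated_by_letters(self, rng):
        d = pd.Series(
            np.concatenate([rng.normal(0.02, 0.005, 10).clip(0.001),
                            rng.normal(0.02, 0.005, 10).clip(0.001),
                            rng.normal(0.40, 0.005, 10)]),
            index=[f"s{i}" for i in range(30)],
        )
        phyla = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=d.index)
        fit = bp.dprime_anova(d, phyla)
        letters = fit.tukey("phylum").letters
        assert letters["C"] not in (letters["A"], letters["B"])
        assert set(letters["A"]) & set(letters["B"])

    def test_equal_dprimes_give_zero_f(self):
        d = pd.Series(np.full(20, 0.01), index=[f"s{i}" for i in range(20)])
        phyla = pd.Series(["A"] * 10 + ["B"] * 10, index=d.index)
        fit = bp.dprime_anova(d, phyla)
        assert fit.anova_table.loc["phylum", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_delegates_to_diversity_module(self, rng):
        from virosurvey.diversity import DiversityANOVA

        d = pd.Series(rng.uniform(0.0, 0.1, 24), index=[f"s{i}" for i in range(24)])
        phyla = pd.Series(rng.choice(["A", "B"], 24), index=d.index)
        ours = bp.dprime_anova(d, phyla)
        direct = DiversityANOVA(
            pd.DataFrame({"dprime": d, "phylum": phyla}),
            response="dprime", factors=("phylum",), min_group_size=5,
        ).fit()
        assert ours.aic == pytest.approx(direct.aic, abs=1e-12)
        pd.testing.assert_frame_equal(ours.anova_table, direct.anova_table)


class TestAnalysisWrapper:
    def test_fit_returns_indices_nulls_and_ztests(self, small_survey):
        from virosurvey import composition as comp

        counts, meta, _ = small_survey
        rel = comp.filter_families(comp.to_relative_abundance(counts))
        matrix = bp.build_bipartite(rel, mode="abundance", groups=meta["phylum"])
        res = bp.BipartiteAnalysis(matrix).fit(n_null=60, seed=0)
        assert set(res.indices.index) == {"linkage_density", "h2_prime", "nodf",
                                          "q_modularity"}
        assert len(res.nulls) == 60
        assert res.dprime_rows.index.equals(matrix.index)
        assert "z" in res.null_table.columns
        # deterministic under seed
        res2 = bp.BipartiteAnalysis(matrix).fit(n_null=60, seed=0)
        assert res.indices.equals(res2.indices)
        assert res.nulls.equals(res2.nulls)
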