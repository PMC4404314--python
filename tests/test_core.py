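"""Scoring statistic, Monte Carlo p-values, invariances, brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_design
from peacs import (
    Centroid,
    ExpressionMatrix,
    PerturbationEmbedding,
    embed,
    empirical_pvalue,
    global_centroid,
    monte_carlo_pvalues,
    run_peacs,
    score_all,
    score_perturbation,
    svd_factor,
)


def make_embedding(coords, sample_ids=None):
    coords = np.asarray(coords, dtype=float)
    ids = sample_ids or [f"s{i}" for i in range(coords.shape[0])]
    return PerturbationEmbedding(coords=coords, sample_ids=ids, k=coords.shape[1])


class TestEmbed:
    def test_full_k_equals_U(self, rng):
        F = svd_factor(rng.normal(size=(10, 5)), k=4)
        E = embed(F)
        np.testing.assert_array_equal(E.coords, F.U)

    def test_k1_single_unit_column(self, rng):
        F = svd_factor(rng.normal(size=(10, 5)), k=3)
        E = embed(F, k=1)
        assert E.coords.shape == (10, 1)
        assert np.linalg.norm(E.coords[:, 0]) == pytest.approx(1.0)

    def test_matches_slicing_oracle(self, rng):
        X = rng.normal(size=(10, 5))
        E = embed(svd_factor(X, k=5), k=3)
        U_full, _, _ = np.linalg.svd(X, full_matrices=False)
        # sign-agnostic comparison per component
        for i in range(3):
            assert (
                np.allclose(E.coords[:, i], U_full[:, i], atol=1e-10)
                or np.allclose(E.coords[:, i], -U_full[:, i], atol=1e-10)
            )

    def test_k_too_large_errors(self, rng):
        F = svd_factor(rng.normal(size=(6, 4)), k=2)
        with pytest.raises(ValueError, match="k="):
            embed(F, k=3)


class TestGlobalCentroid:
    def test_symmetric_coords_give_zero(self):
        E = make_embedding([[1, 2], [-1, -2], [3, -1], [-3, 1]])
        np.testing.assert_allclose(global_centroid(E).values, 0.0)

    def test_single_row(self):
        E = make_embedding([[0.3, -0.7]])
        np.testing.assert_allclose(global_centroid(E).values, [0.3, -0.7])

    def test_median_matches_sort_oracle(self, rng):
        coords = rng.normal(size=(5, 3))
        c = global_centroid(make_embedding(coords))
        expected = [oracles.sort_median(coords[:, i]) for i in range(3)]
        np.testing.assert_allclose(c.values, expected)

    def test_mean_option(self, rng):
        coords = rng.normal(size=(6, 2))
        c = global_centroid(make_embedding(coords), method="mean")
        np.testing.assert_allclose(c.values, coords.mean(axis=0))


def two_group_design():
    return make_design(
        [
            ("s0", "pertA", "GA", "hA", 1, False),
            ("s1", "pertA", "GA", "hA", 2, False),
            ("s2", "pertB", "GB", "hB", 1, False),
            ("s3", "pertB", "GB", "hB", 2, False),
        ]
    )


class TestScore:
    def test_hand_computed_example(self):
        """Replicates at (1,0) and (3,0) vs centroid (0,0): d=2, SE=(1,0), score=2."""
        E = make_embedding([[1, 0], [3, 0], [0, 1], [0, -1]])
        row = score_perturbation(E, two_group_design(), "pertA", Centroid(np.zeros(2)))
        assert row["d"] == pytest.approx(2.0)
        assert row["se_1"] == pytest.approx(1.0)  # sd sqrt(2) / sqrt(2)
        assert row["se_2"] == pytest.approx(0.0)
        assert row["score"] == pytest.approx(2.0)
        assert row["flags"] == ""

    def test_replicates_at_centroid_score_zero(self):
        E = make_embedding([[0, 0], [0, 0], [1, 1], [2, 2]])
        row = score_perturbation(E, two_group_design(), "pertA", Centroid(np.zeros(2)))
        assert row["d"] == 0.0 and row["score"] == 0.0

    def test_identical_offset_replicates_hit_floor(self):
        E = make_embedding([[1, 0], [1, 0], [0, 1], [0, -1]])
        row = score_perturbation(
            E, two_group_design(), "pertA", Centroid(np.zeros(2)), se_floor=1e-8
        )
        assert row["score"] == pytest.approx(1.0 / 1e-8)
        assert "se_floored" in row["flags"]

    def test_single_replicate_unscorable(self):
        design = make_design(
            [
                ("s0", "lonely", "GA", "h1", 1, False),
                ("s1", "pair", "GB", "h2", 1, False),
                ("s2", "pair", "GB", "h2", 2, False),
            ]
        )
        E = make_embedding(np.arange(6).reshape(3, 2))
        table = score_all(E, design, Centroid(np.zeros(2)))
        lonely = table.set_index("perturbation").loc["lonely"]
        assert lonely["flags"] == "unscorable" and np.isnan(lonely["score"])

    def test_gene_level_grouping_pools_hairpins(self):
        design = make_design(
            [
                ("s0", "shG_1", "G", "shG_1", 1, False),
                ("s1", "shG_1", "G", "shG_1", 2, False),
                ("s2", "shG_2", "G", "shG_2", 1, False),
                ("s3", "shG_2", "G", "shG_2", 2, False),
            ]
        )
        E = make_embedding([[1, 0], [2, 0], [3, 0], [4, 0]])
        table = score_all(E, design, Centroid(np.zeros(2)), group_by="gene")
        assert len(table) == 1 and table.iloc[0]["n_replicates"] == 4


class TestEmpiricalPvalue:
    def test_counting_with_ties(self):
        null = [5, 4, 4, 3, 2, 2, 2, 1, 1, 0]
        # observed 4 ties with 2 entries >= handled as >=: count = 3
        assert empirical_pvalue(np.array(null, float), 4.0) == pytest.approx(4 / 11)
        assert empirical_pvalue(np.array(null, float), 4.0, raw_rank=True) == pytest.approx(0.3)

    def test_bottom_and_top_rank(self):
        null = np.arange(100, dtype=float)
        assert empirical_pvalue(null, -1.0) == pytest.approx(1.0, abs=1 / 101)
        assert empirical_pvalue(null, 1e9) == pytest.approx(1 / 101)


class TestMonteCarlo:
    def _run(self, seed=0, iterations=500):
        rng = np.random.default_rng(42)
        E = make_embedding(rng.normal(size=(12, 2)))
        design = make_design(
            [(f"s{i}", f"p{i // 2}", f"g{i // 2}", f"h{i // 2}", i % 2 + 1, False) for i in range(12)]
        )
        c = global_centroid(E)
        table = score_all(E, design, c)
        return monte_carlo_pvalues(E, design, table, c, iterations=iterations, seed=seed)

    def test_reproducible_and_floored(self):
        t1, t2 = self._run(seed=7), self._run(seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["p_value"] >= 1 / 501).all()

    def test_bonferroni_definition(self):
        t = self._run()
        n_scored = int((t["n_replicates"] >= 2).sum())
        np.testing.assert_allclose(
            t["p_bonferroni"], np.minimum(1.0, t["p_value"] * n_scored)
        )

    def test_group_larger_than_population_errors(self):
        E = make_embedding(np.ones((2, 1)))
        design = make_design(
            [("s0", "p", "g", "h", 1, False), ("s1", "p", "g", "h", 2, False)]
        )
        c = Centroid(np.zeros(1))
        table = score_all(E, design, c)
        table.loc[0, "n_replicates"] = 5
        with pytest.raises(ValueError, match="distinct"):
            monte_carlo_pvalues(E, design, table, c, iterations=100, seed=0)


def scores_of(M, design, **kw):
    res = run_peacs(M, design, filter_kd=False, iterations=200, seed=1, k=2, **kw)
    return res.table.set_index("perturbation")["score"].sort_index()


class TestPipelineInvariances:
    """PEACS scores are invariant to data transformations that leave the
    embedding geometry unchanged."""

    @pytest.fixture
    def dataset(self, rng):
        values = rng.normal(0, 1, size=(12, 5))
        M = ExpressionMatrix(
            values, [f"g{j}" for j in range(5)], [f"s{i}" for i in range(12)]
        )
        design = make_design(
            [
                (f"s{i}", f"p{i // 2}", f"g{i // 2 % 5}", f"h{i // 2}", i % 2 + 1, False)
                for i in range(12)
            ]
        )
        return M, design

    def test_gene_permutation(self, dataset, rng):
        M, design = dataset
        perm = rng.permutation(5)
        M2 = ExpressionMatrix(
            M.values[:, perm], [M.gene_ids[j] for j in perm], M.sample_ids
        )
        pd.testing.assert_series_equal(scores_of(M, design), scores_of(M2, design), atol=1e-8)

    def test_sample_permutation_with_relabel(self, dataset, rng):
        M, design = dataset
        perm = rng.permutation(12)
        M2 = ExpressionMatrix(
            M.values[perm], M.gene_ids, [M.sample_ids[i] for i in perm]
        )
        pd.testing.assert_series_equal(scores_of(M, design), scores_of(M2, design), atol=1e-8)

    def test_positive_rescaling(self, dataset):
        M, design = dataset
        M2 = ExpressionMatrix(3.14 * M.values, M.gene_ids, M.sample_ids)
        pd.testing.assert_series_equal(scores_of(M, design), scores_of(M2, design), atol=1e-8)

    def test_global_sign_flip(self, dataset):
        M, design = dataset
        M2 = ExpressionMatrix(-M.values, M.gene_ids, M.sample_ids)
        pd.testing.assert_series_equal(scores_of(M, design), scores_of(M2, design), atol=1e-8)


class TestBruteForceOracle:
    def test_pipeline_matches_loop_reimplementation(self, rng):
        """6 samples × 4 genes, k=2: scores equal an explicit-loop oracle."""
        values = rng.normal(size=(6, 4))
        M = ExpressionMatrix(values, list("abcd"), [f"s{i}" for i in range(6)])
        design = make_design(
            [
                ("s0", "p1", "a", "h1", 1, False),
                ("s1", "p1", "a", "h1", 2, False),
                ("s2", "p2", "b", "h2", 1, False),
                ("s3", "p2", "b", "h2", 2, False),
                ("s4", "p3", "c", "h3", 1, False),
                ("s5", "p3", "c", "h3", 2, False),
            ]
        )
        res = run_peacs(M, design, filter_kd=False, impute=False, k=2, iterations=100, seed=0)
        groups = {"p1": [0, 1], "p2": [2, 3], "p3": [4, 5]}
        expected = oracles.brute_force_scores(values, groups, k=2)
        got = res.table.set_index("perturbation")["score"]
        for label, val in expected.items():
            assert got[label] == pytest.approx(val, abs=1e-10)


class TestRunPeacs:
    def test_determinism_same_seed_same_table(self, rng):
        from peacs import null_screen

        M, design, _ = null_screen(n_perturbations=12, n_genes=10, seed=3)
        r1 = run_peacs(M, design, k=2, iterations=300, seed=9, filter_kd=False)
        r2 = run_peacs(M, design, k=2, iterations=300, seed=9, filter_kd=False)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.table.to_csv() == r2.table.to_csv()

    def test_effect_perturbation_ranks_top(self):
        from peacs import generate_screen, generate_state_profiles

        profiles = generate_state_profiles(3, 20, n_marker=2, seed=4)
        M, design, _ = generate_screen(
            profiles,
            n_perturbed=8,
            hairpins_range=(3, 3),
            replicates=2,
            effects={"G01": np.array([0.4, 0.0, 0.0])},
            kd_fold_range=(1.0, 1.0),
            seed=4,
        )
        res = run_peacs(
            M, design, filter_kd=False, k=2, group_by="gene", iterations=500, seed=4
        )
        scored = res.table[res.table["n_replicates"] >= 2]
        scored = scored[scored["perturbation"] != "none"]  # pooled controls
        assert scored.iloc[0]["perturbation"] == "G01"

    def test_metadata_records_k_source(self, small_screen):
        M, design = small_screen
        res = run_peacs(M, design, filter_kd=False, k=2, iterations=100, seed=0)
        assert res.metadata["k"] == 2 and res.metadata["k_source"] == "user"
        res_auto = run_peacs(M, design, filter_kd=False, k="auto", iterations=100, seed=0)
        assert res_auto.metadata["k_source"] == "elbow"
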