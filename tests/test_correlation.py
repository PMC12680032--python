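import numpy as np
import pytest
from scipy.stats import spearmanr

from smrlink.correlation import (
    QCConfig,
    combined_rank,
    exclude_model_specific_genes,
    log_normalize,
    permutation_ci,
    qc_filter_cells,
    rho_to_z,
    select_top,
    spearman_vs_biophys,
)
from smrlink.io import CountMatrix


def toy_matrix(counts, mito=()):
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    for i in mito:
        genes[i] = f"MT-{i}"
    return CountMatrix(
        genes=genes,
        cells=[f"c{j}" for j in range(counts.shape[1])],
        counts=counts,
        mito_genes=[g for g in genes if g.startswith("MT-")],
    )


class TestQC:
    def test_read_count_boundary_is_strict_below_1000(self):
        # cells with totals 999 / 1000 / 1001, no mito reads
        m = toy_matrix(np.array([[999, 1000, 1001]]))
        kept, report = qc_filter_cells(m)
        assert kept.cells == ["c1", "c2"]
        assert report["cell_id"].tolist() == ["c0"]
        assert report["reason"].tolist() == ["low_reads"]

    def test_mito_boundary_is_strict_above_20_percent(self):
        # 5000-read cells with 21% and exactly 20% mitochondrial reads
        counts = np.array([[1050, 1000], [3950, 4000]])
        m = toy_matrix(counts, mito=[0])
        kept, report = qc_filter_cells(m)
        assert kept.cells == ["c1"]
        assert report["reason"].tolist() == ["high_mito"]

    def test_cell_at_both_limits_retained(self):
        # exactly 1000 reads, exactly 20% mito: passes both strict gates
        m = toy_matrix(np.array([[200], [800]]), mito=[0])
        kept, _ = qc_filter_cells(m)
        assert kept.cells == ["c0"]

    def test_idempotent(self):
        m = toy_matrix(np.array([[999, 2000, 1500], [0, 0, 600]]))
        once, _ = qc_filter_cells(m)
        twice, _ = qc_filter_cells(once)
        assert once.cells == twice.cells
        assert np.array_equal(once.counts, twice.counts)

    def test_all_removed_is_error(self):
        with pytest.raises(ValueError, match="every cell"):
            qc_filter_cells(toy_matrix(np.array([[5]])))


class TestLogNormalize:
    def test_hand_value(self):
        # cell total 10000, gene count 100 -> ln(101)
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 100
        counts[1, 0] = 9900
        norm = log_normalize(toy_matrix(counts))
        assert norm[0, 0] == pytest.approx(np.log(101))
        assert norm[1, 0] == pytest.approx(np.log(1 + 9900))

    def test_zero_count_maps_to_zero(self):
        norm = log_normalize(toy_matrix(np.array([[0, 5], [10, 5]])))
        assert norm[0, 0] == 0.0

    def test_compositional_invariance(self):
        a = toy_matrix(np.array([[3, 1], [7, 9]]))
        b = toy_matrix(np.array([[6, 1], [14, 9]]))  # first cell doubled
        np.testing.assert_allclose(log_normalize(a)[:, 0], log_normalize(b)[:, 0])

    def test_zero_total_cell_directs_to_qc(self):
        with pytest.raises(ValueError, match="qc"):
            log_normalize(toy_matrix(np.array([[0], [0]])))


class TestModelSpecificExclusion:
    def test_gene_failing_one_model_excluded(self):
        # 20 cells per model; gene0 expressed 50%/50%/5%, gene1 everywhere
        counts = np.zeros((2, 60), dtype=int)
        counts[0, :10] = 1  # model A: 50%
        counts[0, 20:30] = 1  # model B: 50%
        counts[0, 40] = 1  # model C: 5%
        counts[1, :] = 1
        models = np.repeat(["A", "B", "C"], 20)
        keep, report = exclude_model_specific_genes(toy_matrix(counts), models)
        assert keep.tolist() == [False, True]
        assert report["min_expressing_fraction"].tolist() == [0.05, 1.0]

    def test_boundary_exactly_10_percent_retained(self):
        counts = np.zeros((1, 60), dtype=int)
        counts[0, [0, 1, 20, 21, 40, 41]] = 1  # 2 of 20 in each model
        keep, _ = exclude_model_specific_genes(
            toy_matrix(counts), np.repeat(["A", "B", "C"], 20)
        )
        assert keep.tolist() == [True]

    def test_silent_gene_excluded_and_permutation_commutes(self, rng):
        counts = rng.integers(0, 5, (10, 30))
        counts[3] = 0
        models = np.repeat(["A", "B", "C"], 10)
        keep, _ = exclude_model_specific_genes(toy_matrix(counts), models)
        assert not keep[3]
        perm = rng.permutation(30)
        keep_p, _ = exclude_model_specific_genes(
            toy_matrix(counts[:, perm]), models[perm]
        )
        assert keep.tolist() == keep_p.tolist()

    def test_label_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="per cell"):
            exclude_model_specific_genes(toy_matrix(np.ones((1, 2), dtype=int)), ["A"])


class TestSpearman:
    def test_monotone_gives_plus_minus_one(self):
        mass = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        norm = np.vstack([np.exp(mass), -(mass**3)])
        rho = spearman_vs_biophys(norm, mass)
        np.testing.assert_allclose(rho, [1.0, -1.0], atol=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        expr = rng.integers(0, 4, (5, 40)).astype(float)  # heavy ties
        mass = rng.normal(size=40)
        rho = spearman_vs_biophys(expr, mass)
        expected = [spearmanr(expr[g], mass).statistic for g in range(5)]
        np.testing.assert_allclose(rho, expected, atol=1e-12)

    def test_constant_gene_is_nan(self, rng):
        expr = np.vstack([np.ones(10), rng.normal(size=10)])
        rho = spearman_vs_biophys(expr, rng.normal(size=10))
        assert np.isnan(rho[0]) and np.isfinite(rho[1])

    def test_monotone_transform_invariance(self, rng):
        expr = rng.lognormal(0, 1, (4, 50))
        mass = rng.lognormal(4, 0.3, 50)
        base = spearman_vs_biophys(expr, mass)
        np.testing.assert_allclose(
            spearman_vs_biophys(np.log1p(expr), mass**2), base, atol=1e-12
        )

    def test_null_mean_rho_near_zero(self, rng):
        expr = rng.poisson(5, (1000, 500)).astype(float)
        rho = spearman_vs_biophys(expr, rng.normal(size=500))
        assert abs(np.nanmean(rho)) < 0.01

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError):
            spearman_vs_biophys(np.ones((2, 2)), [1.0, 2.0])


class TestZScoresAndSelection:
    def test_hand_standardization(self):
        z = rho_to_z(np.array([-0.1, 0.0, 0.1]))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_location_invariance_and_moments(self, rng):
        rhos = rng.uniform(-0.5, 0.5, 100)
        z = rho_to_z(rhos)
        np.testing.assert_allclose(rho_to_z(rhos + 0.2), z, atol=1e-9)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, rel=1e-12)

    def test_fisher_variant_preserves_order(self, rng):
        rhos = rng.uniform(-0.9, 0.9, 50)
        z_c, z_f = rho_to_z(rhos), rho_to_z(rhos, method="fisher")
        assert np.array_equal(np.argsort(z_c), np.argsort(z_f))

    def test_selection_strict_and_sorted(self):
        genes = ["a", "b", "c", "d"]
        z = np.array([2.5, 3.0, np.nan, 4.0])
        assert select_top(z, genes) == ["d", "b"]  # 2.5 exactly is excluded
        assert select_top(np.array([0.0, 1.0, 2.0, 2.5]), genes) == []

    def test_degenerate_rhos_error(self):
        with pytest.raises(ValueError):
            rho_to_z(np.array([0.3, 0.3, 0.3]))


class TestCombinedRank:
    def test_average_beats_extreme(self):
        df = combined_rank([3.0, 4.0], [3.0, 1.0], ["even", "spiky"])
        assert df.set_index("gene").loc["even", "rank_combined"] == 1

    def test_symmetric_in_the_two_covariates(self, rng):
        zm, zs = rng.normal(size=20), rng.normal(size=20)
        genes = [f"g{i}" for i in range(20)]
        r1 = combined_rank(zm, zs, genes)["rank_combined"]
        r2 = combined_rank(zs, zm, genes)["rank_combined"]
        assert r1.tolist() == r2.tolist()

    def test_rank_is_permutation_and_ties_lexicographic(self):
        df = combined_rank([1.0, 1.0, 0.0], [1.0, 1.0, 0.0], ["b", "a", "c"])
        assert sorted(df["rank_combined"]) == [1, 2, 3]
        by_gene = df.set_index("gene")["rank_combined"]
        assert by_gene["a"] < by_gene["b"]


class TestPermutationCI:
    def test_deterministic_for_fixed_seed(self, rng):
        expr = rng.poisson(4, (50, 60)).astype(float)
        mass = rng.normal(size=60)
        b1 = permutation_ci(expr, mass, n_iter=200, seed=3)
        b2 = permutation_ci(expr, mass, n_iter=200, seed=3)
        np.testing.assert_array_equal(b1, b2)
        assert not np.array_equal(b1, permutation_ci(expr, mass, n_iter=200, seed=4))

    def test_constant_biophys_is_error(self, rng):
        with pytest.raises(ValueError, match="constant"):
            permutation_ci(rng.poisson(4, (5, 30)).astype(float), np.ones(30), n_iter=200)

    def test_small_n_iter_rejected(self, rng):
        with pytest.raises(ValueError, match="n_iter"):
            permutation_ci(rng.poisson(4, (5, 30)).astype(float), rng.normal(size=30), n_iter=50)

    def test_bounds_are_positive_upper_quantiles(self, rng):
        expr = rng.poisson(4, (100, 80)).astype(float)
        mass = rng.normal(size=80)
        bounds = permutation_ci(expr, mass, n_iter=500, seed=0)
        # the signed 95th percentile of a symmetric null sits near +1.645/sqrt(n)
        assert np.all(bounds > 0)
        assert np.median(bounds) == pytest.approx(1.645 / np.sqrt(79), rel=0.25)
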