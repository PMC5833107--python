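import numpy as np
import pandas as pd
import pytest

from taxafun.containers import GenomeContentMatrix, TaxonomicProfile, ValidationError
from taxafun.gdf import (
    average_functional_redundancy,
    average_functional_similarity,
    functional_redundancy,
    functional_similarity,
    gdf_pca,
    gdf_table,
    gdf_vector,
    genome_size_features,
    unique_function_abundance,
)


def profile(taxa, abunds):
    return TaxonomicProfile(np.array(taxa, dtype=object),
                            np.array(abunds, dtype=float))


def content(rows, taxa, functions):
    return GenomeContentMatrix(
        pd.DataFrame(np.asarray(rows, dtype=float), index=taxa,
                     columns=functions))


class TestFunctionalRedundancy:
    def test_single_encoder_is_zero(self):
        c = content([[1, 1], [0, 1]], ["A", "B"], ["F1", "F2"])
        p = profile(["A", "B"], [0.5, 0.5])
        assert functional_redundancy("F1", p, c) == pytest.approx(0.0)

    def test_equal_contributions_ln2(self):
        c = content([[1], [1]], ["A", "B"], ["F1"])
        p = profile(["A", "B"], [0.5, 0.5])
        assert functional_redundancy("F1", p, c) == pytest.approx(np.log(2))

    def test_uneven_contributions_hand_entropy(self):
        # contributions 0.75/0.25: -(0.75 ln 0.75 + 0.25 ln 0.25) ≈ 0.5623
        c = content([[3], [1]], ["A", "B"], ["F1"])
        p = profile(["A", "B"], [0.5, 0.5])
        assert functional_redundancy("F1", p, c) == pytest.approx(0.562335,
                                                                  abs=1e-5)

    def test_literal_mode_unnormalized_formula(self):
        c = content([[1], [1]], ["A", "B"], ["F1"])
        p = profile(["A", "B"], [0.5, 0.5])
        expected = -2 * 0.5 * np.log(0.5)
        assert functional_redundancy("F1", p, c,
                                     mode="literal") == pytest.approx(expected)

    def test_bounded_by_log_n_encoders(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(2, 8)
            c = content(rng.integers(1, 4, size=(n, 1)),
                        [f"T{i}" for i in range(n)], ["F1"])
            p = profile([f"T{i}" for i in range(n)], rng.dirichlet(np.ones(n)))
            r = functional_redundancy("F1", p, c)
            assert 0.0 <= r <= np.log(n) + 1e-12


class TestAverageRedundancy:
    def test_all_singleton_functions_zero(self):
        c = content([[1, 0], [0, 1]], ["A", "B"], ["F1", "F2"])
        p = profile(["A", "B"], [0.5, 0.5])
        assert average_functional_redundancy(p, c) == pytest.approx(0.0)

    def test_identical_genomes_ln_k(self):
        k = 4
        c = content([[2, 1]] * k, [f"T{i}" for i in range(k)], ["F1", "F2"])
        p = profile([f"T{i}" for i in range(k)], np.full(k, 1 / k))
        assert average_functional_redundancy(p, c) == pytest.approx(np.log(k))

    def test_abundance_weighting_of_functions(self):
        # F1 shared evenly (redundancy ln2), F2 private (0); doubling F2's
        # copy number shifts weight toward redundancy 0
        c1 = content([[1, 1], [1, 0]], ["A", "B"], ["F1", "F2"])
        c2 = content([[1, 2], [1, 0]], ["A", "B"], ["F1", "F2"])
        p = profile(["A", "B"], [0.5, 0.5])
        assert average_functional_redundancy(p, c2) < \
            average_functional_redundancy(p, c1)
        # hand check for c1: weights F1=2/3, F2=1/3 of total abundance 1.5
        expected = (1.0 * np.log(2) + 0.5 * 0.0) / 1.5
        assert average_functional_redundancy(p, c1) == pytest.approx(expected)


class TestFunctionalSimilarity:
    def test_identical_genomes_one(self):
        assert functional_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_disjoint_genomes_zero(self):
        assert functional_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert functional_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(
            1 / np.sqrt(2))

    def test_community_average_over_unordered_pairs(self):
        c = content([[1, 0], [0, 1], [1, 1]], ["A", "B", "C"], ["F1", "F2"])
        p = profile(["A", "B", "C"], [0.2, 0.3, 0.5])
        expected = (0.0 + 1 / np.sqrt(2) + 1 / np.sqrt(2)) / 3
        assert average_functional_similarity(p, c) == pytest.approx(expected)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValidationError):
            functional_similarity([0, 0], [1, 0])


class TestGenomeSize:
    def test_no_variation(self):
        c = content([[2, 2], [1, 3]], ["A", "B"], ["F1", "F2"])
        p = profile(["A", "B"], [0.9, 0.1])
        avg, cv = genome_size_features(p, c)
        assert avg == pytest.approx(4.0)
        assert cv == pytest.approx(0.0)

    def test_population_cv(self):
        c = content([[2, 0], [3, 3]], ["A", "B"], ["F1", "F2"])
        p = profile(["A", "B"], [0.5, 0.5])
        avg, cv = genome_size_features(p, c)
        assert avg == pytest.approx(4.0)
        assert cv == pytest.approx(0.5)  # population SD 2 over mean 4

    def test_unweighted_by_abundance(self):
        c = content([[2, 0], [3, 3]], ["A", "B"], ["F1", "F2"])
        for abunds in ([0.5, 0.5], [0.99, 0.01]):
            avg, _ = genome_size_features(profile(["A", "B"], abunds), c)
            assert avg == pytest.approx(4.0)

    def test_single_species_cv_undefined(self):
        c = content([[2, 2]], ["A"], ["F1", "F2"])
        with pytest.warns(UserWarning, match="variability"):
            _, cv = genome_size_features(profile(["A"], [1.0]), c)
        assert np.isnan(cv)


class TestUniqueFunctionAbundance:
    def test_no_unique_functions(self):
        c = content([[1, 1], [1, 1]], ["A", "B"], ["F1", "F2"])
        p = profile(["A", "B"], [0.5, 0.5])
        assert unique_function_abundance(p, c) == pytest.approx(0.0)

    def test_hand_construction(self):
        # F1 only in A with functional abundance 0.6; F2 shared with 0.4
        c = content([[3, 1], [0, 3]], ["A", "B"], ["F1", "F2"])
        p = profile(["A", "B"], [0.4, 0.6])
        # functional profile: F1 = 0.4*3 = 1.2, F2 = 0.4*1 + 0.6*3 = 2.2
        expected = 1.2 / (1.2 + 2.2)
        assert unique_function_abundance(p, c) == pytest.approx(expected)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n, m = rng.integers(2, 6), rng.integers(2, 10)
            mat = rng.integers(0, 3, size=(n, m))
            mat[:, 0] = 1  # keep profile non-zero
            c = content(mat, [f"T{i}" for i in range(n)],
                        [f"F{j}" for j in range(m)])
            p = profile([f"T{i}" for i in range(n)], rng.dirichlet(np.ones(n)))
            assert 0.0 <= unique_function_abundance(p, c) <= 1.0


class TestGdfPca:
    @pytest.fixture
    def table(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 3))
        df = pd.DataFrame(base, columns=["redundancy", "similarity", "size"])
        df["size_cv"] = df["size"] * 2 + 1  # perfectly correlated pair
        df["unique"] = rng.normal(size=20)
        return df

    def test_explained_variance_sums_to_one(self, table):
        _, _, explained = gdf_pca(table)
        assert explained.sum() == pytest.approx(1.0)

    def test_scores_centered(self, table):
        scores, _, _ = gdf_pca(table)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-12)

    def test_correlated_columns_share_pc(self, table):
        _, loadings, _ = gdf_pca(table)
        l1 = loadings.loc["size", "PC1"]
        l2 = loadings.loc["size_cv", "PC1"]
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_constant_column_dropped_with_warning(self, table):
        table = table.copy()
        table["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            _, loadings, _ = gdf_pca(table)
        assert "const" not in loadings.index

    def test_requires_three_communities(self, table):
        with pytest.raises(ValidationError):
            gdf_pca(table.iloc[:2])


def test_gdf_vector_and_table_consistent(small_profile, small_content):
    v = gdf_vector(small_profile, small_content)
    table = gdf_table({"c1": small_profile}, small_content)
    pd.testing.assert_series_equal(table.loc["c1"], v.to_series(),
                                   check_names=False)
    assert 0.0 <= v.avg_functional_similarity <= 1.0
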