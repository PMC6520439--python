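"""Profile matrices, fold change, CLR, PCA and clustering, each against an
independent oracle."""

import numpy as np
import pandas as pd
import pytest

from metacaz.abundance import AbundanceProfile
from metacaz.cazyme import ECAssignment
from metacaz.datasets import table1_matrix
from metacaz.errors import DataError, DegenerateInputError
from metacaz.profiles import (
    clr,
    enzyme_profile,
    fold_change,
    hclust_profiles,
    pca,
    taxon_enzyme_profile,
)
from metacaz.taxonomy import UNCLASSIFIED


@pytest.fixture
def abundance():
    return AbundanceProfile(
        "s", pd.Series({"c1": 2.1e-4, "c2": 0.5 - 2.1e-4, "c3": 0.5})
    )


class TestEnzymeProfile:
    def test_single_gene_cell_is_scaled_contig_abundance(self, abundance):
        row = enzyme_profile([ECAssignment("c1_1", "3.2.1.14", 2)], abundance)
        assert row["3.2.1.14"] == pytest.approx(210.0)

    def test_absent_enzyme_reported_as_zero(self, abundance):
        row = enzyme_profile(
            [ECAssignment("c1_1", "3.2.1.14", 2)], abundance,
            enzymes=["3.2.1.14", "3.2.1.4"],
        )
        assert row["3.2.1.4"] == 0.0

    def test_multiple_genes_on_one_contig_count_each(self, abundance):
        assignments = [
            ECAssignment("c1_1", "3.2.1.14", 2), ECAssignment("c1_2", "3.2.1.14", 2)
        ]
        row = enzyme_profile(assignments, abundance)
        assert row["3.2.1.14"] == pytest.approx(420.0)

    def test_unknown_contig_is_data_error(self, abundance):
        with pytest.raises(DataError, match="c9"):
            enzyme_profile([ECAssignment("c9_1", "3.2.1.14", 2)], abundance)

    def test_matches_bruteforce_join(self, rng, abundance):
        ecs = ["3.2.1.14", "3.2.1.4", "3.2.1.8"]
        assignments = [
            ECAssignment(f"c{int(rng.integers(1, 4))}_{i}", str(rng.choice(ecs)), 2)
            for i in range(60)
        ]
        row = enzyme_profile(assignments, abundance)
        for ec in ecs:
            expected = 1e6 * sum(
                abundance.abundances[a.gene_id.rsplit("_", 1)[0]]
                for a in assignments
                if a.ec == ec
            )
            assert row[ec] == pytest.approx(expected)


class TestTaxonEnzymeProfile:
    def test_single_source_mass_in_one_row(self, small_tree, abundance):
        matrix = taxon_enzyme_profile(
            [ECAssignment("c1_1", "3.2.1.14", 2)],
            {"c1": "14"}, small_tree, abundance, rank="order",
        )
        assert matrix.loc["12", "3.2.1.14"] == pytest.approx(210.0)

    def test_unclassified_contigs_pool(self, small_tree, abundance):
        matrix = taxon_enzyme_profile(
            [ECAssignment("c1_1", "3.2.1.14", 2)],
            {}, small_tree, abundance, rank="order",
        )
        assert matrix.loc[UNCLASSIFIED, "3.2.1.14"] == pytest.approx(210.0)

    def test_column_sums_equal_enzyme_profile(self, small_tree, rng, abundance):
        ecs = ["3.2.1.14", "3.2.1.4"]
        assignments = [
            ECAssignment(f"c{int(rng.integers(1, 4))}_{i}", str(rng.choice(ecs)), 2)
            for i in range(40)
        ]
        taxa = {"c1": "14", "c2": "24", "c3": UNCLASSIFIED}
        matrix = taxon_enzyme_profile(
            assignments, taxa, small_tree, abundance, rank="order", enzymes=ecs
        )
        row = enzyme_profile(assignments, abundance, enzymes=ecs)
        assert np.allclose(matrix.sum(axis=0), row)


class TestFoldChange:
    def test_all_equal_column_gives_ratio_one_log_zero(self):
        m = pd.DataFrame({"e": [3.0, 3.0, 3.0]}, index=list("abc"))
        fc = fold_change(m)
        assert np.allclose(fc.ratio["e"], 1.0)
        assert np.allclose(fc.log2["e"], 0.0)

    def test_row_equal_to_column_mean_maps_to_zero(self):
        m = pd.DataFrame({"e": [1.0, 2.0, 3.0], "f": [2.0, 4.0, 6.0]}, index=list("abc"))
        fc = fold_change(m)
        assert fc.ratio.loc["b", "e"] == pytest.approx(1.0)
        assert fc.log2.loc["b", "f"] == pytest.approx(0.0)

    def test_zero_cell_positive_mean_is_minus_inf_sentinel(self):
        m = pd.DataFrame({"e": [0.0, 2.0]}, index=list("ab"))
        fc = fold_change(m)
        assert fc.ratio.loc["a", "e"] == 0.0
        assert fc.log2.loc["a", "e"] == -np.inf
        assert fc.display(floor=-10.0).loc["a", "e"] == -10.0

    def test_all_zero_column_dropped_with_warning(self):
        m = pd.DataFrame({"e": [0.0, 0.0], "f": [1.0, 2.0]}, index=list("ab"))
        with pytest.warns(UserWarning, match="all-zero"):
            fc = fold_change(m)
        assert fc.dropped_columns == ("e",)
        assert list(fc.ratio.columns) == ["f"]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fold_change(pd.DataFrame({"e": [1.0]}))

    def test_full_table_equals_cellwise_recomputation(self):
        matrix = table1_matrix()
        with pytest.warns(UserWarning):
            fc = fold_change(matrix)
        for col in fc.ratio.columns:
            mean = sum(matrix[col]) / len(matrix)
            for row in matrix.index:
                assert fc.ratio.loc[row, col] == pytest.approx(matrix.loc[row, col] / mean)


class TestCLR:
    def test_uniform_row_maps_to_zeros(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["a"], columns=list("wxyz"))
        m = pd.concat([m, m])
        assert np.allclose(clr(m), 0.0)

    def test_rows_sum_to_zero(self, rng):
        m = pd.DataFrame(rng.uniform(0.1, 10, size=(6, 12)))
        out = clr(m)
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_matches_formula_oracle(self, rng):
        m = pd.DataFrame(rng.uniform(0.1, 10, size=(5, 8)))
        out = clr(m)
        for i in range(5):
            x = m.iloc[i].to_numpy()
            x = x / x.sum()
            expected = np.log(x) - np.log(x).mean()
            assert np.allclose(out.iloc[i], expected)

    def test_matches_skbio_on_positive_compositions(self, rng):
        composition = pytest.importorskip("skbio.stats.composition")
        m = pd.DataFrame(rng.uniform(0.5, 5, size=(4, 9)))
        assert np.allclose(clr(m), composition.clr(m.to_numpy() / m.to_numpy().sum(axis=1, keepdims=True)))

    def test_zero_replacement_keeps_rows_closed_and_centered(self, rng):
        m = pd.DataFrame(rng.uniform(0.0, 5, size=(6, 10)))
        m.iloc[0, 0] = 0.0
        out = clr(m)
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_all_zero_row_degenerate(self):
        m = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["bad", "ok"])
        with pytest.raises(DegenerateInputError, match="bad"):
            clr(m)


class TestPCA:
    def test_identical_rows_have_identical_scores(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [4.0, 0.0, 1.0]], index=list("abc")
        )
        result = pca(m, n_components=2)
        assert np.allclose(result.scores.loc["a"], result.scores.loc["b"])

    def test_full_rank_reconstruction(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 4)))
        k = min(m.shape)
        result = pca(m, n_components=k)
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
        centered = m.to_numpy() - m.to_numpy().mean(axis=0)
        assert np.allclose(recon, centered, atol=1e-8)

    def test_explained_variance_matches_covariance_eigenvalues(self, rng):
        m = pd.DataFrame(rng.normal(size=(9, 20)))
        result = pca(m, n_components=5)
        centered = m.to_numpy() - m.to_numpy().mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(centered.T @ centered))[::-1]
        expected = eigvals[:5] / eigvals.sum()
        assert np.allclose(result.explained_variance_ratio, expected, atol=1e-10)
        assert (np.diff(result.explained_variance_ratio) <= 1e-12).all()
        assert result.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_matches_sklearn_up_to_sign_convention(self, rng):
        sk = pytest.importorskip("sklearn.decomposition")
        m = pd.DataFrame(rng.normal(size=(8, 5)))
        ours = pca(m, n_components=3)
        theirs = sk.PCA(n_components=3).fit_transform(m.to_numpy())
        assert np.allclose(np.abs(ours.scores.to_numpy()), np.abs(theirs), atol=1e-8)

    def test_excess_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca(pd.DataFrame(rng.normal(size=(3, 4))), n_components=4)


def naive_average_linkage(points):
    """Independent agglomeration oracle: merge the closest pair of clusters,
    average-linkage distance recomputed from scratch each round."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean(
                    [
                        np.linalg.norm(points[a] - points[b])
                        for a in clusters[i]
                        for b in clusters[j]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return np.array(heights)


class TestHclust:
    def test_two_rows_merge_at_their_distance(self):
        m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        result = hclust_profiles(m)
        assert result.merge_heights() == pytest.approx([5.0])

    def test_coincident_pair_merges_first_at_zero(self):
        m = pd.DataFrame([[1.0, 1.0], [5.0, 5.0], [1.0, 1.0]], index=list("abc"))
        result = hclust_profiles(m)
        assert result.merge_heights()[0] == pytest.approx(0.0)
        assert set(result.linkage[0, :2].astype(int)) == {0, 2}

    def test_merge_heights_match_naive_agglomeration(self, rng):
        points = rng.normal(size=(9, 6))
        m = pd.DataFrame(points, index=[f"r{i}" for i in range(9)])
        result = hclust_profiles(m)
        assert np.allclose(
            np.sort(result.merge_heights()), np.sort(naive_average_linkage(points)),
            atol=1e-10,
        )

    def test_leaf_order_stable(self, rng):
        points = rng.normal(size=(7, 4))
        m = pd.DataFrame(points, index=[f"r{i}" for i in range(7)])
        assert hclust_profiles(m).leaf_order == hclust_profiles(m).leaf_order
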