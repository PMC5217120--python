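"""Spearman matrices, sample clustering, and the variability contrast."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exorna import (
    cluster_samples,
    compare_within_compartment_variability,
    spearman_matrix,
)
from exorna.variability import cut_two_clusters, dendrogram_newick


def _expr(values, samples=None):
    arr = np.asarray(values, dtype=float)
    cols = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


class TestSpearman:
    def test_reversed_ranking_gives_minus_one(self):
        x = np.arange(10.0)
        rho = spearman_matrix(_expr(np.column_stack([x, x[::-1]])))
        assert rho.iloc[0, 1] == pytest.approx(-1.0)

    def test_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        rho = spearman_matrix(_expr(rng.random((20, 5))))
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.random((30, 6))
        rho = spearman_matrix(_expr(data))
        ranks = np.apply_along_axis(stats.rankdata, 0, data)
        expected = np.corrcoef(ranks.T)
        np.testing.assert_allclose(rho.to_numpy(), expected, atol=1e-12)

    def test_constant_sample_flagged_na(self):
        data = np.column_stack([np.arange(5.0), np.ones(5)])
        rho = spearman_matrix(_expr(data))
        assert np.isnan(rho.iloc[0, 1])
        assert rho.iloc[0, 0] == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.random((25, 4)) + 0.1
        rho1 = spearman_matrix(_expr(data))
        transformed = data.copy()
        transformed[:, 0] = np.exp(3 * transformed[:, 0])  # strictly monotone
        transformed[:, 1] *= 17.0  # per-sample scaling
        rho2 = spearman_matrix(_expr(transformed))
        np.testing.assert_allclose(rho1.to_numpy(), rho2.to_numpy(), atol=1e-12)


class TestClustering:
    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(3)
        base_a = rng.random(50) * 10
        base_b = rng.random(50) * 10
        cols = {}
        for i in range(4):
            cols[f"a{i}"] = base_a + 0.01 * rng.standard_normal(50)
        for i in range(4):
            cols[f"b{i}"] = base_b + 0.01 * rng.standard_normal(50)
        expr = pd.DataFrame(cols)
        rho = spearman_matrix(expr)
        linkage, leaves = cluster_samples(rho)
        membership = cut_two_clusters(linkage, list(rho.index))
        groups = {}
        for s, g in membership.items():
            groups.setdefault(g, set()).add(s[0])
        assert sorted(map(sorted, groups.values())) == [["a"], ["b"]]

    def test_identical_samples_merge_at_zero_height(self):
        expr = _expr(np.column_stack([np.arange(10.0)] * 3))
        rho = spearman_matrix(expr)
        linkage, _ = cluster_samples(rho)
        np.testing.assert_allclose(linkage[:, 2], 0.0, atol=1e-12)

    def test_sample_order_permutation_leaves_heights_unchanged(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.random((40, 6)))
        rho = spearman_matrix(expr)
        l1, _ = cluster_samples(rho)
        perm = list(rng.permutation(rho.index))
        l2, _ = cluster_samples(rho.loc[perm, perm])
        np.testing.assert_allclose(np.sort(l1[:, 2]), np.sort(l2[:, 2]), atol=1e-12)

    def test_na_entries_rejected(self):
        rho = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        rho.iloc[0, 1] = np.nan
        with pytest.raises(ValueError, match="remove samples"):
            cluster_samples(rho)

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(5)
        expr = _expr(rng.random((30, 5)))
        rho = spearman_matrix(expr)
        linkage, _ = cluster_samples(rho)
        nwk = dendrogram_newick(linkage, list(rho.index))
        assert nwk.endswith(";")
        for s in rho.index:
            assert s in nwk


class TestVariabilityComparison:
    def _corr_from_groups(self, n_per_group, noise_cell, noise_exo, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.random(80) * 10
        cols, ids, comps = {}, [], []
        for i in range(n_per_group):
            cols[f"i{i}_cell"] = base + noise_cell * rng.standard_normal(80)
            ids.append(f"i{i}")
            comps.append("cell")
        for i in range(n_per_group):
            cols[f"i{i}_exosome"] = base + noise_exo * rng.standard_normal(80)
            ids.append(f"i{i}")
            comps.append("exosome")
        expr = pd.DataFrame(cols)
        samples = pd.DataFrame(
            {"individual": ids, "compartment": comps}, index=list(cols)
        )
        return spearman_matrix(expr), samples

    def test_pair_counts_for_17_samples(self):
        rho, samples = self._corr_from_groups(17, 1.0, 2.0)
        res = compare_within_compartment_variability(rho, samples)
        assert res.n_cell_pairs == 136 and res.n_exosome_pairs == 136

    def test_noisier_exosomes_give_lower_rho(self):
        rho, samples = self._corr_from_groups(10, 0.5, 3.0, seed=1)
        res = compare_within_compartment_variability(rho, samples)
        assert res.mean_within_exosome < res.mean_within_cell
        assert res.pvalue < 0.01

    def test_exact_small_sample_rank_sum(self):
        """Fully separated groups of 3 pairs each: exact two-sided p = 2/C(6,3).

        Three samples per compartment give three within-pairs per group; with
        the cell values {0.1, 0.2, 0.3} all below the exosome values
        {0.4, 0.5, 0.6}, enumeration of the 20 equally likely rank splits
        gives a one-sided p of 1/20, doubled to 0.1.
        """
        ids = ["a_cell", "b_cell", "c_cell", "a_exo", "b_exo", "c_exo"]
        rho = pd.DataFrame(np.eye(6), index=ids, columns=ids)
        for (i, j), v in {(0, 1): 0.1, (0, 2): 0.2, (1, 2): 0.3,
                          (3, 4): 0.4, (3, 5): 0.5, (4, 5): 0.6}.items():
            rho.iloc[i, j] = rho.iloc[j, i] = v
        samples = pd.DataFrame(
            {"individual": ["a", "b", "c"] * 2,
             "compartment": ["cell"] * 3 + ["exosome"] * 3},
            index=ids,
        )
        res = compare_within_compartment_variability(rho, samples)
        assert res.pvalue == pytest.approx(2 / 20)
        assert res.mean_within_cell == pytest.approx(0.2)
        assert res.mean_within_exosome == pytest.approx(0.5)

    def test_null_pvalues_roughly_uniform(self):
        """Equal-noise compartments give uniform comparison p-values."""
        rng = np.random.default_rng(6)
        n = 5
        ids = [f"i{j}_cell" for j in range(n)] + [f"i{j}_exo" for j in range(n)]
        samples = pd.DataFrame(
            {"individual": [f"i{j}" for j in range(n)] * 2,
             "compartment": ["cell"] * n + ["exosome"] * n},
            index=ids,
        )
        iu = np.triu_indices(n, k=1)
        pvals = []
        for _ in range(200):
            rho = pd.DataFrame(np.eye(2 * n), index=ids, columns=ids)
            for block in (0, n):
                vals = rng.uniform(0, 1, size=len(iu[0]))
                for (i, j), v in zip(zip(*iu), vals):
                    rho.iloc[block + i, block + j] = v
                    rho.iloc[block + j, block + i] = v
            res = compare_within_compartment_variability(rho, samples)
            pvals.append(res.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_sample_compartment_rejected(self):
        rho, samples = self._corr_from_groups(2, 1.0, 1.0)
        keep = [s for s in rho.index if s != "i1_exosome"]
        with pytest.raises(ValueError, match=">= 2 samples"):
            compare_within_compartment_variability(
                rho.loc[keep, keep], samples.loc[keep]
            )
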