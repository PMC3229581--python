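"""Spearman distances, complete-linkage clustering, branch enrichment, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, rankdata

from crossmir.multivariate import (
    cut_two_branches,
    enrichment_chi2,
    expression_matrix,
    hierarchical_cluster,
    linkage_to_newick,
    pca,
    rank_loadings,
    spearman_distance_matrix,
    top_loading_overlap,
)
from crossmir.preprocess import preprocess
from conftest import make_ct_matrix


def sample_frame(X, prefix="S"):
    return pd.DataFrame(
        X, index=[f"{prefix}{i}" for i in range(X.shape[0])],
        columns=[f"v{j}" for j in range(X.shape[1])],
    )


class TestSpearmanDistance:
    def test_self_distance_zero_and_symmetry(self, rng):
        expr = sample_frame(rng.normal(size=(5, 8)))
        d = spearman_distance_matrix(expr)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)

    def test_antiranked_samples_at_distance_two(self):
        expr = sample_frame(np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1], [1.0, 3, 2, 4]]))
        d = spearman_distance_matrix(expr)
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        expr = sample_frame(rng.normal(size=(5, 8)))
        d = spearman_distance_matrix(expr)
        R = np.vstack([rankdata(row) for row in expr.to_numpy()])
        oracle = 1.0 - np.corrcoef(R)
        assert np.allclose(d.to_numpy(), oracle, atol=1e-12)

    def test_constant_profile_named_in_error(self, rng):
        X = rng.normal(size=(4, 6))
        X[2] = 3.14
        with pytest.raises(ValueError, match="S2"):
            spearman_distance_matrix(sample_frame(X))


class TestHierarchicalCluster:
    def test_three_point_hand_agglomeration(self):
        d = pd.DataFrame(
            [[0.0, 1.0, 5.0], [1.0, 0.0, 5.0], [5.0, 5.0, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        part = hierarchical_cluster(d)
        Z = part.linkage
        assert Z[0, 2] == pytest.approx(1.0)   # {A,B} merge first at height 1
        assert Z[1, 2] == pytest.approx(5.0)   # complete linkage: final at max dist
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_five_point_complete_linkage_matches_hand_result(self):
        # two tight pairs plus an outlier; complete linkage heights known by hand
        pts = np.array([0.0, 0.1, 1.0, 1.05, 5.0])
        D = np.abs(pts[:, None] - pts[None, :])
        d = pd.DataFrame(D, index=list("abcde"), columns=list("abcde"))
        Z = hierarchical_cluster(d).linkage
        heights = sorted(Z[:, 2])
        assert heights[0] == pytest.approx(0.05)   # {c,d}
        assert heights[1] == pytest.approx(0.1)    # {a,b}
        assert heights[2] == pytest.approx(1.05)   # {a,b,c,d} at max pairwise
        assert heights[3] == pytest.approx(5.0)
        assert all(a <= b for a, b in zip(Z[:, 2], Z[1:, 2]))  # monotone merges

    def test_two_sample_tree_single_merge(self):
        d = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]], index=["x", "y"], columns=["x", "y"])
        part = cut_two_branches(hierarchical_cluster(d))
        assert part.linkage.shape[0] == 1
        assert part.branch_of == {"x": 1, "y": 2}

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["x", "y"], columns=["x", "y"])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(d)

    def test_planted_blocks_recovered_by_two_branch_cut(self, rng):
        n = 12
        D = np.full((n, n), 1.9)
        D[:6, :6] = 0.1
        D[6:, 6:] = 0.1
        np.fill_diagonal(D, 0.0)
        labels = [f"S{i}" for i in range(n)]
        part = cut_two_branches(
            hierarchical_cluster(pd.DataFrame(D, index=labels, columns=labels)))
        b = [part.branch_of[s] for s in labels]
        assert len(set(b[:6])) == 1 and len(set(b[6:])) == 1 and b[0] != b[6]
        assert b[0] == 1  # branch 1 holds the first sample in input order

    def test_branch_labels_stable_under_reordering_up_to_swap(self, rng):
        n = 10
        D = np.full((n, n), 1.5)
        D[:5, :5] = 0.2
        D[5:, 5:] = 0.2
        np.fill_diagonal(D, 0.0)
        labels = [f"S{i}" for i in range(n)]
        d1 = pd.DataFrame(D, index=labels, columns=labels)
        perm = rng.permutation(n)
        d2 = d1.iloc[perm, perm]
        p1 = cut_two_branches(hierarchical_cluster(d1)).branch_of
        p2 = cut_two_branches(hierarchical_cluster(d2)).branch_of
        parts1 = {frozenset(s for s in labels if p1[s] == b) for b in (1, 2)}
        parts2 = {frozenset(s for s in labels if p2[s] == b) for b in (1, 2)}
        assert parts1 == parts2  # same partition up to a branch-label swap

    def test_monotone_transform_invariance_via_spearman(self, rng):
        m = make_ct_matrix(rng.uniform(20, 33, (30, 8)))
        norm = preprocess(m, min_samples=0)
        nrq_expr = expression_matrix(norm, "nrq")
        log_expr = expression_matrix(norm, "log2_nrq")
        Z1 = hierarchical_cluster(spearman_distance_matrix(nrq_expr)).linkage
        Z2 = hierarchical_cluster(spearman_distance_matrix(log_expr)).linkage
        assert np.allclose(Z1, Z2)

    def test_newick_contains_all_samples(self, rng):
        expr = sample_frame(rng.normal(size=(6, 9)))
        part = cut_two_branches(hierarchical_cluster(spearman_distance_matrix(expr)))
        nwk = linkage_to_newick(part)
        assert nwk.endswith(";")
        for s in expr.index:
            assert s in nwk


class TestEnrichmentChi2:
    @staticmethod
    def partition_from(branches: dict[str, int]):
        from crossmir.multivariate import ClusterPartition
        return ClusterPartition(linkage=np.empty((0, 4)),
                                sample_ids=list(branches), branch_of=dict(branches))

    def test_perfect_separation_table(self):
        branches = {f"S{i}": (1 if i < 10 else 2) for i in range(20)}
        labels = {f"S{i}": ("MNA" if i < 10 else "non-MNA") for i in range(20)}
        res = enrichment_chi2(self.partition_from(branches), labels)
        assert res.chi2 == pytest.approx(20.0)  # Pearson on [[10,0],[0,10]]
        assert res.enriched_branch == 1

    def test_identical_proportions_give_zero(self):
        branches = {f"S{i}": (1 if i < 10 else 2) for i in range(20)}
        labels = {f"S{i}": ("a" if i % 2 == 0 else "b") for i in range(20)}
        assert enrichment_chi2(self.partition_from(branches), labels).chi2 == \
            pytest.approx(0.0)

    def test_mean_statistic_near_one_under_independence(self, rng):
        # chi-square with 1 df has expectation 1 under the null
        stats = []
        branches = {f"S{i}": (1 if i < 15 else 2) for i in range(30)}
        part = self.partition_from(branches)
        for _ in range(400):
            lab = rng.permutation(["a"] * 15 + ["b"] * 15)
            labels = {f"S{i}": lab[i] for i in range(30)}
            try:
                stats.append(enrichment_chi2(part, labels).chi2)
            except ValueError:
                continue
        assert np.mean(stats) == pytest.approx(1.0, abs=0.2)

    def test_matches_scipy_without_correction(self, rng):
        branches = {f"S{i}": (1 if i < 12 else 2) for i in range(30)}
        lab = rng.permutation(["a"] * 18 + ["b"] * 12)
        labels = {f"S{i}": lab[i] for i in range(30)}
        res = enrichment_chi2(self.partition_from(branches), labels)
        chi2, p, _, _ = chi2_contingency(res.table.to_numpy(), correction=False)
        assert res.chi2 == pytest.approx(chi2)
        assert res.p_value == pytest.approx(p)

    def test_yates_correction_reduces_statistic(self):
        branches = {f"S{i}": (1 if i < 10 else 2) for i in range(20)}
        labels = {f"S{i}": ("a" if i < 8 or i >= 17 else "b") for i in range(20)}
        part = self.partition_from(branches)
        assert enrichment_chi2(part, labels, yates=True).chi2 < \
            enrichment_chi2(part, labels).chi2

    def test_zero_marginal_rejected(self):
        branches = {f"S{i}": (1 if i < 10 else 2) for i in range(20)}
        labels = {f"S{i}": "a" for i in range(20)}
        with pytest.raises(ValueError, match="two classes"):
            enrichment_chi2(self.partition_from(branches), labels)


class TestPca:
    def test_collinear_variables_single_component(self, rng):
        x = rng.normal(size=10)
        expr = sample_frame(np.column_stack([x, 2 * x + 1]))
        p = pca(expr)
        assert p.explained_var[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self, rng):
        expr = sample_frame(rng.normal(size=(8, 12)))
        p = pca(expr)
        X = expr.to_numpy()
        Xc = X - X.mean(axis=0)
        recon = p.scores.to_numpy() @ p.loadings.to_numpy().T
        assert np.allclose(recon, Xc, atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        p = pca(sample_frame(rng.normal(size=(10, 20))))
        L = p.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_eigenvalues_match_covariance_oracle(self, rng):
        expr = sample_frame(rng.normal(size=(10, 20)))
        p = pca(expr)
        X = expr.to_numpy()
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        eig = eig[eig > 1e-10]
        frac_oracle = eig / eig.sum()
        assert np.allclose(p.explained_var[: len(eig)], frac_oracle, atol=1e-8)

    def test_explained_variance_sums_to_one_and_decreases(self, rng):
        p = pca(sample_frame(rng.normal(size=(9, 5))))
        assert p.explained_var.sum() == pytest.approx(1.0)
        assert all(a >= b - 1e-12 for a, b in zip(p.explained_var,
                                                  p.explained_var[1:]))

    def test_sign_convention(self, rng):
        p = pca(sample_frame(rng.normal(size=(7, 6))))
        for comp in p.loadings.columns:
            col = p.loadings[comp]
            assert col.iloc[int(np.argmax(np.abs(col.to_numpy())))] > 0

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            pca(sample_frame(rng.normal(size=(1, 5))))


class TestRankLoadings:
    def test_sorted_by_absolute_loading(self):
        from crossmir.multivariate import PCAResult
        loadings = pd.DataFrame({"PC1": [0.9, -0.1, 0.05]},
                                index=["var1", "var2", "var3"])
        p = PCAResult(scores=pd.DataFrame(), loadings=loadings,
                      explained_var=np.array([1.0]))
        assert rank_loadings(p, "PC1", 3) == ["var1", "var2", "var3"]

    def test_full_list_is_permutation(self, rng):
        p = pca(sample_frame(rng.normal(size=(8, 10))))
        assert sorted(rank_loadings(p, 1, 10)) == sorted(p.loadings.index)

    def test_matches_sort_oracle_and_overlap_count(self, rng):
        p = pca(sample_frame(rng.normal(size=(9, 15))))
        got = rank_loadings(p, "PC2", 15)
        col = p.loadings["PC2"]
        oracle = [v for v, _ in sorted(col.items(), key=lambda kv: (-abs(kv[1]), kv[0]))]
        assert got == oracle
        k = top_loading_overlap(p, "PC1", "PC2", 5)
        a = set(rank_loadings(p, "PC1", 5))
        b = set(rank_loadings(p, "PC2", 5))
        assert k == len(a & b)

    def test_oversized_top_n_truncates_with_warning(self, rng):
        p = pca(sample_frame(rng.normal(size=(6, 4))))
        with pytest.warns(UserWarning, match="top_n"):
            out = rank_loadings(p, "PC1", 20)
        assert len(out) == 4
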