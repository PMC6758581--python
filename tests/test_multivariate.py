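import inspect

import numpy as np
import pandas as pd
import pytest

from nectarevol import (SyndromeMap, dendrogram_lambda_signal,
                        euclidean_distance_matrix, mantel_test, pca,
                        syndrome_distance_matrix, upgma)
from nectarevol.multivariate import standardize


def _df(rows, cols=None, index=None):
    a = np.asarray(rows, dtype=float)
    return pd.DataFrame(a,
                        columns=cols or [f"v{j}" for j in range(a.shape[1])],
                        index=index or [f"s{i}" for i in range(a.shape[0])])


class TestPCA:
    def test_perfectly_correlated_pair_loads_one_axis(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        res = pca(_df(np.column_stack([x, 3.0 * x + 1.0])))
        assert res.variance_explained.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_columns_share_variance(self):
        rng = np.random.default_rng(1)
        res = pca(_df(rng.normal(size=(5000, 4))))
        assert np.allclose(res.variance_explained, 0.25, atol=0.03)

    def test_matches_eigendecomposition_oracle(self):
        X = _df([[2.0, 1.0, 0.5], [1.0, 3.0, 1.5], [0.0, 1.0, 4.0],
                 [3.0, 0.0, 2.0], [1.5, 2.5, 0.0]])
        res = pca(X, scale=True)
        Z = (X - X.mean()) / X.std(ddof=0)
        R = (Z.T @ Z / len(X)).to_numpy()
        evals = np.sort(np.linalg.eigvalsh(R))[::-1]
        assert np.allclose(res.eigenvalues.to_numpy(), evals, atol=1e-10)
        # scores reproduce projections onto the (sign-fixed) eigenvectors
        proj = Z.to_numpy() @ res.loadings.to_numpy()
        assert np.allclose(res.scores.to_numpy(), proj, atol=1e-10)

    def test_reconstruction(self):
        rng = np.random.default_rng(2)
        X = _df(rng.normal(size=(12, 5)))
        res = pca(X, scale=True)
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        back = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(back, Z, atol=1e-8)

    def test_variance_shares_nonincreasing_sum_to_one(self):
        rng = np.random.default_rng(3)
        res = pca(_df(rng.normal(size=(30, 6))))
        ve = res.variance_explained.to_numpy()
        assert np.all(np.diff(ve) <= 1e-12)
        assert ve.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_column_rejected(self):
        X = _df([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="v1"):
            pca(X, scale=True)


class TestUPGMA:
    def test_hand_computed_example(self):
        D = _df([[0, 2, 4], [2, 0, 4], [4, 4, 0]], index=list("ABC"),
                cols=list("ABC"))
        D.columns = list("ABC")
        t = upgma(D)
        d = t.depths
        i = {l: k for k, l in enumerate(t.tip_labels)}
        # A and B join at height 1, C at height 2
        hts = sorted(t.crown_age - d[t.n_tips:])
        assert hts == pytest.approx([1.0, 2.0])
        C = t.shared_depth_matrix()
        assert t.crown_age - C[i["A"], i["B"]] == pytest.approx(1.0)
        assert t.crown_age - C[i["A"], i["C"]] == pytest.approx(2.0)

    def test_equal_distances_merge_at_common_height(self):
        n, dval = 5, 3.0
        D = pd.DataFrame(dval * (1 - np.eye(n)), index=list("ABCDE"),
                         columns=list("ABCDE"))
        t = upgma(D)
        heights = t.crown_age - t.depths[t.n_tips:]
        assert np.allclose(heights, dval / 2.0)

    def test_output_is_exactly_ultrametric(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 3))
        D = euclidean_distance_matrix(
            _df(pts), standardized=False)
        t = upgma(D)
        assert t.is_ultrametric(1e-10)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(5)
        D = euclidean_distance_matrix(_df(rng.normal(size=(15, 4))),
                                      standardized=False)
        t = upgma(D)
        h = t.crown_age - t.depths
        for v in range(t.n_nodes):
            p = int(t.parent[v])
            if p >= 0 and v >= t.n_tips:
                assert h[p] >= h[v] - 1e-12

    def test_asymmetric_input_rejected(self):
        D = _df([[0, 1], [2, 0]], index=list("AB"))
        D.columns = list("AB")
        with pytest.raises(ValueError, match="symmetric"):
            upgma(D)


class TestDistances:
    def test_standardized_distance_affine_invariant(self):
        rng = np.random.default_rng(6)
        X = _df(rng.normal(size=(10, 3)))
        D1 = euclidean_distance_matrix(X)
        D2 = euclidean_distance_matrix(X * 7.0 - 4.0)
        assert np.allclose(D1.to_numpy(), D2.to_numpy(), atol=1e-9)

    def test_standardize_moments(self):
        rng = np.random.default_rng(7)
        Z = standardize(_df(rng.normal(2.0, 5.0, size=(20, 3))))
        assert np.allclose(Z.mean(), 0.0, atol=1e-9)
        assert np.allclose(Z.std(ddof=0), 1.0, atol=1e-9)

    def test_syndrome_distance_rule(self):
        syn = SyndromeMap({"s1": "bee", "s2": "bee", "s3": "bee_and_butterfly",
                           "s4": "bird", "s5": "fly", "s6": "butterfly"})
        D = syndrome_distance_matrix(syn)
        assert D.loc["s1", "s2"] == 0.0
        assert D.loc["s1", "s3"] == 0.5          # bee vs mixed class
        assert D.loc["s6", "s3"] == 0.5          # butterfly vs mixed class
        assert D.loc["s4", "s5"] == 1.0          # bird vs fly
        assert D.loc["s4", "s3"] == 1.0
        assert np.allclose(D.to_numpy(), D.to_numpy().T)


class TestMantel:
    def test_identical_matrices_give_extreme_result(self):
        rng = np.random.default_rng(8)
        D = euclidean_distance_matrix(_df(rng.normal(size=(10, 2))),
                                      standardized=False)
        r, p = mantel_test(D, D.copy(), n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_default_permutation_count(self):
        assert inspect.signature(mantel_test).parameters["n_perm"].default == 9999

    def test_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(9)
        X, Y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        D1 = euclidean_distance_matrix(_df(X), standardized=False)
        D2 = euclidean_distance_matrix(_df(Y), standardized=False)
        r1, _ = mantel_test(D1, D2, n_perm=99, seed=1)
        perm = list(np.random.default_rng(10).permutation(8))
        idx = [D1.index[i] for i in perm]
        r2, _ = mantel_test(D1.loc[idx, idx], D2.loc[idx, idx],
                            n_perm=99, seed=1)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_size_mismatch_rejected(self):
        D1 = _df([[0, 1], [1, 0]], index=list("AB"))
        D1.columns = list("AB")
        D2 = _df([[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("ABC"))
        D2.columns = list("ABC")
        with pytest.raises(ValueError):
            mantel_test(D1, D2, n_perm=99)


class TestDendrogramLambda:
    def _clustered(self, seed=0, n_per=12):
        """Two tight nectar clusters perfectly aligned with two syndromes."""
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 0.3, size=(n_per, 3))
        b = rng.normal(5.0, 0.3, size=(n_per, 3))
        names = [f"s{i}" for i in range(2 * n_per)]
        X = _df(np.vstack([a, b]), index=names)
        syn = SyndromeMap({n: ("bird" if i < n_per else "fly")
                           for i, n in enumerate(names)})
        return upgma(euclidean_distance_matrix(X)), syn

    def test_strong_signal_detected(self):
        dendro, syn = self._clustered()
        lam, lrt, p = dendrogram_lambda_signal(dendro, syn)
        assert lam >= 0.9
        assert p < 0.01

    def test_shuffled_labels_lose_signal(self):
        dendro, syn = self._clustered(seed=1)
        labels = [syn[s] for s in dendro.tip_labels]
        lams = []
        rng = np.random.default_rng(2)
        for _ in range(200):
            perm = rng.permutation(len(labels))
            shuffled = SyndromeMap({s: labels[j] for s, j in
                                    zip(dendro.tip_labels, perm)})
            lam, _, _ = dendrogram_lambda_signal(dendro, shuffled)
            lams.append(lam)
        assert float(np.median(lams)) <= 0.2

    def test_star_dendrogram_reduces_to_white_noise(self):
        """On a star dendrogram the whole λ profile IS the white-noise
        model, so the LRT is exactly zero."""
        n = 10
        D = pd.DataFrame(3.0 * (1 - np.eye(n)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"s{i}" for i in range(n)])
        star = upgma(D)
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(star.shared_depth_matrix()[off], 0.0, atol=1e-12)
        syn = SyndromeMap({f"s{i}": ("bee" if i % 2 else "fly")
                           for i in range(n)})
        lam, lrt, p = dendrogram_lambda_signal(star, syn)
        assert lrt == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_rejected(self):
        dendro, _ = self._clustered(seed=4, n_per=4)
        mono = SyndromeMap({s: "bee" for s in dendro.tip_labels})
        with pytest.raises(ValueError, match="monomorphic"):
            dendrogram_lambda_signal(dendro, mono)
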