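"""z-scoring, sampling adequacy, correlation PCA, Ward, bootstrap stability."""

import numpy as np
import pandas as pd
import pytest

from bandclust.clustering import (
    FeatureTable,
    bartlett_sphericity,
    bootstrap_stability,
    kmo,
    pca2,
    stability_category,
    ward_cluster,
    zscore,
)

from _oracles import kmo3_by_hand, ward_merge_sequence


def _table(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"f{i}" for i in range(arr.shape[1])]
    return FeatureTable(values=pd.DataFrame(arr, columns=cols))


class TestZscore:
    def test_simple_column(self):
        z = zscore(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 0.0, 1.0]}))
        np.testing.assert_allclose(z.values["a"], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.standard_normal((20, 4)))
        once = zscore(df).values
        twice = zscore(once).values
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_mean_and_sample_sd_invariant(self, rng):
        df = pd.DataFrame(rng.standard_normal((31, 10)) * 7 + 3)
        z = zscore(df).values
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-9)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            zscore(df)


class TestKmo:
    def test_duplicated_independent_pairs_give_half(self, rng):
        """Two near-perfectly correlated but mutually independent feature
        pairs sit exactly at the 0.5 adequacy floor."""
        n = 500
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        data = np.column_stack(
            [a, a + 1e-3 * rng.standard_normal(n), b, b + 1e-3 * rng.standard_normal(n)]
        )
        value, _ = kmo(_table(data))
        assert value == pytest.approx(0.5, abs=0.01)

    def test_matches_hand_inverted_3x3_oracle(self, rng):
        data = rng.standard_normal((31, 3))
        data[:, 1] += 0.6 * data[:, 0]
        data[:, 2] += 0.3 * data[:, 1]
        value, pseudo = kmo(_table(data))
        assert not pseudo
        assert value == pytest.approx(kmo3_by_hand(data), abs=1e-10)

    def test_always_in_unit_interval(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            p = int(rng.integers(3, 7))
            value, _ = kmo(_table(rng.standard_normal((n, p))))
            assert 0.0 <= value <= 1.0


class TestBartlett:
    def test_identity_correlation_gives_zero_chi2(self, rng):
        # QR against the constant vector: zero-mean orthogonal columns
        raw = rng.standard_normal((12, 4))
        q, _ = np.linalg.qr(np.column_stack([np.ones(12), raw]))
        data = q[:, 1:]
        chi2, df, p = bartlett_sphericity(_table(data))
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_df_formula(self, rng):
        data = rng.standard_normal((31, 10))
        _, df, _ = bartlett_sphericity(_table(data))
        assert df == 45

    def test_matches_textbook_recomputation(self, rng):
        data = rng.standard_normal((31, 6))
        data[:, 3] += 0.8 * data[:, 0]
        chi2, df, p = bartlett_sphericity(_table(data))
        R = np.corrcoef(data, rowvar=False)
        expect = -(31 - 1 - (2 * 6 + 5) / 6) * np.log(np.linalg.det(R))
        assert chi2 == pytest.approx(expect, abs=1e-8)
        from scipy.stats import chi2 as chi2_dist

        assert p == pytest.approx(chi2_dist.sf(expect, 15), abs=1e-10)


class TestPca2:
    def test_duplicated_feature_pair_loads_jointly(self, rng):
        n = 200
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        # near-duplicate pair (exact duplication makes |R| = 0, which the
        # embedded sphericity test rejects by contract)
        data = np.column_stack([a, a + 1e-6 * rng.standard_normal(n), b])
        res = pca2(_table(data))
        # the duplicated pair spans PC1-direction variance; full spectrum
        # contains a ~zero eigenvalue for the redundant copy
        assert res.explained_variance_ratio[-1] == pytest.approx(0.0, abs=1e-9)
        assert np.isclose(abs(res.loadings.iloc[0, 0]), abs(res.loadings.iloc[1, 0]))

    def test_rank_one_input_rejected(self, rng):
        a = rng.standard_normal(50)
        with pytest.raises(ValueError, match="rank"):
            pca2(_table(np.column_stack([a, a])))

    def test_isotropic_ratios_near_uniform(self, rng):
        p = 5
        data = rng.standard_normal((4000, p))
        res = pca2(_table(data))
        eigref = np.sort(np.linalg.eigvalsh(np.corrcoef(data, rowvar=False)))[::-1]
        np.testing.assert_allclose(
            res.explained_variance_ratio, eigref / eigref.sum(), atol=1e-10
        )
        assert np.all(np.abs(res.explained_variance_ratio - 1 / p) < 0.05)

    def test_sign_convention_and_flip_symmetry(self, rng):
        data = rng.standard_normal((40, 4))
        data[:, 1] += data[:, 0]
        t1 = _table(data.copy())
        flipped = data.copy()
        flipped[:, 2] *= -1
        t2 = _table(flipped)
        r1, r2 = pca2(t1), pca2(t2)
        np.testing.assert_allclose(
            np.abs(r1.scores.to_numpy()), np.abs(r2.scores.to_numpy()), atol=1e-9
        )
        for c in range(2):
            j = np.argmax(np.abs(r1.loadings.iloc[:, c]))
            assert r1.loadings.iloc[j, c] > 0

    def test_scores_zero_mean_and_ratios_sum_to_one(self, rng):
        res = pca2(_table(rng.standard_normal((31, 10))))
        np.testing.assert_allclose(res.scores.mean(), 0.0, atol=1e-9)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)


class TestWardCluster:
    def test_separated_pairs_group_together(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        sol = ward_cluster(pts, k=2)
        assert sol.labels[0] == sol.labels[1]
        assert sol.labels[2] == sol.labels[3]
        assert sol.labels[0] != sol.labels[2]

    def test_inertia_nonincreasing_in_k(self, rng):
        sol = ward_cluster(rng.standard_normal((20, 2)), k=2, k_range=range(2, 9))
        vals = [sol.inertia_by_k[k] for k in sorted(sol.inertia_by_k)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_merge_order_matches_exhaustive_ward_oracle(self, rng):
        """scipy's Lance-Williams Ward replays the brute-force minimum
        variance-increase merge sequence on 8 seeded 2-D points."""
        from scipy.cluster.hierarchy import fcluster

        pts = rng.standard_normal((8, 2))
        sol = ward_cluster(pts, k=2)
        oracle_partitions = ward_merge_sequence(pts)
        for step, expect in enumerate(oracle_partitions[:-1], start=1):
            lab = fcluster(sol.linkage_tree, t=8 - step, criterion="maxclust")
            got = {
                frozenset(np.nonzero(lab == c)[0].tolist()) for c in np.unique(lab)
            }
            assert got == expect

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            ward_cluster(rng.standard_normal((4, 2)), k=5)

    def test_labels_invariant_to_row_order(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.3, (12, 2)), rng.normal(6, 0.3, (7, 2))]
        )
        sol = ward_cluster(pts, k=2)
        perm = rng.permutation(len(pts))
        sol_p = ward_cluster(pts[perm], k=2)
        np.testing.assert_array_equal(sol.labels[perm], sol_p.labels)


class TestBootstrapStability:
    def test_separated_blobs_are_stable(self, rng):
        """Two tight, widely separated blobs must be 'stable' (J > 0.9
        averaged over 10 generator seeds)."""
        means = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            pts = np.vstack(
                [r.normal(0, 0.2, (15, 2)), r.normal(8, 0.2, (15, 2))]
            )
            sol = ward_cluster(pts, k=2)
            rep = bootstrap_stability(pts, sol, n_boot=100, frac=0.8, seed=seed)
            means.append(rep.mean_jaccard)
        means = np.array(means).mean(axis=0)
        assert np.all(means > 0.9)

    def test_homogeneous_blob_forced_split_is_fragile(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1.0, (30, 2))
        sol = ward_cluster(pts, k=2)
        rep = bootstrap_stability(pts, sol, n_boot=200, frac=0.8, seed=5)
        assert any(c in ("unstable", "dissolved") for c in rep.category)

    def test_full_fraction_gives_perfect_jaccard(self, rng):
        pts = rng.standard_normal((20, 2))
        sol = ward_cluster(pts, k=2)
        rep = bootstrap_stability(pts, sol, n_boot=20, frac=1.0, seed=0)
        np.testing.assert_allclose(rep.mean_jaccard, 1.0)

    def test_category_bands_partition_unit_interval(self):
        assert stability_category(0.75) == "stable"
        assert stability_category(0.60) == "consistent"
        assert stability_category(0.50) == "unstable"
        assert stability_category(0.7499) == "consistent"
        assert stability_category(0.5999) == "unstable"
        assert stability_category(0.4999) == "dissolved"
        assert stability_category(1.0) == "stable"
        assert stability_category(0.0) == "dissolved"
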