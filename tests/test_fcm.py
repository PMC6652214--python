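import warnings

import numpy as np
import pytest

from phenoprofiles.fcm import (FuzzyCMeans, MajorityResult, majority_rule,
                               scan_cluster_sizes, validity_indices,
                               _memberships)


def two_blobs(n_per=100, sep=10.0, sd=0.5, dim=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n_per, dim))
    b = rng.normal(sep, sd, size=(n_per, dim))
    return np.vstack([a, b])


class TestFcmFit:
    def test_symmetric_pair_recovers_antipodal_centroids(self):
        data = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        res = FuzzyCMeans(data, 2).fit(seed=0)
        assert np.sort(res.centroids.ravel()) == pytest.approx([-1.0, 1.0], abs=1e-6)
        # each point essentially crisp up to cluster relabeling
        assert np.sort(res.memberships, axis=1)[:, -1] == pytest.approx(1.0, abs=1e-6)

    def test_bruteforce_objective_oracle_1d(self):
        """Fitted objective matches a grid search over centroid pairs."""
        data = np.array([[-1.0], [-0.9], [1.0], [1.1]])
        grid = np.linspace(-2, 2, 401)
        best = np.inf
        for i, v1 in enumerate(grid):
            d1 = (data.ravel() - v1) ** 2
            for v2 in grid[i + 1:]:
                d2 = (data.ravel() - v2) ** 2
                denom = 1.0 / np.maximum(d1, 1e-300) + 1.0 / np.maximum(d2, 1e-300)
                # optimal memberships for m=2, then objective
                j = np.sum(1.0 / denom)
                best = min(best, j)
        res = FuzzyCMeans(data, 2).fit(seed=0, tol=1e-12)
        assert res.objective == pytest.approx(best, rel=1e-3)

    def test_point_at_centroid_gets_full_membership(self):
        d2 = np.array([[0.0, 4.0]])
        assert _memberships(d2, 2.0).tolist() == [[1.0, 0.0]]
        d2 = np.array([[0.0, 0.0, 3.0]])
        assert _memberships(d2, 2.0).tolist() == [[0.5, 0.5, 0.0]]

    def test_objective_nonincreasing_all_seeds(self):
        data = two_blobs(40, sep=3.0)
        for seed in range(5):
            res = FuzzyCMeans(data, 3).fit(seed=seed, n_restarts=1)
            assert np.all(np.diff(res.objective_history) <= 1e-10)

    def test_membership_rows_normalized(self):
        res = FuzzyCMeans(two_blobs(50), 4).fit(seed=1)
        assert np.allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_centroid_fixed_point_identity(self):
        res = FuzzyCMeans(two_blobs(50), 2, m=2.0).fit(seed=2)
        um = res.memberships ** 2
        expected = (um.T @ res.model.data) / um.sum(axis=0)[:, None]
        assert np.allclose(res.centroids, expected, rtol=1e-6)

    def test_invalid_parameters(self):
        data = two_blobs(3)
        with pytest.raises(ValueError):
            FuzzyCMeans(data, len(data))
        with pytest.raises(ValueError):
            FuzzyCMeans(data, 2, m=1.0)

    def test_degenerate_identical_data_warns(self):
        data = np.ones((10, 2))
        with pytest.warns(UserWarning):
            res = FuzzyCMeans(data, 2).fit(seed=0, n_restarts=1)
        assert np.allclose(res.centroids[0], res.centroids[1])

    def test_summary_mentions_key_quantities(self):
        res = FuzzyCMeans(two_blobs(30), 2).fit(seed=0)
        text = res.summary()
        assert "Clusters (C)" in text and "Validity indices" in text


class TestValidityIndices:
    def test_crisp_partition_bounds(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(8, 1, (20, 3))])
        u = np.zeros((40, 2))
        u[:20, 0] = 1.0
        u[20:, 1] = 1.0
        v = np.vstack([x[:20].mean(0), x[20:].mean(0)])
        idx = validity_indices(u, v, x)
        assert idx["PC"] == pytest.approx(1.0)
        assert idx["PE"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_membership_bounds(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        c = 4
        u = np.full((30, c), 1 / c)
        v = np.tile(x.mean(0), (c, 1)) + rng.normal(0, 0.01, (c, 3))
        idx = validity_indices(u, v, x)
        assert idx["PC"] == pytest.approx(1 / c)
        assert idx["PE"] == pytest.approx(np.log(c))

    def test_xb_smaller_when_blobs_separated(self):
        def fit_idx(sep):
            data = two_blobs(60, sep=sep, sd=0.5, dim=2, seed=3)
            res = FuzzyCMeans(data, 2).fit(seed=0)
            return res.validity_indices()

        far = fit_idx(10.0)
        near = fit_idx(1.5)
        assert far["XB"] < near["XB"]

    def test_permutation_invariance(self):
        data = two_blobs(40, sep=5.0, dim=3)
        res = FuzzyCMeans(data, 3).fit(seed=4)
        idx = validity_indices(res.memberships, res.centroids, data)
        perm = [2, 0, 1]
        idx_p = validity_indices(res.memberships[:, perm], res.centroids[perm], data)
        for k in idx:
            assert idx[k] == pytest.approx(idx_p[k], rel=1e-9), k


class TestScanAndMajority:
    def test_two_blob_scan_unanimous(self):
        data = two_blobs(150, sep=10.0, sd=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = scan_cluster_sizes(data, range(2, 7), seed=0, n_restarts=2)
        assert all(c == 2 for c in scan.proposals.values())
        assert scan.selected_c == 2 and scan.selection.has_majority

    def test_three_repeated_points_minimize_fhv_xb_at_three(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        data = np.repeat(pts, 12, axis=0)
        data = data + np.random.default_rng(0).normal(0, 1e-3, data.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = scan_cluster_sizes(data, range(2, 5), seed=0, n_restarts=3)
        assert scan.table["FHV"].idxmin() == 3
        assert scan.table["XB"].idxmin() == 3

    def test_single_blob_pc_near_lower_bound(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(200, 4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = scan_cluster_sizes(data, range(2, 5), seed=0, n_restarts=2)
        for c in scan.table.index:
            assert scan.table.loc[c, "PC"] < 1 / c + 0.12

    def test_majority_paper_style_vote(self):
        out = majority_rule({"FHV": 2, "PD": 2, "XB": 2, "FS": 2, "PC": 2, "PE": 4})
        assert out == MajorityResult(2, True, {2: 5, 4: 1})

    def test_unanimity(self):
        out = majority_rule({k: 3 for k in ("PC", "PE", "XB", "FS", "FHV", "PD")})
        assert out.selected_c == 3 and out.has_majority

    def test_no_majority_falls_back_to_smallest_plurality(self):
        props = {"PC": 2, "PE": 2, "XB": 2, "FS": 4, "FHV": 4, "PD": 4}
        out = majority_rule(props)
        assert out.selected_c == 2 and not out.has_majority

    def test_empty_proposals_raise(self):
        with pytest.raises(ValueError):
            majority_rule({})

    def test_scan_requires_enough_data(self):
        with pytest.raises(ValueError):
            scan_cluster_sizes(np.zeros((4, 2)), range(2, 6))
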