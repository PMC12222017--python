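import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from neckconn.morpho import (
    Dotprops,
    GaussScoreFunction,
    ScoreMatrix,
    TabulatedScoreFunction,
    cluster_cut,
    dotprops_from_points,
    fit_tps,
    mirror_points,
    nblast_allbyall,
    nblast_mean_normalized,
    nblast_raw,
    nblast_self,
    skeleton_to_dotprops,
)

import pandas as pd


def brute_force_dotprops(points, k):
    """Independent per-point covariance eigendecomposition oracle."""
    points = np.asarray(points, float)
    tangents, alphas = [], []
    for p in points:
        d = np.linalg.norm(points - p, axis=1)
        nbrs = points[np.argsort(d)[:k]]
        c = np.cov(nbrs.T, bias=True)
        evals, evecs = np.linalg.eigh(c)
        tangents.append(evecs[:, -1])
        alphas.append((evals[-1] - evals[-2]) / evals.sum())
    return np.array(tangents), np.array(alphas)


def brute_force_nblast(query, target, score_fn):
    """Exhaustive all-pairs nearest-neighbour NBLAST oracle."""
    total = 0.0
    for p, u in zip(query.points, query.tangents):
        d = np.linalg.norm(target.points - p, axis=1)
        j = int(np.argmin(d))
        total += float(score_fn(d[j], abs(np.dot(u, target.tangents[j]))))
    return total


class TestDotprops:
    def test_colinear_points_give_unit_alpha_and_axis_tangent(self, chain_skeleton):
        dp = skeleton_to_dotprops(chain_skeleton, resample_step=1000.0, k=5)
        assert np.allclose(np.abs(dp.tangents[:, 0]), 1.0, atol=1e-9)
        assert np.allclose(dp.alpha, 1.0, atol=1e-9)

    def test_matches_brute_force_pca_oracle(self, rng):
        pts = rng.normal(size=(50, 3)) * 1000
        dp = dotprops_from_points(pts, k=5)
        tan, alpha = brute_force_dotprops(pts, k=5)
        # tangents are sign-ambiguous eigenvectors
        assert np.allclose(np.abs(np.einsum("ij,ij->i", dp.tangents, tan)), 1.0, atol=1e-8)
        assert np.allclose(dp.alpha, alpha, atol=1e-8)

    def test_circle_tangents_orthogonal_to_radius(self):
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        r = 100_000.0
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)])
        dp = dotprops_from_points(pts, k=5)
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        cos_angle = np.abs(np.einsum("ij,ij->i", dp.tangents, radial))
        assert np.all(cos_angle < np.sin(np.deg2rad(5)))

    def test_k_clamped_with_warning(self):
        pts = np.array([[0, 0, 0], [1000, 0, 0], [2000, 0, 0.0]])
        with pytest.warns(UserWarning, match="clamping"):
            dp = dotprops_from_points(pts, k=10)
        assert dp.k == 3

    def test_single_point_is_an_error(self):
        with pytest.raises(ValueError):
            dotprops_from_points(np.array([[0.0, 0, 0]]), k=5)


class TestMirror:
    def test_involution_is_exact(self, rng):
        pts = rng.normal(size=(30, 3)) * 1e5
        assert np.array_equal(mirror_points(mirror_points(pts, 1234.5), 1234.5), pts)

    def test_midline_points_are_fixed(self):
        pts = np.array([[500.0, 3.0, 7.0]])
        assert np.array_equal(mirror_points(pts, 500.0), pts)

    def test_mirrored_left_scores_higher_than_unmirrored(self, tiny_bundle):
        ds_f, _, truth, _ = tiny_bundle
        score_fn = GaussScoreFunction()
        mid = ds_f.atlas.midline_x
        wins = 0
        total = 0
        for row in truth.pairs[truth.pairs["dataset_id"] == "F"].itertuples(index=False):
            left = skeleton_to_dotprops(ds_f.skeletons[row.left_id])
            right = skeleton_to_dotprops(ds_f.skeletons[row.right_id])
            mirrored = nblast_mean_normalized(left.mirror(mid), right, score_fn)
            plain = nblast_mean_normalized(left, right, score_fn)
            wins += mirrored > plain
            total += 1
        assert wins == total


class TestTPS:
    def test_identity_landmarks_give_identity_map(self, rng):
        src = rng.uniform(0, 1e5, size=(10, 3))
        tps = fit_tps(src, src)
        probes = rng.uniform(0, 1e5, size=(20, 3))
        assert np.allclose(tps(probes), probes, atol=1e-6)

    def test_affine_recovered_with_zero_warp(self, rng):
        src = rng.uniform(0, 1e5, size=(20, 3))
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        b = rng.normal(size=3) * 1e4
        dst = src @ A.T + b
        tps = fit_tps(src, dst)
        assert tps.warp_norm < 1e-6
        probes = rng.uniform(0, 1e5, size=(50, 3))
        assert np.allclose(tps(probes), probes @ A.T + b, atol=1e-5)

    def test_landmarks_interpolated_exactly(self, rng):
        src = rng.uniform(0, 1e5, size=(20, 3))
        dst = src + rng.normal(0, 5e3, size=(20, 3))
        tps = fit_tps(src, dst)
        assert np.max(np.abs(tps(src) - dst)) < 1e-6

    def test_coplanar_landmarks_rejected(self, rng):
        src = rng.uniform(0, 1e5, size=(10, 3))
        src[:, 2] = 0.0
        with pytest.raises(np.linalg.LinAlgError):
            fit_tps(src, src + 1.0)

    def test_too_few_landmarks_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_tps(np.zeros((3, 3)), np.zeros((3, 3)))


class TestNBLAST:
    def test_self_match_is_maximum(self, rng):
        dp = dotprops_from_points(rng.normal(size=(30, 3)) * 2000, k=5)
        fn = GaussScoreFunction()
        assert nblast_raw(dp, dp, fn) == pytest.approx(len(dp) * fn.self_score)

    def test_raw_matches_exhaustive_oracle(self, rng):
        fn = GaussScoreFunction()
        for _ in range(10):
            a = dotprops_from_points(rng.normal(size=(40, 3)) * 3000, k=5)
            b = dotprops_from_points(rng.normal(size=(35, 3)) * 3000, k=5)
            assert nblast_raw(a, b, fn) == pytest.approx(brute_force_nblast(a, b, fn), abs=1e-9)

    def test_far_separated_clouds_score_below_zero(self, rng):
        fn = GaussScoreFunction()
        a = dotprops_from_points(rng.normal(size=(30, 3)) * 2000, k=5)
        b = dotprops_from_points(rng.normal(size=(30, 3)) * 2000 + 1e6, k=5)
        assert nblast_raw(a, b, fn) <= 0

    def test_mean_normalized_identity_and_symmetry(self, rng):
        fn = GaussScoreFunction()
        a = dotprops_from_points(rng.normal(size=(30, 3)) * 2000, k=5)
        b = dotprops_from_points(rng.normal(size=(25, 3)) * 2000, k=5)
        assert nblast_mean_normalized(a, a, fn) == pytest.approx(1.0)
        assert nblast_mean_normalized(a, b, fn) == pytest.approx(
            nblast_mean_normalized(b, a, fn)
        )

    def test_jitter_monotonically_degrades_score(self, rng):
        """More positional noise means lower expected similarity."""
        fn = GaussScoreFunction()
        base_pts = np.column_stack([np.arange(50) * 1000.0, np.zeros(50), np.zeros(50)])
        base = dotprops_from_points(base_pts, k=5)
        sigmas = [100.0, 1000.0, 3000.0, 10000.0]
        means = []
        for s in sigmas:
            scores = [
                nblast_mean_normalized(
                    base, dotprops_from_points(base_pts + rng.normal(0, s, base_pts.shape), k=5), fn
                )
                for _ in range(20)
            ]
            means.append(np.mean(scores))
        assert all(m1 > m2 for m1, m2 in zip(means, means[1:]))

    def test_allbyall_diagonal_symmetry_and_elementwise_agreement(self, rng):
        fn = GaussScoreFunction()
        cohort = {
            f"n{i}": dotprops_from_points(rng.normal(size=(20, 3)) * 2000 + i * 4000, k=5)
            for i in range(4)
        }
        sm = nblast_allbyall(cohort, fn)
        vals = sm.values
        assert np.allclose(np.diag(vals), 1.0)
        assert np.allclose(vals, vals.T, atol=1e-12)
        assert vals[0, 1] == pytest.approx(
            nblast_mean_normalized(cohort["n0"], cohort["n1"], fn)
        )


class TestTabulatedScores:
    def test_round_trip_and_binning(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text(
            "0 1000 5000 100000\n"  # distance edges
            "0 1.0 0.5 -0.5\n"  # dot edge 0 + scores
            "0.5 2.0 1.0 -0.2\n"  # dot edge 0.5 + scores
            "1.0\n"  # final dot edge
        )
        fn = TabulatedScoreFunction.from_file(p)
        assert fn(500, 0.2) == pytest.approx(1.0)
        assert fn(500, 0.9) == pytest.approx(2.0)
        assert fn(50_000, 0.9) == pytest.approx(-0.2)
        assert fn.self_score == pytest.approx(2.0)


class TestClusterCut:
    def test_height_zero_gives_singletons(self, rng):
        ids = ["a", "b", "c"]
        d = pd.DataFrame(1 - np.eye(3) * 0.0, index=ids, columns=ids)
        np.fill_diagonal(d.values, 1.0)
        sm = ScoreMatrix(pd.DataFrame(np.eye(3), index=ids, columns=ids))
        labels = cluster_cut(sm, height=0.0)
        assert labels.nunique() == 3

    def test_two_separated_blobs_found_at_intermediate_height(self, rng):
        # scores near 1 within blobs, near 0 across
        ids = [f"n{i}" for i in range(6)]
        s = np.full((6, 6), 0.05)
        s[:3, :3] = 0.95
        s[3:, 3:] = 0.95
        np.fill_diagonal(s, 1.0)
        sm = ScoreMatrix(pd.DataFrame(s, index=ids, columns=ids))
        labels = cluster_cut(sm, height=0.5, method="average")
        assert labels.nunique() == 2
        assert labels["n0"] == labels["n1"] == labels["n2"]
        assert labels["n3"] == labels["n4"] == labels["n5"]

    def test_agrees_with_hand_computed_average_linkage(self):
        # 4-item toy distance matrix, average linkage worked through scipy
        # directly as the independent reference
        d = np.array(
            [
                [0.0, 0.1, 0.8, 0.9],
                [0.1, 0.0, 0.85, 0.95],
                [0.8, 0.85, 0.0, 0.2],
                [0.9, 0.95, 0.2, 0.0],
            ]
        )
        ids = list("abcd")
        scores = ScoreMatrix(pd.DataFrame(1 - d, index=ids, columns=ids))
        labels = cluster_cut(scores, height=0.5, method="average")
        from scipy.spatial.distance import squareform

        want = fcluster(linkage(squareform(d), method="average"), t=0.5, criterion="distance")
        assert labels.tolist() == list(want)
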