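"""Morphological machinery: dotprops, NBLAST, mirroring, TPS registration.

NBLAST reduces each skeleton to a cloud of points with local dominant
directions ("dotprops") and scores a query against a target by summing, over
query points, a function of the nearest-target-point distance and the
absolute tangent dot product.  The mean-normalized score — the average of
the two direction-wise raw scores, each divided by the corresponding
self-score — is 1 for identical morphologies and is what the matching
pipeline consumes.

Cross-dataset registration is an unregularized ("one-step") 3-D thin-plate
spline with kernel U(r) = r, fitted to landmark pairs and interpolating them
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from neckconn.model import Skeleton


@dataclass
class Dotprops:
    """Point/tangent cloud reduction of a skeleton.

    ``alpha`` is the colinearity of each local neighbourhood,
    (λ1−λ2)/(λ1+λ2+λ3) of the covariance eigenvalues, in [0, 1].
    """

    points: np.ndarray
    tangents: np.ndarray
    alpha: np.ndarray
    k: int
    _tree: cKDTree | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.tangents = np.atleast_2d(np.asarray(self.tangents, float))
        self.alpha = np.asarray(self.alpha, float)
        if self.points.shape[0] < 1:
            raise ValueError("empty dotprops")
        if self.points.shape != self.tangents.shape:
            raise ValueError("points/tangents shape mismatch")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def mirror(self, midline_x: float) -> "Dotprops":
        pts = self.points.copy()
        pts[:, 0] = 2.0 * midline_x - pts[:, 0]
        tan = self.tangents.copy()
        tan[:, 0] = -tan[:, 0]
        return Dotprops(pts, tan, self.alpha.copy(), self.k)

    def transform(self, fn) -> "Dotprops":
        """Map points through ``fn`` and re-derive tangents from the warped cloud."""
        return dotprops_from_points(fn(self.points), k=self.k)


def _tangents_from_points(points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-point dominant direction and colinearity from k-NN covariance."""
    n = len(points)
    k = min(k, n)
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx.T).T if k == 1 else idx
    nbrs = points[idx]  # (n, k, 3)
    centred = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / k
    evals, evecs = np.linalg.eigh(cov)  # ascending
    tangents = evecs[:, :, 2]
    total = evals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(total > 0, (evals[:, 2] - evals[:, 1]) / np.where(total > 0, total, 1), 1.0)
    return tangents, np.clip(alpha, 0.0, 1.0)


def dotprops_from_points(points: np.ndarray, k: int = 5) -> Dotprops:
    """Build dotprops straight from a point cloud (k-NN PCA tangents)."""
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) < 2:
        raise ValueError("need at least 2 points to derive tangents")
    if len(points) < k:
        warnings.warn(f"fewer points ({len(points)}) than k={k}; clamping k")
        k = len(points)
    tangents, alpha = _tangents_from_points(points, k)
    return Dotprops(points, tangents, alpha, k)


def resample_skeleton(skeleton: Skeleton, step: float) -> np.ndarray:
    """Resample every parent-child segment at ~``step`` nm spacing.

    Each segment contributes its child endpoint plus evenly spaced interior
    points; roots contribute their own position.  Node order is preserved.
    """
    nodes = skeleton.nodes
    idx = pd.Index(nodes["node_id"])
    xyz = nodes[["x", "y", "z"]].to_numpy(float)
    out = []
    parent_pos = idx.get_indexer(nodes["parent_id"].where(nodes["parent_id"] != -1, nodes["node_id"]))
    for i in range(len(nodes)):
        if nodes["parent_id"].iat[i] == -1:
            out.append(xyz[i][None, :])
            continue
        a, b = xyz[parent_pos[i]], xyz[i]
        seg = np.linalg.norm(b - a)
        n_sub = max(1, int(round(seg / step)))
        ts = np.arange(1, n_sub + 1) / n_sub
        out.append(a[None, :] + ts[:, None] * (b - a)[None, :])
    return np.concatenate(out, axis=0)


def skeleton_to_dotprops(skeleton: Skeleton, resample_step: float = 1000.0, k: int = 5) -> Dotprops:
    """Resample a skeleton and reduce it to a point/tangent cloud."""
    points = resample_skeleton(skeleton, resample_step)
    if len(points) < 2:
        raise ValueError("skeleton reduces to a single point; cannot build dotprops")
    return dotprops_from_points(points, k=k)


# ---------------------------------------------------------------------------
# Mirroring


def mirror_points(points: np.ndarray, midline_x: float) -> np.ndarray:
    """Reflect points about the sagittal plane x = midline_x."""
    points = np.asarray(points, float)
    out = points.copy()
    out[..., 0] = 2.0 * midline_x - points[..., 0]
    return out


# ---------------------------------------------------------------------------
# Thin-plate spline registration


@dataclass
class TPSTransform:
    """Unregularized 3-D thin-plate spline interpolant, kernel U(r) = r.

    f(p) = A·[1, p] + Σ_i w_i · |p − s_i|, interpolating each source
    landmark onto its paired target exactly.
    """

    src: np.ndarray  # (m, 3)
    affine: np.ndarray  # (4, 3): rows = [const, x, y, z] coefficients
    warp: np.ndarray  # (m, 3)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        U = np.linalg.norm(points[:, None, :] - self.src[None, :, :], axis=2)
        P = np.hstack([np.ones((len(points), 1)), points])
        return P @ self.affine + U @ self.warp

    @property
    def warp_norm(self) -> float:
        return float(np.linalg.norm(self.warp))


def fit_tps(src: np.ndarray, dst: np.ndarray) -> TPSTransform:
    """Fit the exact (unregularized) TPS mapping src landmarks onto dst.

    Requires m ≥ 4 non-coplanar source landmarks; a coplanar or otherwise
    degenerate system raises ``np.linalg.LinAlgError``.  For exactly affine
    displacement fields the recovered warp coefficients are ~0.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (m, 3) arrays")
    m = len(src)
    if m < 4:
        raise ValueError(f"need at least 4 landmark pairs, got {m}")
    K = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    P = np.hstack([np.ones((m, 1)), src])
    A = np.zeros((m + 4, m + 4))
    A[:m, :m] = K
    A[:m, m:] = P
    A[m:, :m] = P.T
    rhs = np.zeros((m + 4, 3))
    rhs[:m] = dst
    # guard against numerically singular (coplanar) systems that solve()
    # would happily "solve" with garbage
    if np.linalg.matrix_rank(P) < 4:
        raise np.linalg.LinAlgError("source landmarks are coplanar or degenerate")
    sol = np.linalg.solve(A, rhs)
    return TPSTransform(src=src, affine=sol[m:], warp=sol[:m])


# ---------------------------------------------------------------------------
# NBLAST scoring


class GaussScoreFunction:
    """Parametric NBLAST score: s(d, dp) = dp·exp(−d²/2σ²) − c.

    Positive for close, aligned point pairs; negative (−c) at large
    distance, so unrelated clouds score below zero.  σ is in nm.
    """

    def __init__(self, sigma: float = 3000.0, c: float = 0.1):
        self.sigma = float(sigma)
        self.c = float(c)

    def __call__(self, dist, absdot):
        dist = np.asarray(dist, float)
        absdot = np.asarray(absdot, float)
        return absdot * np.exp(-(dist**2) / (2.0 * self.sigma**2)) - self.c

    @property
    def self_score(self) -> float:
        """Score of a point against itself (d = 0, |dp| = 1)."""
        return 1.0 - self.c


class TabulatedScoreFunction:
    """Score function from a tabulated (distance-bin × dot-bin) matrix.

    File format: whitespace/tab-delimited; first row = D+1 distance bin
    edges in nm; the following A+1 rows start with the dot-product bin
    edges, rows 1..A additionally carrying the D log-odds scores of that
    dot bin.  Out-of-range values are clamped to the edge bins.
    """

    def __init__(self, dist_edges: np.ndarray, dot_edges: np.ndarray, scores: np.ndarray):
        self.dist_edges = np.asarray(dist_edges, float)
        self.dot_edges = np.asarray(dot_edges, float)
        self.scores = np.asarray(scores, float)
        if self.scores.shape != (len(self.dot_edges) - 1, len(self.dist_edges) - 1):
            raise ValueError("score table shape does not match bin edges")

    @classmethod
    def from_file(cls, path) -> "TabulatedScoreFunction":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    rows.append([float(v) for v in line.split()])
        dist_edges = np.array(rows[0])
        dot_edges = np.array([r[0] for r in rows[1:]])
        scores = np.array([r[1:] for r in rows[1:] if len(r) > 1])
        return cls(dist_edges, dot_edges, scores)

    def __call__(self, dist, absdot):
        dist = np.asarray(dist, float)
        absdot = np.asarray(absdot, float)
        di = np.clip(np.digitize(dist, self.dist_edges) - 1, 0, self.scores.shape[1] - 1)
        ai = np.clip(np.digitize(absdot, self.dot_edges) - 1, 0, self.scores.shape[0] - 1)
        return self.scores[ai, di]

    @property
    def self_score(self) -> float:
        return float(self(0.0, 1.0))


def nblast_raw(query: Dotprops, target: Dotprops, score_fn=None) -> float:
    """Raw (asymmetric) NBLAST score of ``query`` against ``target``.

    Sum over query points of score_fn(nearest-target distance, |u_q·u_t|).
    """
    if score_fn is None:
        score_fn = GaussScoreFunction()
    if len(query) == 0 or len(target) == 0:
        raise ValueError("empty dotprops")
    dist, idx = target.tree.query(query.points, k=1)
    absdot = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[idx]))
    return float(np.sum(score_fn(dist, absdot)))


def nblast_self(dp: Dotprops, score_fn=None) -> float:
    """Self score n · s(0, 1), the maximum a query of that size can attain."""
    if score_fn is None:
        score_fn = GaussScoreFunction()
    return len(dp) * float(score_fn(0.0, 1.0))


def nblast_mean_normalized(a: Dotprops, b: Dotprops, score_fn=None) -> float:
    """Mean-normalized NBLAST: (raw(a,b)/raw(a,a) + raw(b,a)/raw(b,b)) / 2.

    Symmetric; equals 1 iff the clouds coincide point-for-point.
    """
    if score_fn is None:
        score_fn = GaussScoreFunction()
    return 0.5 * (
        nblast_raw(a, b, score_fn) / nblast_self(a, score_fn)
        + nblast_raw(b, a, score_fn) / nblast_self(b, score_fn)
    )


@dataclass
class ScoreMatrix:
    """Labelled real-valued score matrix (raw or mean-normalized)."""

    data: pd.DataFrame
    kind: str = "mean_normalized"

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    @property
    def ids(self) -> list:
        return list(self.data.index)


def nblast_pairwise(
    queries: dict[str, Dotprops], targets: dict[str, Dotprops], score_fn=None
) -> ScoreMatrix:
    """Mean-normalized NBLAST of every query against every target."""
    if score_fn is None:
        score_fn = GaussScoreFunction()
    q_ids, t_ids = list(queries), list(targets)
    q_self = {i: nblast_self(queries[i], score_fn) for i in q_ids}
    t_self = {j: nblast_self(targets[j], score_fn) for j in t_ids}
    out = np.empty((len(q_ids), len(t_ids)))
    for i, qi in enumerate(q_ids):
        for j, tj in enumerate(t_ids):
            out[i, j] = 0.5 * (
                nblast_raw(queries[qi], targets[tj], score_fn) / q_self[qi]
                + nblast_raw(targets[tj], queries[qi], score_fn) / t_self[tj]
            )
    return ScoreMatrix(pd.DataFrame(out, index=q_ids, columns=t_ids), kind="mean_normalized")


def nblast_allbyall(cohort: dict[str, Dotprops], score_fn=None) -> ScoreMatrix:
    """Symmetric all-by-all mean-normalized matrix; diagonal = 1."""
    if len(cohort) < 2:
        raise ValueError("need at least 2 dotprops for an all-by-all matrix")
    sm = nblast_pairwise(cohort, cohort, score_fn)
    vals = sm.values
    np.fill_diagonal(vals, 1.0)
    sm.data.iloc[:, :] = vals
    return sm


# ---------------------------------------------------------------------------
# Hierarchical clustering


def cluster_rows(
    matrix: np.ndarray, height: float, method: str = "ward", is_distance: bool = True
) -> np.ndarray:
    """Hierarchically cluster rows and cut the dendrogram at ``height``.

    ``matrix`` is either a square distance matrix (``is_distance``) or a
    feature matrix clustered on Euclidean row distance.  Returns integer
    labels starting at 1; deterministic given the input.
    """
    matrix = np.asarray(matrix, float)
    if is_distance:
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("distance input must be a square matrix")
        sym = 0.5 * (matrix + matrix.T)
        np.fill_diagonal(sym, 0.0)
        condensed = squareform(sym, checks=False)
        Z = scipy_linkage(condensed, method=method)
    else:
        Z = scipy_linkage(matrix, method=method, metric="euclidean")
    return fcluster(Z, t=height, criterion="distance")


def cluster_cut(score_matrix: ScoreMatrix, height: float, method: str = "ward") -> pd.Series:
    """Cut an NBLAST score matrix into flat clusters at the given height.

    Distance is 1 − mean-normalized score (clipped at 0).  Height 0 puts
    every item in its own cluster.
    """
    vals = score_matrix.values
    if vals.shape[0] != vals.shape[1]:
        raise ValueError("cluster_cut needs a square score matrix")
    dist = np.clip(1.0 - vals, 0.0, None)
    labels = cluster_rows(dist, height=height, method=method, is_distance=True)
    return pd.Series(labels, index=score_matrix.ids, name="cluster")
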