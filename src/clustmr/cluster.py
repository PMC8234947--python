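"""k-means clustering of the z-score matrix, cluster-count selection, and PCA.

Variants that act through a shared biological pathway are expected to show
similar association profiles across traits, so clustering rows of the
variant × trait z-score matrix groups variants into putative etiologic
pathways.  k-means requires the number of clusters k in advance; k is chosen
by a majority vote over eight internal validity indices, each voting for its
own optimal k (a deliberately small, well-defined subset of the classical
index battery, chosen to behave sensibly at a few dozen rows):

========================  ============================================
index                     best-k rule
========================  ============================================
silhouette                maximize mean silhouette width
calinski_harabasz         maximize (B/(k−1)) / (W/(n−k))
davies_bouldin            minimize mean worst pairwise cluster overlap
dunn                      maximize min inter-cluster gap / max diameter
gap                       smallest k with Gap(k) ≥ Gap(k+1) − s(k+1)
                          (uniform bounding-box references)
hartigan                  smallest k with (W_k/W_{k+1}−1)(n−k−1) ≤ 10
krzanowski_lai            maximize |DIFF_k / DIFF_{k+1}|,
                          DIFF_k = (k−1)^{2/p} W_{k−1} − k^{2/p} W_k
ball_hall                 maximize the drop of W_k/k from k−1 to k
========================  ============================================

W_k is the total within-cluster sum of squares of the best k-means solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .zmatrix import ZScoreMatrix

__all__ = [
    "ClusterSolution",
    "KSelectionReport",
    "PCAProjection",
    "kmeans",
    "select_k",
    "pca_project",
    "INDEX_NAMES",
]

INDEX_NAMES = (
    "silhouette",
    "calinski_harabasz",
    "davies_bouldin",
    "dunn",
    "gap",
    "hartigan",
    "krzanowski_lai",
    "ball_hall",
)


def _as_array(matrix: Union[ZScoreMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(matrix, ZScoreMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


@dataclass
class ClusterSolution:
    """Best-of-restarts k-means solution.

    ``labels`` are 1-based cluster indices in {1..k}, relabelled by order of
    first appearance so output is stable; ``wss`` is the total within-cluster
    sum of squares of the returned solution.
    """

    labels: np.ndarray
    centroids: np.ndarray
    wss: float
    n_iter: int
    seed: int
    n_restarts: int
    k: int
    variant_ids: Optional[list[str]] = None

    def labels_frame(self) -> pd.DataFrame:
        ids = self.variant_ids or [str(i) for i in range(len(self.labels))]
        return pd.DataFrame({"variant_id": ids, "cluster": self.labels})

    def members(self, cluster: int) -> list[str]:
        ids = self.variant_ids or [str(i) for i in range(len(self.labels))]
        return [v for v, lab in zip(ids, self.labels) if lab == cluster]


@dataclass
class KSelectionReport:
    k_range: tuple[int, int]
    per_index_k: dict[str, Optional[int]]
    vote_counts: dict[int, int]
    chosen_k: Optional[int]
    ambiguous: bool
    degenerate: bool
    no_cluster_evidence: bool = False
    index_values: dict[str, dict[int, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "per_index_k": self.per_index_k,
            "vote_counts": {str(k): v for k, v in self.vote_counts.items()},
            "chosen_k": self.chosen_k,
            "ambiguous": self.ambiguous,
            "degenerate": self.degenerate,
            "no_cluster_evidence": self.no_cluster_evidence,
            "index_values": {
                name: {str(k): v for k, v in vals.items()}
                for name, vals in self.index_values.items()
            },
        }


@dataclass
class PCAProjection:
    scores: np.ndarray  # n × m variant scores
    loadings: np.ndarray  # traits × m
    variance_explained: np.ndarray  # fraction per component
    rank: int
    variant_ids: Optional[list[str]] = None
    trait_ids: Optional[list[str]] = None

    @property
    def zero_variance_components(self) -> list[int]:
        return [j for j in range(self.scores.shape[1]) if j >= self.rank]


# ---------------------------------------------------------------------------
# k-means (Lloyd, k-means++ init, restarts batched across the restart axis)
# ---------------------------------------------------------------------------


def _kmeanspp_init(X: np.ndarray, k: int, n_restarts: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding for all restarts at once; returns (R, k, p) centroids."""
    n = X.shape[0]
    centers = np.empty((n_restarts, k, X.shape[1]))
    first = rng.integers(0, n, size=n_restarts)
    centers[:, 0] = X[first]
    # squared distance of every point to its nearest chosen center, per restart
    d2 = ((X[None, :, :] - centers[:, 0, None, :]) ** 2).sum(-1)  # (R, n)
    for j in range(1, k):
        total = d2.sum(axis=1)
        probs = np.where(total[:, None] > 0, d2 / np.maximum(total, 1e-300)[:, None], 1.0 / n)
        u = rng.random(n_restarts)
        idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(max=n - 1)
        centers[:, j] = X[idx]
        d2 = np.minimum(d2, ((X[None, :, :] - centers[:, j, None, :]) ** 2).sum(-1))
    return centers


def kmeans(
    matrix: Union[ZScoreMatrix, np.ndarray],
    k: int,
    n_restarts: int = 100,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> ClusterSolution:
    """Lloyd's algorithm from k-means++ starts; best of ``n_restarts`` by wss.

    Deterministic given (seed, n_restarts).  An empty cluster arising during
    iteration is re-seeded at the point currently farthest from its assigned
    centroid.
    """
    X = _as_array(matrix)
    n, p = X.shape
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside [1, n_variants={n}]")
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    C = _kmeanspp_init(X, k, n_restarts, rng)  # (R, k, p)
    R = n_restarts
    x_sq = (X**2).sum(-1)  # (n,)
    n_iter = np.zeros(R, dtype=int)
    active = np.ones(R, dtype=bool)
    labels = np.zeros((R, n), dtype=int)
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ca = C[idx]  # (r, k, p)
        d2 = x_sq[None, :, None] - 2 * np.einsum("np,rkp->rnk", X, Ca) + (Ca**2).sum(-1)[:, None, :]
        lab = d2.argmin(axis=2)  # (r, n)
        onehot = np.eye(k, dtype=float)[lab]  # (r, n, k)
        counts = onehot.sum(axis=1)  # (r, k)
        sums = np.einsum("rnk,np->rkp", onehot, X)
        newC = np.where(counts[:, :, None] > 0, sums / np.maximum(counts, 1)[:, :, None], Ca)
        # re-seed empty clusters at the farthest point from its assigned centroid
        empty_r, empty_k = np.nonzero(counts == 0)
        for r_loc, k_loc in zip(empty_r, empty_k):
            dists = ((X - newC[r_loc][lab[r_loc]]) ** 2).sum(-1)
            far = int(np.argmax(dists))
            newC[r_loc, k_loc] = X[far]
            lab[r_loc, far] = k_loc
        shift = np.sqrt(((newC - Ca) ** 2).sum(-1)).max(axis=1)  # (r,)
        C[idx] = newC
        labels[idx] = lab
        n_iter[idx] = it
        still = shift >= tol
        active[idx] = still
    # final assignment and wss per restart
    d2 = x_sq[None, :, None] - 2 * np.einsum("np,rkp->rnk", X, C) + (C**2).sum(-1)[:, None, :]
    labels = d2.argmin(axis=2)
    wss_all = np.take_along_axis(d2, labels[:, :, None], axis=2)[:, :, 0].sum(axis=1)
    best = int(np.argmin(wss_all))
    best_labels = labels[best]
    # relabel clusters by order of first appearance -> stable 1-based labels
    order: dict[int, int] = {}
    for lab in best_labels:
        if lab not in order:
            order[lab] = len(order) + 1
    relabelled = np.array([order[lab] for lab in best_labels], dtype=int)
    centroids = np.empty((k, p))
    for old, new in order.items():
        centroids[new - 1] = C[best, old]
    for old in range(k):  # clusters that ended empty keep their coordinates
        if old not in order:
            centroids[len(order)] = C[best, old]
            order[old] = len(order) + 1
    variant_ids = matrix.variant_ids if isinstance(matrix, ZScoreMatrix) else None
    return ClusterSolution(
        labels=relabelled,
        centroids=centroids,
        wss=float(max(wss_all[best], 0.0)),
        n_iter=int(n_iter[best]),
        seed=seed,
        n_restarts=n_restarts,
        k=k,
        variant_ids=variant_ids,
    )


# ---------------------------------------------------------------------------
# internal validity indices
# ---------------------------------------------------------------------------


def _pairwise_d(X: np.ndarray) -> np.ndarray:
    sq = (X**2).sum(-1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    return np.sqrt(np.maximum(d2, 0.0))


def _silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    D = _pairwise_d(X)
    n = len(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return float("nan")
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        a = D[i, own].sum() / (n_own - 1) if n_own > 1 else 0.0
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def _calinski_harabasz(X: np.ndarray, labels: np.ndarray, wss: float) -> float:
    n = len(labels)
    k = len(np.unique(labels))
    grand = X.mean(axis=0)
    bss = sum(
        (labels == c).sum() * ((X[labels == c].mean(axis=0) - grand) ** 2).sum()
        for c in np.unique(labels)
    )
    if k == 1 or wss == 0:
        return float("inf") if bss > 0 else float("nan")
    return float((bss / (k - 1)) / (wss / (n - k)))


def _davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    uniq = np.unique(labels)
    cents = np.array([X[labels == c].mean(axis=0) for c in uniq])
    scat = np.array(
        [np.sqrt(((X[labels == c] - cents[i]) ** 2).sum(-1)).mean() for i, c in enumerate(uniq)]
    )
    k = len(uniq)
    db = 0.0
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            d = np.sqrt(((cents[i] - cents[j]) ** 2).sum())
            if d > 0:
                worst = max(worst, (scat[i] + scat[j]) / d)
        db += worst
    return float(db / k)


def _dunn(X: np.ndarray, labels: np.ndarray) -> float:
    D = _pairwise_d(X)
    uniq = np.unique(labels)
    max_diam = max(
        (D[np.ix_(labels == c, labels == c)].max() if (labels == c).sum() > 1 else 0.0)
        for c in uniq
    )
    min_sep = np.inf
    for i, ci in enumerate(uniq):
        for cj in uniq[i + 1 :]:
            min_sep = min(min_sep, D[np.ix_(labels == ci, labels == cj)].min())
    if max_diam == 0:
        return float("inf") if np.isfinite(min_sep) and min_sep > 0 else float("nan")
    return float(min_sep / max_diam)


def select_k(
    matrix: Union[ZScoreMatrix, np.ndarray],
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    n_restarts: int = 100,
    gap_b: int = 100,
    gap_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> KSelectionReport:
    """Choose the number of clusters by a majority vote of eight indices.

    Each index votes for one k in ``k_range`` (inclusive); the k with most
    votes wins, ties broken toward the smallest k.  The report is flagged
    ``ambiguous`` when no k reaches an absolute majority (>= half of the
    indices that voted), and ``degenerate`` when all rows are identical, in
    which case ``chosen_k`` is None.
    """
    X = _as_array(matrix)
    n = X.shape[0]
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if not (2 <= k_lo <= k_hi <= n - 1):
        raise ParameterError(f"k_range {k_range} not within [2, n-1={n - 1}]")
    if np.allclose(X, X[0]):
        return KSelectionReport(
            k_range=(k_lo, k_hi),
            per_index_k={name: None for name in INDEX_NAMES},
            vote_counts={},
            chosen_k=None,
            ambiguous=True,
            degenerate=True,
        )
    rng = np.random.default_rng(seed)
    ks_ext = range(1, min(k_hi + 1, n) + 1)  # W_k needed one past each end
    sol: dict[int, ClusterSolution] = {}
    wss: dict[int, float] = {}
    for k in ks_ext:
        if k == 1:
            wss[1] = float(((X - X.mean(axis=0)) ** 2).sum())
            continue
        s = kmeans(X, k, n_restarts=n_restarts, seed=int(rng.integers(2**31)),
                   max_iter=max_iter, tol=tol)
        sol[k] = s
        wss[k] = s.wss
    ks = list(range(k_lo, k_hi + 1))
    values: dict[str, dict[int, float]] = {name: {} for name in INDEX_NAMES}
    p = X.shape[1]

    for k in ks:
        lab = sol[k].labels
        values["silhouette"][k] = _silhouette(X, lab)
        values["calinski_harabasz"][k] = _calinski_harabasz(X, lab, wss[k])
        values["davies_bouldin"][k] = _davies_bouldin(X, lab)
        values["dunn"][k] = _dunn(X, lab)
        nk1 = wss.get(k + 1)
        values["hartigan"][k] = (
            (wss[k] / nk1 - 1.0) * (n - k - 1) if nk1 and nk1 > 0 else float("nan")
        )
        values["ball_hall"][k] = wss[k] / k

    # Krzanowski–Lai needs W at k-1, k, k+1
    def diff(k):
        return (k - 1) ** (2.0 / p) * wss.get(k - 1, np.nan) - k ** (2.0 / p) * wss.get(
            k, np.nan
        )

    for k in ks:
        d_next = diff(k + 1)
        values["krzanowski_lai"][k] = (
            abs(diff(k) / d_next) if d_next not in (0.0,) and np.isfinite(d_next) else float("nan")
        )

    # gap statistic: uniform references over the data's bounding box; k=1 is
    # included so the no-clustering null can be preferred outright
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w_ref = {k: np.empty(gap_b) for k in sorted({1, *range(k_lo, min(k_hi + 1, n) + 1)})}
    for b in range(gap_b):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(2**31))
        for k in log_w_ref:
            w = kmeans(ref, k, n_restarts=gap_restarts, seed=ref_seed, max_iter=max_iter,
                       tol=tol).wss
            log_w_ref[k][b] = np.log(max(w, 1e-300))
    gap = {}
    s_k = {}
    for k in log_w_ref:
        gap[k] = float(log_w_ref[k].mean() - np.log(max(wss[k], 1e-300)))
        s_k[k] = float(log_w_ref[k].std(ddof=0) * np.sqrt(1 + 1.0 / gap_b))
    for k in ks:
        values["gap"][k] = gap[k]

    per_index_k: dict[str, Optional[int]] = {}

    def vote(name, rule):
        try:
            per_index_k[name] = rule()
        except (ValueError, KeyError):
            per_index_k[name] = None

    def argbest(name, best=max):
        vals = {k: v for k, v in values[name].items() if np.isfinite(v)}
        if not vals:
            return None
        target = best(vals.values())
        return min(k for k, v in vals.items() if v == target)

    vote("silhouette", lambda: argbest("silhouette", max))
    vote("calinski_harabasz", lambda: argbest("calinski_harabasz", max))
    vote("davies_bouldin", lambda: argbest("davies_bouldin", min))
    vote("dunn", lambda: argbest("dunn", max))

    def gap_rule():
        for k in ks:
            if k + 1 in gap and gap[k] >= gap[k + 1] - s_k[k + 1]:
                return k
        return argbest("gap", max)

    vote("gap", gap_rule)

    def hartigan_rule():
        finite = {k: v for k, v in values["hartigan"].items() if np.isfinite(v)}
        for k in ks:
            if k in finite and finite[k] <= 10.0:
                return k
        # fallback: largest drop of H between successive k
        drops = {
            k: finite[k - 1] - finite[k] for k in ks if k in finite and (k - 1) in finite
        }
        if drops:
            m = max(drops.values())
            return min(k for k, v in drops.items() if v == m)
        return argbest("hartigan", min)

    vote("hartigan", hartigan_rule)
    vote("krzanowski_lai", lambda: argbest("krzanowski_lai", max))

    def ball_hall_rule():
        bh = {k: wss[k] / k for k in range(max(1, k_lo - 1), k_hi + 1) if k in wss}
        drops = {k: bh[k - 1] - bh[k] for k in ks if (k - 1) in bh and k in bh}
        if not drops:
            return None
        m = max(drops.values())
        return min(k for k, v in drops.items() if v == m)

    vote("ball_hall", ball_hall_rule)

    votes = [k for k in per_index_k.values() if k is not None]
    vote_counts: dict[int, int] = {}
    for k in votes:
        vote_counts[k] = vote_counts.get(k, 0) + 1
    # the gap statistic's one-standard-error rule applied at k=1: when the
    # no-clustering null already wins, any index majority is suspect
    no_cluster_evidence = bool(
        1 in gap and k_lo in gap and gap[1] >= gap[k_lo] - s_k[k_lo]
    )
    if vote_counts:
        top = max(vote_counts.values())
        chosen = min(k for k, c in vote_counts.items() if c == top)
        ambiguous = (
            top < (len(votes) + 1) // 2
            or sum(1 for c in vote_counts.values() if c == top) > 1
            or no_cluster_evidence
        )
    else:
        chosen, ambiguous = None, True
    return KSelectionReport(
        k_range=(k_lo, k_hi),
        per_index_k=per_index_k,
        vote_counts=vote_counts,
        chosen_k=chosen,
        ambiguous=ambiguous,
        degenerate=False,
        no_cluster_evidence=no_cluster_evidence,
        index_values=values,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_project(matrix: Union[ZScoreMatrix, np.ndarray], m: int = 2) -> PCAProjection:
    """Column-centered SVD projection onto the first ``m`` principal components.

    Scores are the variant coordinates, loadings the trait directions (the
    biplot arrows), and variance_explained the fraction of total variance per
    component.  Sign convention: within each component the largest-magnitude
    loading is positive.  Components beyond the matrix rank carry zero
    variance and are flagged via ``rank``.
    """
    X = _as_array(matrix)
    n, p = X.shape
    if not 1 <= m <= min(n, p):
        raise ParameterError(f"m={m} outside [1, min(n, p)={min(n, p)}]")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * max(n, p) * np.finfo(float).eps).sum()) if S.size else 0
    scores = U[:, :m] * S[:m]
    loadings = Vt[:m].T  # p × m
    for j in range(m):
        i_star = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_star, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total = float((S**2).sum())
    var_frac = (S[:m] ** 2 / total) if total > 0 else np.zeros(m)
    variant_ids = matrix.variant_ids if isinstance(matrix, ZScoreMatrix) else None
    trait_ids = matrix.trait_ids if isinstance(matrix, ZScoreMatrix) else None
    return PCAProjection(
        scores=scores,
        loadings=loadings,
        variance_explained=np.asarray(var_frac, dtype=float),
        rank=rank,
        variant_ids=variant_ids,
        trait_ids=trait_ids,
    )
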