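"""Connectivity-based parcellation of the target region by fuzzy c-means.

The target region's unsmoothed, temporally filtered voxel time courses are
z-standardized, reduced by PCA to the smallest subspace capturing at least
90% of the variance, and partitioned by fuzzy c-means (FCM).  FCM assigns
each voxel n a graded membership u_cn in [0, 1] to every cluster c (rows
sum to 1) and alternates the Bezdek updates

    u_cn = 1 / sum_j (d_cn / d_jn)^(2/(m-1))
    v_c  = sum_n u_cn^m x_n / sum_n u_cn^m

until memberships stabilize.  The fuzziness exponent m (> 1 in this
standard formulation) controls how soft the assignment is; the number of
clusters is chosen by an unsupervised search minimizing the Xie-Beni
validity index.

Distance metric.  For BOLD time-course clustering the similarity of a
voxel to a centroid is naturally a *correlation*: it is scale invariant
and, unlike Euclidean distance in a high-dimensional retained subspace,
is not dominated by the voxel's own noise energy (with Euclidean
distances every voxel is roughly equidistant from every denoised
centroid, and the fuzzifier then collapses all centroids onto the grand
mean).  The parcellation entry points therefore default to
``metric="cosine"`` -- spherical FCM on length-normalized vectors with
``d^2 = 1 - cos`` and a renormalized weighted-mean centroid update, which
keeps the objective nonincreasing.  The classical ``metric="euclidean"``
variant is available and is what the small-sample 2-means equivalences
hold for.  Per-subject partitions are aligned across subjects by
Dice-maximizing label assignment with a consensus pass, and summarized as
per-cluster probabilistic maps.

Note on the fuzziness parameter: some fMRI clustering tools parameterize
fuzziness on a reciprocal scale where a published value of 0.4 corresponds
to the standard Bezdek exponent m = 1/0.4 = 2.5.  This package uses the
standard exponent, default ``m = 2.5``; the mapping is a declared
assumption and is logged when the default is used.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "FuzzyPartition",
    "target_timecourses",
    "pca_reduce",
    "fcm",
    "xie_beni",
    "select_n_clusters",
    "harden",
    "to_label_map",
    "match_clusters",
    "cluster_probability_maps",
    "apply_display_floor",
    "label_clusters_by_network",
]

DEFAULT_FUZZINESS = 2.5  # standard-exponent counterpart of the 0.4 plugin scale
_m_logged = False


@dataclasses.dataclass
class FuzzyPartition:
    """Result of one FCM run.

    ``memberships`` is (n_voxels, c) with rows summing to 1; ``centroids``
    is (c, d) in the reduced space; ``voxel_index`` maps row -> 3-D voxel
    coordinate when the partition came from an image.
    """

    memberships: np.ndarray
    centroids: np.ndarray
    fuzziness_m: float
    objective: float
    n_iter: int
    metric: str = "euclidean"
    voxel_index: Optional[np.ndarray] = None
    objective_history: Optional[List[float]] = None

    def __post_init__(self) -> None:
        u = np.asarray(self.memberships, dtype=float)
        if u.ndim != 2 or u.shape[1] < 1:
            raise ValueError("memberships must be (n, c) with c >= 1")
        if np.any(u < -1e-9) or np.any(u > 1 + 1e-9):
            raise ValueError("memberships must lie in [0, 1]")
        row_sums = u.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-6):
            raise ValueError("membership rows must sum to 1")
        if self.fuzziness_m <= 1:
            raise ValueError("fuzziness exponent must be > 1")

    @property
    def n_clusters(self) -> int:
        return self.memberships.shape[1]


def target_timecourses(run, target_mask: np.ndarray):
    """(n_voxels, t) matrix of target-region time courses plus voxel index."""
    target_mask = np.asarray(target_mask, dtype=bool) & run.brain_mask
    if not np.any(target_mask):
        raise ValueError("target mask does not intersect the brain")
    X = run.data[target_mask].astype(float)
    voxel_index = np.array(np.nonzero(target_mask)).T
    return X, voxel_index


def pca_reduce(X: np.ndarray, var_frac: float = 0.9):
    """Z-score rows, then project onto the smallest principal subspace
    capturing at least ``var_frac`` of the variance.

    Returns ``(reduced, explained_fractions, kept_rows)``; constant rows
    cannot be z-scored and are dropped with a warning (``kept_rows`` maps
    reduced rows back to input rows).
    """
    if not (0 < var_frac <= 1):
        raise ValueError("var_frac must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("X must be (n >= 2, t >= 2)")
    sd = X.std(axis=1)
    keep = sd > 1e-12 * max(1.0, np.abs(X).max())
    if not np.all(keep):
        warnings.warn(f"dropping {np.count_nonzero(~keep)} constant voxel rows")
    X = X[keep]
    Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    max_d = min(Xz.shape)
    if var_frac == 1.0:
        pca = PCA(n_components=max_d, svd_solver="full")
    else:
        pca = PCA(n_components=var_frac, svd_solver="full")
    reduced = pca.fit_transform(Xz)
    return reduced, pca.explained_variance_ratio_, np.nonzero(keep)[0]


def _init_centroids(
    X: np.ndarray, c: int, rng: np.random.Generator, max_tries: int = 100
) -> np.ndarray:
    """Seeded draw of c distinct data rows; re-draw coincident rows."""
    n = X.shape[0]
    for _ in range(max_tries):
        idx = rng.choice(n, size=c, replace=False)
        cand = X[idx]
        d = np.linalg.norm(cand[:, None] - cand[None], axis=-1)
        if np.all(d[np.triu_indices(c, 1)] > 1e-12):
            return cand.copy()
    raise ValueError("could not draw distinct initial centroids (duplicated data?)")


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cosine metric undefined for all-zero rows")
    return X / norms


def fcm(
    X: np.ndarray,
    c: int,
    m: float = DEFAULT_FUZZINESS,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    metric: str = "euclidean",
) -> FuzzyPartition:
    """Fuzzy c-means with the standard Bezdek alternating updates.

    Convergence when the maximum absolute membership change drops below
    ``tol`` (or after ``max_iter`` iterations).  Voxels coinciding with a
    centroid get membership 1 there.  The objective
    ``J = sum u^m d^2`` is tracked and is nonincreasing across iterations.
    ``metric`` is ``"euclidean"`` (classical FCM) or ``"cosine"``
    (spherical FCM on length-normalized rows, ``d^2 = 1 - cos``; the
    natural choice for z-scored time courses, see module docstring).
    """
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unknown metric '{metric}'")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if metric == "cosine":
        X = _normalize_rows(X)
    n = X.shape[0]
    if c > n:
        raise ValueError(f"c={c} exceeds number of points n={n}")
    if m <= 1:
        raise ValueError("fuzziness exponent m must be > 1")
    global _m_logged
    if m == DEFAULT_FUZZINESS and not _m_logged:
        logger.info(
            "fuzziness m=2.5 (standard exponent; reciprocal of the 0.4 "
            "plugin-scale convention)"
        )
        _m_logged = True
    rng = np.random.default_rng(seed)
    if c == 1:
        centroid = _update_centroids(X, np.ones((n, 1)), 1.0, metric)
        u = np.ones((n, 1))
        d2 = _sq_distances(X, centroid, metric)[:, 0]
        return FuzzyPartition(u, centroid, m, float(d2.sum()), 0, metric=metric,
                              objective_history=[float(d2.sum())])
    centroids = _init_centroids(X, c, rng)
    expo = 2.0 / (m - 1.0)
    u = _memberships(X, centroids, expo, metric)
    history: List[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        centroids = _update_centroids(X, u, m, metric)
        new_u = _memberships(X, centroids, expo, metric)
        d2 = _sq_distances(X, centroids, metric)
        history.append(float((new_u**m * d2).sum()))
        if np.max(np.abs(new_u - u)) < tol:
            u = new_u
            break
        u = new_u
    d2 = _sq_distances(X, centroids, metric)
    objective = float((u**m * d2).sum())
    return FuzzyPartition(
        memberships=u,
        centroids=centroids,
        fuzziness_m=m,
        objective=objective,
        n_iter=n_iter,
        metric=metric,
        objective_history=history,
    )


def _sq_distances(X: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cosine":
        return np.clip(1.0 - X @ centroids.T, 0.0, None)
    diff = X[:, None, :] - centroids[None, :, :]
    return np.einsum("ncd,ncd->nc", diff, diff)


def _update_centroids(
    X: np.ndarray, u: np.ndarray, m: float, metric: str
) -> np.ndarray:
    um = u**m
    v = (um.T @ X) / um.sum(axis=0)[:, None]
    if metric == "cosine":
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        v = v / norms
    return v


def _memberships(
    X: np.ndarray, centroids: np.ndarray, expo: float, metric: str
) -> np.ndarray:
    d2 = _sq_distances(X, centroids, metric)
    zero = d2 <= 1e-12
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-expo / 2.0)
        u = inv / inv.sum(axis=1, keepdims=True)
    if np.any(any_zero):
        u[any_zero] = 0.0
        rows = np.nonzero(any_zero)[0]
        first = np.argmax(zero[rows], axis=1)
        u[rows, first] = 1.0
    return u


def xie_beni(partition: FuzzyPartition, X: np.ndarray) -> float:
    """Xie-Beni validity index: compactness over minimum centroid separation.

    ``XB = sum u^m d^2 / (n * min_{i != j} d^2(v_i, v_j))`` in the
    partition's own metric; smaller is better.  Undefined (inf) for c = 1
    or coincident centroids.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if partition.metric == "cosine":
        X = _normalize_rows(X)
    v = partition.centroids
    c = v.shape[0]
    if c < 2:
        return np.inf
    sep = _sq_distances(v, v, partition.metric)
    min_sep = sep[~np.eye(c, dtype=bool)].min()
    if min_sep <= 1e-12:
        return np.inf
    d2 = _sq_distances(X, v, partition.metric)
    num = float((partition.memberships**partition.fuzziness_m * d2).sum())
    return num / (X.shape[0] * min_sep)


def select_n_clusters(
    X: np.ndarray,
    c_range: Sequence[int] = range(2, 9),
    m: float = DEFAULT_FUZZINESS,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 300,
    metric: str = "cosine",
) -> Tuple[int, pd.DataFrame, Dict[int, FuzzyPartition]]:
    """Unsupervised cluster-count search minimizing the Xie-Beni index.

    For each candidate c the FCM run with the lowest objective across
    ``restarts`` seeded restarts is retained and scored; the c with the
    smallest index wins.  Returns ``(c_star, table, best_partitions)``
    where ``table`` lists c, Xie-Beni index and objective for audit.
    Defaults to the cosine (correlation-similarity) metric, the
    convention for z-scored BOLD time courses (module docstring).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    c_range = [int(c) for c in c_range]
    if any(c < 2 or c > n - 1 for c in c_range):
        raise ValueError(f"c_range must lie within [2, n-1] = [2, {n - 1}]")
    rows = []
    best_parts: Dict[int, FuzzyPartition] = {}
    for c in c_range:
        best: Optional[FuzzyPartition] = None
        for r in range(restarts):
            sub_seed = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(c, r)).generate_state(1)[0]
                % (2**31)
            )
            part = fcm(X, c, m=m, tol=tol, max_iter=max_iter, seed=sub_seed,
                       metric=metric)
            if best is None or part.objective < best.objective:
                best = part
        idx = xie_beni(best, X)
        best_parts[c] = best
        rows.append({"c": c, "xie_beni": idx, "objective": best.objective})
    table = pd.DataFrame(rows)
    if not np.any(np.isfinite(table["xie_beni"])):
        raise ValueError("all validity indices are non-finite (degenerate data)")
    c_star = int(table.loc[table["xie_beni"].idxmin(), "c"])
    return c_star, table, best_parts


def harden(partition: FuzzyPartition) -> np.ndarray:
    """Maximum-membership label per voxel (0-based); ties break to the
    lowest cluster index."""
    return np.argmax(partition.memberships, axis=1)


def to_label_map(
    labels: np.ndarray, voxel_index: np.ndarray, grid_shape
) -> np.ndarray:
    """Embed 0-based label vector into a 3-D map (background 0, clusters
    1..c)."""
    out = np.zeros(grid_shape, dtype=np.int32)
    out[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = labels + 1
    return out


def _dice_matrix(labels_a: np.ndarray, labels_b: np.ndarray, c: int) -> np.ndarray:
    dice = np.zeros((c, c))
    for i in range(c):
        a = labels_a == i
        na = a.sum()
        for j in range(c):
            b = labels_b == j
            denom = na + b.sum()
            dice[i, j] = 2.0 * np.count_nonzero(a & b) / denom if denom else 1.0
    return dice


def _consensus(aligned: np.ndarray, c: int) -> np.ndarray:
    # per-voxel modal label; ties to the lowest label
    counts = np.stack([(aligned == k).sum(axis=0) for k in range(c)])
    return np.argmax(counts, axis=0)


def match_clusters(
    partitions: Sequence[FuzzyPartition],
    reference: Optional[np.ndarray] = None,
    n_passes: int = 2,
) -> List[np.ndarray]:
    """Align cluster labels across subjects by Dice-optimal assignment.

    Each subject's hardened labeling is matched to the reference (first
    subject by default) with an exact linear assignment maximizing total
    Dice; a consensus labeling is then rebuilt and the matching repeated
    (``n_passes`` total).  Returns one permutation per subject where
    ``perm[k]`` is the aligned index of the subject's original cluster k.
    """
    cs = {p.n_clusters for p in partitions}
    if len(cs) != 1:
        raise ValueError(f"cluster counts differ across subjects: {sorted(cs)}")
    c = cs.pop()
    hardened = np.stack([harden(p) for p in partitions])
    ref = hardened[0].copy() if reference is None else np.asarray(reference)
    perms = [np.arange(c) for _ in partitions]
    for _ in range(n_passes):
        aligned = np.empty_like(hardened)
        for s in range(hardened.shape[0]):
            dice = _dice_matrix(hardened[s], ref, c)
            row, col = linear_sum_assignment(-dice)
            perm = np.empty(c, dtype=int)
            perm[row] = col
            perms[s] = perm
            aligned[s] = perm[hardened[s]]
        ref = _consensus(aligned, c)
    return perms


def cluster_probability_maps(
    aligned_labels: Sequence[np.ndarray],
    n_clusters: int,
    voxel_index: np.ndarray,
    grid_shape,
) -> Dict[int, np.ndarray]:
    """Per-cluster percent maps: 100 x frequency of assignment across
    subjects at each target voxel (raw [0, 100] values; see
    ``apply_display_floor`` for the reporting convention)."""
    stack = np.stack([np.asarray(l) for l in aligned_labels])
    out = {}
    for k in range(n_clusters):
        frac = 100.0 * (stack == k).mean(axis=0)
        vol = np.zeros(grid_shape)
        vol[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = frac
        out[k] = vol
    return out


def apply_display_floor(pmap: np.ndarray, floor: float = 10.0) -> np.ndarray:
    """Reporting-layer floor: probabilities below ``floor`` percent are
    blanked (set to 0), so displayed values lie in [floor, 100]."""
    out = np.asarray(pmap, dtype=float).copy()
    out[(out > 0) & (out < floor)] = 0.0
    return out


def label_clusters_by_network(
    partition: FuzzyPartition,
    X_time: np.ndarray,
    network_timecourses: np.ndarray,
    network_labels: Sequence[str],
    ambiguity_margin: float = 0.05,
) -> List[dict]:
    """Name each cluster after the network its centroid course tracks best.

    The cluster centroid time course is the membership-weighted (u^m) mean
    of the voxel time courses; it is correlated with every candidate
    network course.  When the cluster count equals the number of networks
    the assignment is made injective by exact assignment optimization;
    otherwise each cluster takes its best-correlated network.  Clusters
    whose top-2 correlations differ by less than ``ambiguity_margin`` are
    flagged ambiguous (but still labeled).
    """
    X_time = np.asarray(X_time, dtype=float)
    S = np.asarray(network_timecourses, dtype=float)
    um = partition.memberships**partition.fuzziness_m
    cent_courses = (um.T @ X_time) / um.sum(axis=0)[:, None]  # (c, t)
    c, n_net = cent_courses.shape[0], S.shape[1]
    corr = np.zeros((c, n_net))
    for i in range(c):
        for j in range(n_net):
            corr[i, j] = np.corrcoef(cent_courses[i], S[:, j])[0, 1]
    if c == n_net:
        row, col = linear_sum_assignment(-corr)
        assign = dict(zip(row, col))
    else:
        assign = {i: int(np.argmax(corr[i])) for i in range(c)}
    out = []
    for i in range(c):
        j = assign[i]
        order = np.sort(corr[i])[::-1]
        ambiguous = bool(len(order) > 1 and (order[0] - order[1]) < ambiguity_margin)
        out.append(
            {
                "cluster": i,
                "network": network_labels[j],
                "correlation": float(corr[i, j]),
                "ambiguous": ambiguous,
            }
        )
    return out
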