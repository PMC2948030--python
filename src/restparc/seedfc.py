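"""Seed-based functional connectivity mapping.

Each seed region's averaged BOLD time course, z-normalized and
sequentially orthogonalized against the preceding seeds, enters a single
voxelwise general linear model together with an intercept, 9 tissue-derived
nuisance covariates (global / white-matter / CSF course, temporal
derivative and square of each) and the 6 rigid-body motion parameters.
Temporal autocorrelation is handled by per-voxel AR(1) prewhitening
(quasi-differencing on the estimated lag-1 coefficient) before the final
fit, yielding one t-statistic map per seed.  Multiple comparisons are
controlled at the cluster level with a Monte-Carlo-calibrated minimum
cluster extent, and group inference uses a random-effects model on the
per-subject seed betas with age and sex as covariates.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .preprocess import BoldRun, smooth_gaussian

__all__ = [
    "Roi",
    "RoiSet",
    "DesignMatrix",
    "StatMap",
    "GLMResult",
    "read_roi_table",
    "write_roi_table",
    "default_seed_rois",
    "validate_rois",
    "extract_roi_timecourse",
    "build_nuisance",
    "orthogonalize_seeds",
    "prewhiten",
    "fit_glm",
    "seed_fc_map",
    "monte_carlo_cluster_threshold",
    "threshold_clusters",
    "group_random_effects",
    "probability_map",
]

T_CAP = 1e6  # reported |t| ceiling for numerically exact fits (SE ~ 0)


# --------------------------------------------------------------------------
# ROI geometry
# --------------------------------------------------------------------------

@dataclasses.dataclass
class Roi:
    """A cubic seed region: centre voxel, edge length in mm, optional
    bilateral flag (bilateral seeds include the cube mirrored across the
    x midline and average both cubes' voxels)."""

    label: str
    center_voxel: Tuple[int, int, int]
    edge_mm: float = 5.0  # 5 mm edge -> 125 mm^3 seed volume
    bilateral: bool = False

    def _half_extent(self, voxel_size_mm) -> Tuple[int, int, int]:
        # edge rounded to the nearest odd voxel count per axis, minimum 1
        halves = []
        for vs in voxel_size_mm:
            n_vox = max(1, int(np.round(self.edge_mm / vs)))
            if n_vox % 2 == 0:
                n_vox += 1 if (self.edge_mm / vs) > n_vox else -1
            n_vox = max(1, n_vox)
            halves.append(n_vox // 2)
        return tuple(halves)

    def voxel_indices(
        self, grid_shape, voxel_size_mm, mirrored: bool = False
    ) -> np.ndarray:
        """(k, 3) int array of the cube's voxel indices; raises if any part
        of the cube falls outside the grid."""
        cx, cy, cz = self.center_voxel
        if mirrored:
            cx = grid_shape[0] - 1 - cx
        hx, hy, hz = self._half_extent(voxel_size_mm)
        lo = (cx - hx, cy - hy, cz - hz)
        hi = (cx + hx, cy + hy, cz + hz)
        if any(l < 0 for l in lo) or any(h >= n for h, n in zip(hi, grid_shape)):
            raise ValueError(
                f"ROI '{self.label}' cube {lo}..{hi} falls outside grid {tuple(grid_shape)}"
            )
        xs, ys, zs = np.meshgrid(
            np.arange(lo[0], hi[0] + 1),
            np.arange(lo[1], hi[1] + 1),
            np.arange(lo[2], hi[2] + 1),
            indexing="ij",
        )
        return np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)

    def mask(self, grid_shape, voxel_size_mm) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        idx = self.voxel_indices(grid_shape, voxel_size_mm)
        m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        if self.bilateral:
            idx2 = self.voxel_indices(grid_shape, voxel_size_mm, mirrored=True)
            m[idx2[:, 0], idx2[:, 1], idx2[:, 2]] = True
        return m


@dataclasses.dataclass
class RoiSet:
    """Ordered seed list; order matters because seed orthogonalization is
    sequential in list order."""

    rois: List[Roi]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate ROI labels")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def check_geometry(self, grid_shape, voxel_size_mm) -> None:
        """All cubes inside the grid and pairwise non-overlapping."""
        occupied = np.zeros(grid_shape, dtype=np.int32)
        for roi in self.rois:
            occupied += roi.mask(grid_shape, voxel_size_mm)
        if occupied.max() > 1:
            raise ValueError("ROIs overlap")


def read_roi_table(path) -> RoiSet:
    """Read the tab-separated ROI file: label  cx  cy  cz  edge_mm  bilateral."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "cx", "cy", "cz", "edge_mm", "bilateral"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    rois = [
        Roi(
            label=str(r.label),
            center_voxel=(int(r.cx), int(r.cy), int(r.cz)),
            edge_mm=float(r.edge_mm),
            bilateral=bool(r.bilateral),
        )
        for r in df.itertuples()
    ]
    return RoiSet(rois)


def write_roi_table(rois: RoiSet, path) -> None:
    rows = [
        {
            "label": r.label,
            "cx": r.center_voxel[0],
            "cy": r.center_voxel[1],
            "cz": r.center_voxel[2],
            "edge_mm": r.edge_mm,
            "bilateral": int(r.bilateral),
        }
        for r in rois
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_seed_rois(atlas, edge_mm: float = 5.0) -> RoiSet:
    """One cubic seed per network, centred on the network's peak weight
    inside the target region."""
    rois = [
        Roi(label=lab, center_voxel=atlas.network_peak_in_target(k), edge_mm=edge_mm)
        for k, lab in enumerate(atlas.labels)
    ]
    return RoiSet(rois)


def validate_rois(
    rois: RoiSet,
    gm_masks: Sequence[np.ndarray],
    voxel_size_mm,
    min_overlap: float = 0.70,
) -> pd.DataFrame:
    """Across-subject mean gray-matter coverage per ROI; pass iff >= min_overlap
    (inclusive at the boundary)."""
    if len(gm_masks) < 1:
        raise ValueError("need at least one subject GM mask")
    grid = gm_masks[0].shape
    rows = []
    for roi in rois:
        m = roi.mask(grid, voxel_size_mm)
        fracs = [gm[m].mean() for gm in gm_masks]
        frac = float(np.mean(fracs))
        rows.append({"label": roi.label, "gm_overlap": frac, "passed": frac >= min_overlap})
    return pd.DataFrame(rows)


def extract_roi_timecourse(run: BoldRun, roi: Roi) -> np.ndarray:
    """Arithmetic mean over the ROI's in-brain voxels at each time point."""
    m = roi.mask(run.grid_shape, run.voxel_size_mm) & run.brain_mask
    if not np.any(m):
        raise ValueError(f"ROI '{roi.label}' does not intersect the brain mask")
    return run.data[m].mean(axis=0)


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------

@dataclasses.dataclass
class DesignMatrix:
    values: np.ndarray  # (t, p)
    names: List[str]
    roles: List[str]  # intercept | seed | nuisance_tissue | nuisance_global | motion

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.values.shape[1] != len(self.names) or len(self.names) != len(self.roles):
            raise ValueError("names/roles/values column mismatch")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("design matrix is rank deficient: " +
                             ", ".join(_dependent_columns(self.values, self.names)))

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def columns_of(self, role: str) -> List[int]:
        return [j for j, r in enumerate(self.roles) if r == role]


def _dependent_columns(X: np.ndarray, names: Sequence[str]) -> List[str]:
    """Columns whose removal restores full rank (diagnostic for errors)."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[j] for j in range(len(names)) if j < len(diag) and diag[j] < tol]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd < 1e-12 * max(1.0, np.abs(x).max()):
        raise ValueError("cannot z-normalize a (near-)constant series")
    return (x - x.mean()) / sd


def orthogonalize_seeds(
    seed_ts: Sequence[np.ndarray], labels: Optional[Sequence[str]] = None
) -> List[np.ndarray]:
    """Sequential Gram-Schmidt in seed order, each output z-normalized.

    The first seed is only z-normalized; each later seed is residualized
    against all previous orthogonalized seeds, so each regressor carries the
    variance unique to its ROI given the earlier ones.  Seed order therefore
    matters for every seed but the first.
    """
    if len(seed_ts) == 0:
        raise ValueError("need at least one seed time course")
    labels = list(labels) if labels is not None else [f"seed{i}" for i in range(len(seed_ts))]
    out: List[np.ndarray] = []
    for i, ts in enumerate(seed_ts):
        v = _zscore(np.asarray(ts, dtype=float))
        orig_norm = np.linalg.norm(v)
        for b in out:
            v = v - (v @ b) / (b @ b) * b
        if np.linalg.norm(v) < 1e-8 * orig_norm:
            raise ValueError(
                f"seed '{labels[i]}' is collinear with preceding seeds"
            )
        out.append(_zscore(v))
    return out


def build_nuisance(run: BoldRun, mode: str = "expanded") -> DesignMatrix:
    """Nuisance block: tissue/global covariates plus 6 motion parameters.

    ``mode='expanded'`` (default) expands each of the three source courses
    (global mean, white matter, CSF) into the course itself, its first
    temporal derivative and its square, i.e. 9 covariates; ``mode='plain'``
    keeps just the 3 courses.  All columns are mean-centered.  All-zero
    motion columns are dropped with a warning.
    """
    if not np.any(run.wm_mask):
        raise ValueError("empty white-matter mask")
    if not np.any(run.csf_mask):
        raise ValueError("empty CSF mask")
    sources = {
        "global": run.data[run.brain_mask].mean(axis=0),
        "wm": run.data[run.wm_mask].mean(axis=0),
        "csf": run.data[run.csf_mask].mean(axis=0),
    }
    cols, names, roles = [], [], []
    for name, c in sources.items():
        c = c - c.mean()
        role = "nuisance_global" if name == "global" else "nuisance_tissue"
        if mode == "expanded":
            block = [c, np.gradient(c), c**2 - (c**2).mean()]
            suffixes = ["", "_deriv", "_sq"]
        elif mode == "plain":
            block, suffixes = [c], [""]
        else:
            raise ValueError(f"unknown nuisance mode '{mode}'")
        for b, sfx in zip(block, suffixes):
            cols.append(b - b.mean())
            names.append(name + sfx)
            roles.append(role)
    motion = run.motion - run.motion.mean(axis=0)
    for j in range(6):
        col = motion[:, j]
        if np.allclose(col, 0.0):
            warnings.warn(f"motion column {j} is all zero; dropped")
            continue
        cols.append(col)
        names.append(f"motion{j}")
        roles.append("motion")
    return DesignMatrix(np.column_stack(cols), names, roles)


# --------------------------------------------------------------------------
# GLM with AR(1) prewhitening
# --------------------------------------------------------------------------

@dataclasses.dataclass
class GLMResult:
    beta: np.ndarray
    t: np.ndarray
    se: np.ndarray
    dof: int
    sigma2: float
    capped: np.ndarray  # bool flags where |t| hit the cap


def fit_glm(y: np.ndarray, X) -> GLMResult:
    """Ordinary least squares with classical t statistics.

    ``t_j = beta_j / SE(beta_j)``, ``dof = t - p``.  An SE numerically at
    zero (perfect fit) yields a capped, flagged t.
    """
    Xv = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    names = X.names if isinstance(X, DesignMatrix) else [
        f"x{j}" for j in range(Xv.shape[1])
    ]
    y = np.asarray(y, dtype=float)
    t_len, p = Xv.shape
    if t_len <= p:
        raise ValueError(f"need more time points ({t_len}) than regressors ({p})")
    if np.linalg.matrix_rank(Xv) < p:
        raise ValueError(
            "rank-deficient design; dependent columns: "
            + ", ".join(_dependent_columns(Xv, names))
        )
    xtx = Xv.T @ Xv
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (Xv.T @ y)
    resid = y - Xv @ beta
    dof = t_len - p
    rss = float(resid @ resid)
    sigma2 = rss / dof
    var = sigma2 * np.diag(xtx_inv)
    se = np.sqrt(np.maximum(var, 0.0))
    scale = np.abs(beta).max() if beta.size else 1.0
    capped = se < 1e-12 * max(1.0, scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    t = np.where(capped, np.sign(beta) * T_CAP, t)
    return GLMResult(beta=beta, t=t, se=se, dof=dof, sigma2=sigma2, capped=capped)


def _lag1_autocorr(resid: np.ndarray, y_scale: float = 1.0) -> float:
    denom = float(resid @ resid)
    # residuals at rounding-error level carry no autocorrelation information
    if denom <= 1e-16 * max(y_scale, 1e-300):
        return 0.0
    return float(resid[1:] @ resid[:-1]) / denom


def _quasi_difference(v: np.ndarray, rho: float) -> np.ndarray:
    out = np.empty_like(v, dtype=float)
    out[0] = np.sqrt(1.0 - rho**2) * v[0]
    out[1:] = v[1:] - rho * v[:-1]
    return out


def prewhiten(y: np.ndarray, X) -> Tuple[np.ndarray, np.ndarray, float]:
    """AR(1) prewhitening by quasi-differencing.

    The lag-1 autocorrelation rho of the OLS residuals is estimated, then y
    and every design column are quasi-differenced (first row scaled by
    sqrt(1 - rho^2) so the rho = 0 path is exactly the identity and the row
    count is preserved).  Estimates with |rho| >= 1 are clipped to +-0.95
    with a warning.
    """
    Xv = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] <= Xv.shape[1] + 2:
        raise ValueError("too few time points for prewhitening")
    res = fit_glm(y, Xv)
    resid = y - Xv @ res.beta
    rho = _lag1_autocorr(resid, y_scale=float(y @ y))
    if abs(rho) >= 1.0:
        warnings.warn(f"AR(1) estimate {rho:.3f} out of range; clipped to +-0.95")
        rho = float(np.clip(rho, -0.95, 0.95))
    if rho == 0.0:
        return y, Xv, 0.0
    yw = _quasi_difference(y, rho)
    Xw = np.column_stack([_quasi_difference(Xv[:, j], rho) for j in range(Xv.shape[1])])
    return yw, Xw, rho


def _ar1_glm_batch(Y: np.ndarray, X: np.ndarray):
    """Prewhitened GLM for many series sharing one design.

    Y is (t, n).  For each column the AR(1) coefficient is estimated from
    its OLS residuals, then the quasi-differenced normal equations are
    assembled from precomputed matrices: X'X(rho), X'y(rho) and y'y(rho)
    are quadratic polynomials in rho, so the whole batch reduces to one
    stacked (n, p, p) solve.  Identical to the per-series scalar path.

    Returns (beta (p, n), t (p, n), dof, rho (n,)).
    """
    t_len, p = X.shape
    n = Y.shape[1]
    dof = t_len - p
    # OLS pass for residual autocorrelation
    pinv = np.linalg.pinv(X)
    B0 = pinv @ Y
    R = Y - X @ B0
    denom = np.einsum("tn,tn->n", R, R)
    num = np.einsum("tn,tn->n", R[1:], R[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    rho = np.clip(rho, -0.95, 0.95)

    x0 = X[0]
    Xc, Xl = X[1:], X[:-1]
    A = Xc.T @ Xc + np.outer(x0, x0)
    Bm = Xc.T @ Xl
    Bm = Bm + Bm.T
    C = Xl.T @ Xl - np.outer(x0, x0)
    XtX = A[None] - rho[:, None, None] * Bm[None] + (rho**2)[:, None, None] * C[None]

    Yc, Yl = Y[1:], Y[:-1]
    y0 = Y[0]
    a = Xc.T @ Yc + np.outer(x0, y0)  # (p, n)
    b = Xc.T @ Yl + Xl.T @ Yc
    d = Xl.T @ Yl - np.outer(x0, y0)
    Xty = (a - rho[None] * b + (rho**2)[None] * d).T[:, :, None]  # (n, p, 1)

    yy = np.einsum("tn,tn->n", Yc, Yc) + y0**2
    yly = np.einsum("tn,tn->n", Yc, Yl)
    yll = np.einsum("tn,tn->n", Yl, Yl) - y0**2
    yty = yy - 2 * rho * yly + rho**2 * yll

    beta = np.linalg.solve(XtX, Xty)  # (n, p, 1)
    rss = yty - np.einsum("npi,npi->n", beta, Xty)
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / dof
    XtX_inv = np.linalg.inv(XtX)
    var = sigma2[:, None] * np.einsum("npp->np", XtX_inv)
    se = np.sqrt(np.maximum(var, 0.0))  # (n, p)
    beta = beta[:, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    t = np.where(se < 1e-12, np.sign(beta) * T_CAP, t)
    return beta.T, t.T, dof, rho


# --------------------------------------------------------------------------
# Statistic maps and cluster-level correction
# --------------------------------------------------------------------------

@dataclasses.dataclass
class StatMap:
    """Per-voxel t statistics with threshold metadata.

    ``labels``, when set, is a 3-D integer map: positive integers index
    retained positive-t clusters, negative integers retained negative-t
    clusters, 0 is background.
    """

    t_values: np.ndarray
    dof: int
    voxel_p: Optional[float] = None
    cluster_k: Optional[int] = None
    corrected_alpha: Optional[float] = None
    labels: Optional[np.ndarray] = None
    beta_values: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.dof < 1:
            raise ValueError("dof must be >= 1")
        if self.cluster_k is not None and self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")


_STRUCT_6 = ndimage.generate_binary_structure(3, 1)  # face connectivity


def seed_fc_map(
    run: BoldRun,
    rois: RoiSet,
    nuisance_mode: str = "expanded",
    orthogonalize: bool = True,
) -> Dict[str, StatMap]:
    """Voxelwise seed-connectivity t-maps from one joint prewhitened GLM.

    The run must already be preprocessed (detrended, band-passed, smoothed
    for this branch).  All seeds enter a single model together with the
    intercept and nuisance block; with ``orthogonalize=False`` each seed is
    fit in its own model instead (robustness variant).
    """
    rois.check_geometry(run.grid_shape, run.voxel_size_mm)
    seed_courses = [extract_roi_timecourse(run, roi) for roi in rois]
    labels = [roi.label for roi in rois]
    for lab, ts in zip(labels, seed_courses):
        if np.allclose(ts, 0.0):
            raise ValueError(f"seed '{lab}' has an all-zero time course")
    nuis = build_nuisance(run, mode=nuisance_mode)
    Y = run.data[run.brain_mask].T.astype(float)  # (t, n)
    t_len = Y.shape[0]
    intercept = np.ones(t_len)

    def _fit(seed_block: np.ndarray, seed_names: List[str]) -> Dict[str, StatMap]:
        X = np.column_stack([intercept, seed_block, nuis.values])
        beta, t, dof, _ = _ar1_glm_batch(Y, X)
        out = {}
        for j, lab in enumerate(seed_names, start=1):
            tmap = np.zeros(run.grid_shape)
            bmap = np.zeros(run.grid_shape)
            tmap[run.brain_mask] = t[j]
            bmap[run.brain_mask] = beta[j]
            out[lab] = StatMap(
                t_values=tmap, dof=dof, beta_values=bmap, mask=run.brain_mask
            )
        return out

    if orthogonalize:
        ortho = orthogonalize_seeds(seed_courses, labels)
        return _fit(np.column_stack(ortho), labels)
    result: Dict[str, StatMap] = {}
    for lab, ts in zip(labels, seed_courses):
        result.update(_fit(_zscore(ts)[:, None], [lab]))
    return result


def monte_carlo_cluster_threshold(
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
) -> int:
    """Minimum cluster extent K controlling family-wise error at ``alpha``.

    Simulates smooth Gaussian null volumes on the mask, z-thresholds them
    two-tailed at ``voxel_p`` and records each iteration's largest
    6-connected supra-threshold cluster; K is the smallest size whose
    exceedance probability is <= alpha.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if not (0 < voxel_p < 1 and 0 < alpha <= 1):
        raise ValueError("voxel_p and alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    z_thr = stats.norm.ppf(1.0 - voxel_p / 2.0)
    maxima = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        vol = rng.standard_normal(mask.shape)
        if fwhm_mm > 0:
            vol = smooth_gaussian(vol, fwhm_mm, voxel_size_mm)
        vals = vol[mask]
        vol = (vol - vals.mean()) / vals.std()
        supra = (np.abs(vol) >= z_thr) & mask
        lab, n_lab = ndimage.label(supra, structure=_STRUCT_6)
        if n_lab == 0:
            maxima[i] = 0
        else:
            maxima[i] = int(np.bincount(lab.ravel())[1:].max())
    for k in range(1, int(maxima.max()) + 2):
        if np.mean(maxima >= k) <= alpha:
            return k
    return int(maxima.max()) + 1


def threshold_clusters(stat_map: StatMap, voxel_p: float, k: int) -> StatMap:
    """Cluster-extent thresholding of a t-map.

    Voxels passing the two-tailed t threshold at ``voxel_p`` are grouped by
    6-connectivity, separately for positive and negative t (so clusters are
    sign-pure), and clusters of at least ``k`` voxels are retained: positive
    clusters get labels 1, 2, ...; negative clusters -1, -2, ...
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    t_thr = stats.t.ppf(1.0 - voxel_p / 2.0, stat_map.dof)
    mask = stat_map.mask if stat_map.mask is not None else np.isfinite(stat_map.t_values)
    t = np.where(mask, stat_map.t_values, 0.0)
    labels = np.zeros(stat_map.t_values.shape, dtype=np.int32)
    for sign in (1, -1):
        supra = (sign * t) >= t_thr
        lab, n_lab = ndimage.label(supra, structure=_STRUCT_6)
        next_idx = 1
        for comp in range(1, n_lab + 1):
            members = lab == comp
            if members.sum() >= k:
                labels[members] = sign * next_idx
                next_idx += 1
    return dataclasses.replace(
        stat_map, voxel_p=voxel_p, cluster_k=k, labels=labels
    )


def group_random_effects(
    subject_maps: Sequence[np.ndarray],
    ages: Sequence[float],
    sexes: Sequence[int],
    mask: Optional[np.ndarray] = None,
) -> StatMap:
    """Random-effects group map controlling for age and sex.

    Per voxel, the subject-level betas are regressed on an intercept plus
    mean-centered age and sex; the reported t is the intercept's (the group
    mean effect adjusted for covariates), dof = n - 3.  Voxels with zero
    between-subject residual variance are flagged undefined (NaN).
    """
    maps = np.stack([np.asarray(m, dtype=float) for m in subject_maps])
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for random-effects analysis")
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes, dtype=float)
    if len(ages) != n or len(sexes) != n:
        raise ValueError("covariates must be complete (one age and sex per subject)")
    G = np.column_stack([np.ones(n), ages - ages.mean(), sexes - sexes.mean()])
    p = G.shape[1]
    dof = n - p
    if dof < 1:
        raise ValueError("too few subjects for the covariate model")
    flat = maps.reshape(n, -1)
    pinv_g = np.linalg.pinv(G)
    beta = pinv_g @ flat  # (3, v)
    resid = flat - G @ beta
    rss = np.einsum("nv,nv->v", resid, resid)
    sigma2 = rss / dof
    c_var = np.linalg.pinv(G.T @ G)[0, 0]  # pinv: degenerate covariates allowed
    se0 = np.sqrt(sigma2 * c_var)
    scale = np.abs(flat).max() if flat.size else 1.0
    undefined = se0 < 1e-12 * max(1.0, scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = beta[0] / se0
    t0[undefined] = np.nan
    shape = maps.shape[1:]
    tmap = t0.reshape(shape)
    bmap = beta[0].reshape(shape)
    if mask is not None:
        tmap = np.where(mask, tmap, 0.0)
        bmap = np.where(mask, bmap, 0.0)
    return StatMap(t_values=tmap, dof=dof, beta_values=bmap, mask=mask)


def probability_map(binary_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise percentage of subjects with a positive (nonzero) entry."""
    if len(binary_maps) < 1:
        raise ValueError("need at least one map")
    shapes = {np.asarray(m).shape for m in binary_maps}
    if len(shapes) != 1:
        raise ValueError(f"grid mismatch across maps: {sorted(shapes)}")
    stack = np.stack([np.asarray(m).astype(bool) for m in binary_maps])
    return 100.0 * stack.mean(axis=0)
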