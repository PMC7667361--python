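"""Group-level inference on voxel-wise maps.

Voxel-wise general linear model (group indicator plus age, gender and
mean-FD covariates), Monte-Carlo cluster-extent correction in the style
of AFNI's AlphaSim/3dClustSim (null maximum-cluster-size distribution of
smoothed Gaussian noise, thresholded two-tailed at the voxel p), cluster
labeling by a metric connectivity radius (rmm), Cohen's d effect sizes,
demographic summary tests, partial correlations and Benjamini-Hochberg
FDR.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .fcd import smooth_map
from .types import voxel_coords_mm


# ---------------------------------------------------------------------------
# design and voxel-wise GLM
# ---------------------------------------------------------------------------

def build_design(cohort: pd.DataFrame, covariates=("age", "gender", "mean_fd")) -> tuple[np.ndarray, list[str]]:
    """Design matrix ``[intercept, group, covariates...]`` from a cohort table.

    ``group`` is coded patient = 1 / control = 0; ``gender`` F = 1 / M = 0.
    Covariates are mean-centered so the intercept stays interpretable.
    Returns ``(X, column_names)``; the group contrast is column 1.
    """
    n = len(cohort)
    cols = [np.ones(n), (cohort["group"].to_numpy() == "patient").astype(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        v = cohort[cov]
        if cov == "gender":
            v = (v == "F").astype(float)
        v = np.asarray(v, dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"covariate {cov!r} contains missing values")
        cols.append(v - v.mean())
        names.append(cov)
    return np.column_stack(cols), names


@dataclass
class StatMap:
    """Voxel-wise t statistics for one contrast."""

    t: np.ndarray
    p: np.ndarray
    df: int
    beta: np.ndarray | None = None
    residuals: np.ndarray | None = None  # (n_subjects, x, y, z), optional


def fit_voxel_glm(
    maps: np.ndarray,
    design: np.ndarray,
    mask: np.ndarray,
    contrast_col: int = 1,
    keep_residuals: bool = False,
    column_names: list[str] | None = None,
) -> StatMap:
    """Ordinary least squares per mask voxel; t for one design column.

    ``maps`` is ``(n_subjects, x, y, z)``. The two-tailed p comes from the
    t distribution at ``df = n - rank(design)``. A rank-deficient design
    raises, naming the collinear columns.
    """
    maps = np.asarray(maps, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    design = np.asarray(design, dtype=np.float64)
    n, p = design.shape
    if maps.shape[0] != n:
        raise ValueError(f"{maps.shape[0]} maps for {n} design rows")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        # identify offending columns by pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(design, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        names = (
            [column_names[j] for j in bad] if column_names is not None else bad
        )
        raise ValueError(f"design matrix is rank deficient; collinear columns: {names}")
    df = n - rank
    if df < 1:
        raise ValueError("no residual degrees of freedom")

    y = maps[:, mask]  # (n, n_vox)
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    # numerically-zero residual variance (e.g. identical maps) -> t = 0
    scale = np.maximum((y**2).mean(axis=0), 1.0)
    degenerate = sigma2 <= 1e-24 * scale
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[contrast_col, contrast_col], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate | (se == 0), 0.0, beta[contrast_col] / se)
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    t_map = np.zeros(mask.shape)
    p_map = np.ones(mask.shape)
    b_map = np.zeros(mask.shape)
    t_map[mask] = t
    p_map[mask] = pval
    b_map[mask] = beta[contrast_col]
    res = None
    if keep_residuals:
        res = np.zeros((n,) + mask.shape)
        res[:, mask] = resid
    return StatMap(t=t_map, p=p_map, df=df, beta=b_map, residuals=res)


# ---------------------------------------------------------------------------
# cluster labeling
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """A suprathreshold cluster of voxels."""

    indices: np.ndarray  # (size, 3) voxel indices
    sign: int  # +1 or -1
    peak_index: np.ndarray  # (3,)
    peak_stat: float
    peak_mm: np.ndarray  # (3,)

    @property
    def size(self) -> int:
        return self.indices.shape[0]

    def mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[tuple(self.indices.T)] = True
        return out


def _connected_components(indices: np.ndarray, coords_mm: np.ndarray, rmm: float):
    """Group voxels whose centers are within ``rmm`` mm (transitively).

    KD-tree pairs + union-find; independent of voxel enumeration order.
    """
    n = indices.shape[0]
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = cKDTree(coords_mm)
    for a, b in tree.query_pairs(rmm + 1e-9):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(n)])
    return [np.flatnonzero(roots == r) for r in np.unique(roots)]


def label_clusters(
    stat: np.ndarray,
    threshold: float,
    affine: np.ndarray,
    rmm: float = 5.0,
    mask: np.ndarray | None = None,
) -> list[Cluster]:
    """Suprathreshold clusters of a statistic map, two-tailed.

    Positive (``stat > threshold``) and negative (``stat < -threshold``)
    voxels are labeled separately; two voxels join a cluster iff their
    centers are within ``rmm`` mm (on a 3 mm grid, rmm = 5 connects face
    and edge but not corner neighbours). Clusters are sorted by
    descending size.
    """
    stat = np.asarray(stat, dtype=np.float64)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        sel = stat * sign > threshold
        if mask is not None:
            sel &= np.asarray(mask, dtype=bool)
        idx = np.argwhere(sel)
        if idx.size == 0:
            continue
        coords = voxel_coords_mm(idx, affine)
        for comp in _connected_components(idx, coords, rmm):
            members = idx[comp]
            vals = stat[tuple(members.T)]
            peak_local = np.argmax(vals * sign)
            clusters.append(
                Cluster(
                    indices=members,
                    sign=sign,
                    peak_index=members[peak_local],
                    peak_stat=float(vals[peak_local]),
                    peak_mm=voxel_coords_mm(members[peak_local], affine)[0],
                )
            )
    clusters.sort(key=lambda c: (-c.size, -abs(c.peak_stat)))
    return clusters


# ---------------------------------------------------------------------------
# Monte-Carlo cluster-extent threshold (AlphaSim-style)
# ---------------------------------------------------------------------------

@dataclass
class AlphaSimConfig:
    """Monte-Carlo null simulation parameters.

    ``rmm``: cluster connectivity radius (mm); ``fwhm``: smoothness of the
    simulated noise (mm, the applied smoothing of the analyzed maps);
    ``iterations``: Monte-Carlo draws; ``voxel_p``: two-tailed
    voxel-level p; ``alpha``: corrected cluster-level level.
    """

    rmm: float = 5.0
    fwhm: float = 6.0
    iterations: int = 1000
    voxel_p: float = 0.001
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.voxel_p <= 0:
            raise ValueError("voxel_p must be positive")
        # voxel_p >= 1 is tolerated as the degenerate everything-survives bound
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def extent_threshold(null_max_sizes: np.ndarray, alpha: float) -> int:
    """Smallest k with P(max null cluster >= k) <= alpha."""
    null_max_sizes = np.asarray(null_max_sizes)
    n = null_max_sizes.size
    for k in range(1, int(null_max_sizes.max(initial=0)) + 2):
        if np.count_nonzero(null_max_sizes >= k) / n <= alpha:
            return k
    return int(null_max_sizes.max(initial=0)) + 1


def alphasim_extent(
    mask: np.ndarray,
    affine: np.ndarray,
    config: AlphaSimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[int, np.ndarray]:
    """Monte-Carlo cluster-extent threshold under smooth Gaussian noise.

    Each iteration fills the grid with unit Gaussian noise, smooths it to
    ``config.fwhm``, re-standardizes within the mask, thresholds
    two-tailed at ``voxel_p``, labels positive and negative clusters
    separately (connectivity ``rmm``) and records the pooled maximum
    cluster size. Returns ``(k_min, null_max_sizes)`` where ``k_min`` is
    the smallest extent whose null exceedance probability is <= alpha; a
    ``k_min`` of ``mask_size + 1`` means no cluster can pass.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.voxel_p >= 1:
        zcrit = -np.inf
    else:
        zcrit = stats.norm.isf(config.voxel_p / 2.0)
    maxima = np.empty(config.iterations, dtype=np.int64)
    for it in range(config.iterations):
        noise = rng.standard_normal(mask.shape)
        if config.fwhm > 0:
            noise = smooth_map(noise, config.fwhm, affine)
        vals = noise[mask]
        noise_std = vals.std()
        z = np.zeros(mask.shape)
        z[mask] = (vals - vals.mean()) / noise_std
        clusters = label_clusters(z, zcrit, affine, rmm=config.rmm, mask=mask)
        maxima[it] = max((c.size for c in clusters), default=0)
    return extent_threshold(maxima, config.alpha), maxima


def estimate_smoothness(
    maps: np.ndarray, mask: np.ndarray, affine: np.ndarray
) -> float:
    """Estimate the Gaussian-equivalent FWHM (mm) of residual maps.

    Classic neighbour-correlation estimator: along each axis the lag-1
    autocorrelation r1 of the (mask-interior) residuals gives
    ``FWHM_axis = 1.1774 * d / sqrt(-ln r1)`` for voxel spacing d; the
    geometric mean over axes is returned. Maps rougher than the voxel
    grid return 0.
    """
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim == 3:
        maps = maps[None]
    mask = np.asarray(mask, dtype=bool)
    sizes = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    fwhms = []
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        pair_mask = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        if not pair_mask.any():
            continue
        a = maps[(slice(None),) + tuple(sl_a)][:, pair_mask].ravel()
        b = maps[(slice(None),) + tuple(sl_b)][:, pair_mask].ravel()
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        r1 = (a * b).sum() / denom if denom > 0 else 0.0
        if r1 <= 0:
            fwhms.append(0.0)
        else:
            fwhms.append(1.1774 * sizes[ax] / np.sqrt(-np.log(r1)))
    if not fwhms or min(fwhms) == 0:
        return 0.0
    return float(np.exp(np.mean(np.log(fwhms))))


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

def cohen_d(values1, values2) -> float:
    """Cohen's d: standardized mean difference with pooled SD
    (``n1 + n2 - 2`` denominator)."""
    x1 = np.asarray(values1, dtype=np.float64)
    x2 = np.asarray(values2, dtype=np.float64)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 values per group")
    pooled_var = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD; Cohen's d undefined")
    return float((x1.mean() - x2.mean()) / np.sqrt(pooled_var))


def two_sample_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance Student t test from printed summary statistics.

    Returns ``(t, two-tailed p)`` at ``df = n1 + n2 - 2``. With both SDs
    zero and equal means, t is defined as 0.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        raise ValueError("zero pooled SD with unequal means")
    t = (mean1 - mean2) / np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table; 1 df."""
    table = np.asarray(table, dtype=np.float64)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariates (OLS).

    Both variables are residualized on ``[intercept | covariates]``; the p
    value comes from ``t = rho * sqrt(df / (1 - rho^2))`` with
    ``df = n - 2 - n_covariates``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or (np.asarray(covariates).size == 0):
        z = np.ones((n, 1))
        n_cov = 0
    else:
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
        z = np.column_stack([np.ones(n), cov])
        n_cov = cov.shape[1]
    if n < n_cov + 3:
        raise ValueError(f"need at least {n_cov + 3} observations, got {n}")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate residuals (zero variance after partialling)")
    rho = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    df = n - 2 - n_cov
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    return rho, float(2.0 * stats.t.sf(abs(t), df))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# cluster reporting
# ---------------------------------------------------------------------------

def cluster_report(
    clusters: list[Cluster],
    extent: int,
    value_maps: np.ndarray,
    group1: np.ndarray,
    group2: np.ndarray,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Table of surviving clusters with extracted effect sizes.

    ``value_maps`` is ``(n_subjects, x, y, z)`` of the per-subject maps to
    extract (normalized k/k0 maps for FCD contrasts); ``group1``/
    ``group2`` are boolean subject selectors (patients, controls). Cohen's
    d is computed on per-subject cluster means, group1 minus group2.
    Clusters smaller than ``extent`` are omitted; an empty table keeps the
    header.
    """
    value_maps = np.asarray(value_maps, dtype=np.float64)
    rows = []
    surviving = [c for c in clusters if c.size >= extent]
    for i, c in enumerate(surviving):
        cmask = c.mask(value_maps.shape[1:])
        means = value_maps[:, cmask].mean(axis=1)
        try:
            d = cohen_d(means[group1], means[group2])
        except ValueError:
            d = 0.0
        rows.append(
            {
                "label": labels[i] if labels else f"cluster_{i + 1}",
                "size": c.size,
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "peak_t": c.peak_stat,
                "sign": c.sign,
                "cohen_d": d,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "size", "peak_x_mm", "peak_y_mm", "peak_z_mm",
            "peak_t", "sign", "cohen_d",
        ],
    )
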