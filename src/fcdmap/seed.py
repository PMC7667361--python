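"""Seed-based intrinsic functional connectivity (iFC).

Backtracks the connectivity pattern of a region (typically a surviving
long-range-FCD difference cluster): the seed's mean time course is
correlated with every gray-matter voxel, the correlation map is
Fisher r-to-z transformed, within-group one-sample t maps define the
positive connectivity mask (BH-FDR corrected, positive mean z only), and
between-group differences reuse the voxel-wise GLM plus Monte-Carlo
cluster-extent machinery of :mod:`fcdmap.stats`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .stats import (
    AlphaSimConfig,
    StatMap,
    alphasim_extent,
    bh_fdr,
    cluster_report,
    fit_voxel_glm,
    label_clusters,
)
from .types import BoldSeries

log = logging.getLogger(__name__)

#: correlations are clamped to +-(1 - R_CLAMP_EPS) before atanh
R_CLAMP_EPS = 1e-7


@dataclass
class SeedSpec:
    """A seed region: nonempty 3D binary mask plus a label."""

    mask: np.ndarray
    label: str = "seed"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"seed {self.label!r} is empty")


def seed_timecourse(series: BoldSeries, seed: SeedSpec) -> np.ndarray:
    """Unweighted mean time course over the seed voxels."""
    if seed.mask.shape != series.grid_shape:
        raise ValueError("seed mask shape does not match the series grid")
    return np.asarray(series.data[seed.mask], dtype=np.float64).mean(axis=0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z (atanh), with |r| clamped to 1 - 1e-7 first."""
    r_arr = np.asarray(r, dtype=np.float64)
    clipped = np.clip(r_arr, -1.0 + R_CLAMP_EPS, 1.0 - R_CLAMP_EPS)
    n_clamped = int(np.count_nonzero(clipped != r_arr))
    if n_clamped:
        log.info("fisher_z: clamped %d correlation(s) at |r| = 1 - 1e-7", n_clamped)
    out = np.arctanh(clipped)
    return float(out) if np.isscalar(r) else out


@dataclass
class IfcMaps:
    """Per-subject seed correlation (r) and Fisher z maps."""

    r: np.ndarray
    z: np.ndarray
    label: str = "seed"


def ifc_map(series: BoldSeries, seed_series: np.ndarray, mask: np.ndarray, label: str = "seed") -> IfcMaps:
    """Voxel-wise Pearson correlation with a seed time course, plus Fisher z."""
    seed_series = np.asarray(seed_series, dtype=np.float64)
    if seed_series.size != series.n_volumes:
        raise ValueError("seed series length does not match the volume count")
    s = seed_series - seed_series.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("seed time course is constant; correlations undefined")
    mask = np.asarray(mask, dtype=bool)
    ts = np.asarray(series.data[mask], dtype=np.float64)
    ts = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ts, axis=1)
    norms[norms == 0] = np.inf  # constant voxels -> r = 0
    r_vals = ts @ s / (norms * s_norm)
    r = np.zeros(mask.shape)
    r[mask] = r_vals
    z = np.zeros(mask.shape)
    z[mask] = fisher_z(r_vals)
    return IfcMaps(r=r, z=z, label=label)


def group_onesample_map(
    z_maps: np.ndarray,
    mask: np.ndarray,
    p_threshold: float = 0.001,
    positive_only: bool = True,
) -> np.ndarray:
    """Binary within-group connectivity mask from per-subject z maps.

    One-sample t against zero per mask voxel; two-tailed p values are
    BH-FDR adjusted over the mask, and voxels pass iff the adjusted p is
    below ``p_threshold`` and (with ``positive_only``) the group mean z is
    positive.
    """
    z_maps = np.asarray(z_maps, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    n = z_maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for the one-sample map")
    vals = z_maps[:, mask]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    p = np.clip(2.0 * sstats.t.sf(np.abs(t), n - 1), np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)
    keep = q < p_threshold
    if positive_only:
        keep &= mean > 0
    out = np.zeros(mask.shape, dtype=bool)
    out[mask] = keep
    return out


def group_difference_ifc(
    z_maps: np.ndarray,
    design: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    alphasim: AlphaSimConfig,
    voxel_p: float = 0.001,
    group1: np.ndarray | None = None,
    group2: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[StatMap, pd.DataFrame, int]:
    """Between-group iFC comparison on Fisher z maps.

    Identical code path to the FCD group analysis: voxel-wise GLM with
    covariates, two-tailed threshold at ``voxel_p``, Monte-Carlo extent
    threshold, cluster table with Cohen's d of the per-subject mean z in
    each surviving cluster. Returns ``(statmap, table, extent)``.
    """
    statmap = fit_voxel_glm(z_maps, design, mask)
    tcrit = sstats.t.isf(voxel_p / 2.0, statmap.df)
    clusters = label_clusters(statmap.t, tcrit, affine, rmm=alphasim.rmm, mask=mask)
    extent, _ = alphasim_extent(mask, affine, alphasim, rng=rng)
    if group1 is None:
        group1 = design[:, 1] > 0.5
    if group2 is None:
        group2 = ~group1
    table = cluster_report(clusters, extent, z_maps, group1, group2)
    return statmap, table, extent
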