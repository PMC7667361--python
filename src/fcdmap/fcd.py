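"""Voxel-wise functional connectivity density (FCD) mapping.

FCD at a voxel is its degree in the thresholded whole-mask correlation
graph: the number of other gray-matter voxels whose Pearson correlation
with it exceeds r0 (default 0.25, positive correlations only). The degree
is partitioned by anatomical (Euclidean, world-mm) distance into

* short-range FCD (sFCD): neighbours within the 12 mm sphere, and
* long-range FCD (lFCD): suprathreshold voxels beyond 12 mm,

so ``k_short + k_long`` is the total degree. Raw counts k are
Z-standardized over the mask, spatially smoothed (6 mm FWHM), and
separately normalized by the whole-mask mean count k0 (k/k0 maps used for
ROI extraction and effect sizes).

The pairwise computation is blocked so memory stays bounded; counts are
integer-exact and independent of the block size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .types import BoldSeries, voxel_coords_mm

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class FCDConfig:
    """Parameters of the FCD computation.

    ``r0``: correlation threshold (edges are strictly ``r > r0``);
    ``cutoff_mm``: anatomical distance separating short from long range
    (ties at exactly the cutoff are short-range); ``smooth_fwhm``: Gaussian
    kernel FWHM in mm applied to the Z maps; ``block_size``: voxels per
    block of the pairwise correlation computation.
    """

    r0: float = 0.25
    cutoff_mm: float = 12.0
    smooth_fwhm: float = 6.0
    block_size: int = 1024

    def __post_init__(self) -> None:
        if not -1.0 < self.r0 < 1.0:
            raise ValueError("r0 must lie strictly inside (-1, 1)")
        if self.cutoff_mm <= 0:
            raise ValueError("cutoff_mm must be positive")
        if self.smooth_fwhm < 0:
            raise ValueError("smooth_fwhm must be >= 0")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass
class FCDMaps:
    """Per-subject FCD products.

    ``k_short``/``k_long`` are raw integer edge counts (zero outside the
    mask); ``z_short``/``z_long`` the Z-standardized (and, when produced
    by :func:`compute_fcd_maps`, smoothed) maps feeding voxel-wise group
    statistics; ``norm_short``/``norm_long`` the k/k0 maps from raw counts
    used for ROI extraction; ``k0_short``/``k0_long`` the whole-mask mean
    counts.
    """

    k_short: np.ndarray
    k_long: np.ndarray
    z_short: np.ndarray | None = None
    z_long: np.ndarray | None = None
    norm_short: np.ndarray | None = None
    norm_long: np.ndarray | None = None
    k0_short: float | None = None
    k0_long: float | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# raw edge counting
# ---------------------------------------------------------------------------

def compute_fcd(
    series: BoldSeries, mask: np.ndarray, config: FCDConfig | None = None
) -> FCDMaps:
    """Count short- and long-range suprathreshold edges per mask voxel.

    For mask voxels i, j (i != j), an edge exists iff the Pearson
    correlation of their full retained time courses is strictly greater
    than ``config.r0``; it is short-range iff the center-to-center world
    distance is <= ``config.cutoff_mm``. Zero-variance voxels contribute
    no edges (their correlations are undefined) and are logged; they stay
    in the mask with count 0.
    """
    config = config or FCDConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ValueError(f"mask shape {mask.shape} != series grid {series.grid_shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    if series.n_volumes < 3:
        raise ValueError("need at least 3 volumes to correlate")

    idx = np.argwhere(mask)
    coords = voxel_coords_mm(idx, series.affine)
    ts = np.asarray(series.data[mask], dtype=np.float64)  # (n_vox, t)
    ts = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ts, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        log.warning(
            "%d zero-variance voxel(s) in mask; they contribute no edges",
            int(degenerate.sum()),
        )
        norms[degenerate] = 1.0
    ts /= norms[:, None]
    ts[degenerate] = 0.0  # correlation 0 with everything -> no edges

    n = ts.shape[0]
    k_short = np.zeros(n, dtype=np.int64)
    k_long = np.zeros(n, dtype=np.int64)
    cutoff2 = config.cutoff_mm**2
    for start in range(0, n, config.block_size):
        stop = min(start + config.block_size, n)
        r_block = ts[start:stop] @ ts.T  # (b, n)
        adj = r_block > config.r0
        adj[np.arange(start, stop) - start, np.arange(start, stop)] = False
        d2 = cdist(coords[start:stop], coords, metric="sqeuclidean")
        near = d2 <= cutoff2
        k_short[start:stop] = np.count_nonzero(adj & near, axis=1)
        k_long[start:stop] = np.count_nonzero(adj & ~near, axis=1)

    out_s = np.zeros(series.grid_shape, dtype=np.int64)
    out_l = np.zeros(series.grid_shape, dtype=np.int64)
    out_s[mask] = k_short
    out_l[mask] = k_long
    return FCDMaps(
        k_short=out_s,
        k_long=out_l,
        meta={
            "r0": config.r0,
            "cutoff_mm": config.cutoff_mm,
            "n_mask_voxels": int(n),
            "n_volumes": int(series.n_volumes),
            "n_zero_variance": int(degenerate.sum()),
        },
    )


# ---------------------------------------------------------------------------
# standardization, smoothing, normalization
# ---------------------------------------------------------------------------

def zscore_map(k_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-standardize a map over the mask (population SD); zero outside."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(k_map, dtype=np.float64)[mask]
    sd = vals.std()  # population (n) convention
    if sd == 0:
        raise ValueError("map is constant over the mask; Z scores undefined")
    out = np.zeros(k_map.shape, dtype=np.float64)
    out[mask] = (vals - vals.mean()) / sd
    return out


def smooth_map(
    map3d: np.ndarray,
    fwhm: float,
    affine: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian-smooth a 3D map with an isotropic FWHM in mm.

    ``fwhm = 0`` returns the input unchanged. With a mask, the map is
    smoothed embedded in zeros and renormalized by the smoothed mask
    indicator (avoids attenuation at the mask boundary); output is zero
    outside the mask.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    map3d = np.asarray(map3d, dtype=np.float64)
    if fwhm == 0:
        return map3d.copy()
    voxel_sizes = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    sigma_vox = fwhm * FWHM_TO_SIGMA / voxel_sizes
    if mask is None:
        return gaussian_filter(map3d, sigma=sigma_vox)
    mask = np.asarray(mask, dtype=bool)
    num = gaussian_filter(np.where(mask, map3d, 0.0), sigma=sigma_vox)
    den = gaussian_filter(mask.astype(np.float64), sigma=sigma_vox)
    out = np.zeros_like(map3d)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def normalize_k(k_map: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide a count map by its whole-mask mean k0; mask mean becomes 1."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(k_map, dtype=np.float64)[mask]
    k0 = float(vals.mean())
    if k0 == 0:
        raise ValueError("k0 = 0: no edges anywhere in the mask (degenerate input)")
    out = np.zeros(k_map.shape, dtype=np.float64)
    out[mask] = vals / k0
    return out, k0


def compute_fcd_maps(
    series: BoldSeries, mask: np.ndarray, config: FCDConfig | None = None
) -> FCDMaps:
    """Full per-subject FCD products: raw counts, smoothed Z maps, k/k0 maps.

    Order of operations for the Z maps: Z-scoring of the raw counts over
    the mask, then spatial smoothing. The k/k0 maps are computed from raw
    (unsmoothed) counts.
    """
    config = config or FCDConfig()
    maps = compute_fcd(series, mask, config)
    for rng_name in ("short", "long"):
        k = getattr(maps, f"k_{rng_name}")
        z = smooth_map(zscore_map(k, mask), config.smooth_fwhm, series.affine, mask)
        norm, k0 = normalize_k(k, mask)
        setattr(maps, f"z_{rng_name}", z)
        setattr(maps, f"norm_{rng_name}", norm)
        setattr(maps, f"k0_{rng_name}", k0)
    maps.meta["smooth_fwhm"] = config.smooth_fwhm
    return maps
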