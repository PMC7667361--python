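"""Synthetic resting-state BOLD cohorts with known connectivity structure.

The generator emulates a two-group case-control rs-fMRI study: each
subject's 4D series is a mixture of

* band-limited (0.01-0.1 Hz) *network* signals shared across spatially
  separated regions of interest (ROIs), producing long-range functional
  connections;
* a spatially smoothed, temporally band-limited *local* noise field,
  producing distance-decaying short-range correlations;
* AR(1) observation noise, a linear scanner drift and a constant baseline.

Group effects are planted with known masks: patients receive reduced
network coupling in one network (a long-range connectivity-density
deficit) and scaled local-field gain inside dedicated spheres (short-range
decreases/increases). Per-subject effect severity drives simulated
clinical scores (PSQI, STAI, BDI-II, illness duration), so
clinical-correlation analyses are also exercisable with known ground
truth.

Reproducibility: one global seed expands into per-subject substreams via
``numpy`` seed sequences keyed ``[seed, subject_index]``; cohort-level
draws (ages, genders, severities) use key ``[seed, COHORT_STREAM]``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .preprocess import bandpass_array
from .types import BoldSeries, GroundTruth

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: substream key for cohort-level draws (distinct from any subject index)
COHORT_STREAM = 999_983


@dataclass(frozen=True)
class Roi:
    """A spherical ROI: center in voxel indices, radius in mm, network id."""

    center: tuple[int, int, int]
    radius_mm: float
    network: int


@dataclass(frozen=True)
class ClinicalModel:
    """Linear clinical-score model: ``score = intercept + slope * severity + noise``.

    ``severity`` is the per-subject planted effect magnitude (0 for
    controls); scores are clipped to the instrument range ``[lo, hi]``.
    """

    intercept: float
    slope: float
    noise_sd: float
    lo: float
    hi: float
    patients_only: bool = False


def _frac_center(shape, fracs) -> tuple[int, int, int]:
    return tuple(int(round(f * (s - 1))) for f, s in zip(fracs, shape))


def default_network_rois(grid_shape, voxel_size: float = 3.0) -> tuple[Roi, ...]:
    """Two synthetic networks placed proportionally on the grid.

    On the default 24^3 grid of 3 mm voxels all same-network ROI center
    distances exceed the 12 mm short/long cutoff, so network edges are
    purely long-range. Network 0 is the one whose coupling patients lose.
    """
    fracs = [
        ((0.3, 0.3, 0.5), 0),
        ((0.7, 0.7, 0.5), 0),
        ((0.7, 0.3, 0.5), 0),
        ((0.3, 0.7, 0.5), 1),
        ((0.7, 0.5, 0.75), 1),
    ]
    return tuple(Roi(_frac_center(grid_shape, f), 2.0 * voxel_size, net) for f, net in fracs)


def default_clinical_models() -> dict[str, ClinicalModel]:
    """Clinical-score models calibrated to a chronic-insomnia cohort profile.

    Patient severity is ~N(1, 0.2^2), so e.g. PSQI lands near 13.3 +/- 2.7
    for patients and 0.9 +/- 1.0 for controls.
    """
    return {
        "PSQI": ClinicalModel(0.9, 12.4, 1.0, 0, 21),
        "STAI_s": ClinicalModel(26.2, 1.9, 4.0, 20, 80),
        "STAI_t": ClinicalModel(29.1, 3.2, 5.0, 20, 80),
        "BDI_II": ClinicalModel(4.9, 1.2, 3.0, 0, 63),
        "duration": ClinicalModel(1.0, 10.0, 5.0, 0.5, 40, patients_only=True),
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate the study conditions downstream stages expect: two
    groups of 27 subjects, 240 volumes at TR = 2 s on a 24^3 grid of 3 mm
    voxels, network signals band-limited to 0.01-0.1 Hz.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 3.0
    n_volumes: int = 240
    tr: float = 2.0
    n_per_group: int = 27
    #: None -> proportional default layout for the configured grid
    network_rois: tuple[Roi, ...] | None = None
    #: amplitude of the shared network signal per group (unit-variance signal)
    coupling_strength: dict = field(
        default_factory=lambda: {"control": 0.9, "patient": 0.9}
    )
    #: fractional coupling loss in network 0 for patients, scaled by severity
    lfcd_deficit: float = 0.6
    #: baseline amplitude of the local (short-range) field, per group
    local_gain: dict = field(default_factory=lambda: {"control": 1.0, "patient": 1.0})
    #: patient local-gain multipliers inside the planted spheres
    sfcd_decrease_gain: float = 0.55
    sfcd_increase_gain: float = 1.5
    #: centers (voxels) and radius (mm) of the planted short-range spheres;
    #: None -> proportional placement (0.5, 0.3, 0.3) / (0.5, 0.7, 0.7)
    sfcd_decrease_center: tuple[int, int, int] | None = None
    sfcd_increase_center: tuple[int, int, int] | None = None
    sfcd_sphere_radius_mm: float = 7.5
    #: FWHM (mm) of the spatial smoothing that induces short-range correlation
    local_smoothing_fwhm: float = 9.0
    band: tuple[float, float] = (0.01, 0.1)
    n_sinusoids: int = 40
    noise_ar1: float = 0.3
    drift_slope: float = 0.02
    baseline: float = 100.0
    #: signal-to-noise scale: observation-noise sd is 1/snr
    snr: float = 1.0
    #: patient severity distribution (mean, sd, clip-lo, clip-hi)
    severity_mean: float = 1.0
    severity_sd: float = 0.2
    severity_clip: tuple[float, float] = (0.4, 1.6)
    #: random-walk step scales of the motion trace (mm, radians per volume)
    motion_trans_step: float = 0.05
    motion_rot_step: float = 0.0005
    motion_severity_sd: float = 0.4
    clinical_model: dict = field(default_factory=default_clinical_models)
    age_mean: float = 41.75
    age_sd: float = 11.5
    age_range: tuple[float, float] = (25.0, 65.0)
    female_fraction: float = 17.0 / 27.0
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate YAML/JSON round-trips handing us lists
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.band = tuple(float(f) for f in self.band)
        self.severity_clip = tuple(float(v) for v in self.severity_clip)
        self.age_range = tuple(float(v) for v in self.age_range)
        if self.sfcd_decrease_center is not None:
            self.sfcd_decrease_center = tuple(int(c) for c in self.sfcd_decrease_center)
        if self.sfcd_increase_center is not None:
            self.sfcd_increase_center = tuple(int(c) for c in self.sfcd_increase_center)
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must exceed the 10-volume discard count")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        for group, c in self.coupling_strength.items():
            if not 0 <= c <= 1:
                raise ValueError(f"coupling_strength[{group!r}] must lie in [0, 1]")

    def rois(self) -> tuple[Roi, ...]:
        """The network ROIs, resolving the proportional default layout."""
        if self.network_rois is not None:
            return self.network_rois
        return default_network_rois(self.grid_shape, self.voxel_size)

    def sfcd_centers(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        dec = self.sfcd_decrease_center or _frac_center(self.grid_shape, (0.5, 0.3, 0.3))
        inc = self.sfcd_increase_center or _frac_center(self.grid_shape, (0.5, 0.7, 0.7))
        return dec, inc

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-mm transform: isotropic spacing, world origin at grid center."""
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def sphere_mask(shape, center, radius_mm: float, voxel_size: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center)) * voxel_size**2
    return d2 <= radius_mm**2


def ellipsoid_mask(shape) -> np.ndarray:
    """Brain-like compact mask: the ellipsoid inscribed in the grid."""
    semi = (np.asarray(shape) - 1) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    return sum(((g - c) / a) ** 2 for g, c, a in zip(grids, semi, semi)) <= 1.0


def roi_masks(config: SimConfig) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-ROI boolean masks and the voxel-wise network-id map (-1 outside)."""
    shape = config.grid_shape
    net_id = np.full(shape, -1, dtype=int)
    masks = []
    for i, roi in enumerate(config.rois()):
        if not all(0 <= c < s for c, s in zip(roi.center, shape)):
            raise ValueError(f"ROI {i} (center {roi.center}) lies outside the grid {shape}")
        m = sphere_mask(shape, roi.center, roi.radius_mm, config.voxel_size)
        if not m.any():
            raise ValueError(f"ROI {i} (center {roi.center}) contains no voxels")
        masks.append(m)
        net_id[m] = roi.network
    return masks, net_id


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------

def network_signal(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited signal: random sinusoids at rFFT bin
    frequencies inside the pass band (exactly band-limited by construction)."""
    t = np.arange(config.n_volumes) * config.tr
    df = 1.0 / (config.n_volumes * config.tr)
    lo_bin = int(np.ceil(config.band[0] / df))
    hi_bin = int(np.floor(config.band[1] / df))
    if hi_bin < lo_bin:
        raise ValueError("pass band contains no frequency bins; series too short")
    bins = rng.choice(
        np.arange(lo_bin, hi_bin + 1),
        size=min(config.n_sinusoids, hi_bin - lo_bin + 1),
        replace=False,
    )
    phases = rng.uniform(0, 2 * np.pi, size=bins.size)
    sig = np.sum(np.sin(2 * np.pi * np.outer(bins * df, t) + phases[:, None]), axis=0)
    sig -= sig.mean()
    return sig / sig.std()


def local_field(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated, temporally band-limited noise field.

    White noise is Gaussian-smoothed in space (kernel
    ``local_smoothing_fwhm``), band-passed in time and re-standardized per
    voxel, so every voxel carries unit variance with correlation to its
    neighbours decaying with distance.
    """
    shape = config.grid_shape + (config.n_volumes,)
    field_ = rng.standard_normal(shape).astype(np.float32)
    sigma_vox = config.local_smoothing_fwhm * FWHM_TO_SIGMA / config.voxel_size
    if sigma_vox > 0:
        field_ = gaussian_filter(field_, sigma=(sigma_vox,) * 3 + (0.0,))
    field_ = bandpass_array(field_.astype(np.float64), config.tr, *config.band)
    sd = field_.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    field_ = (field_ - field_.mean(axis=-1, keepdims=True)) / sd
    return field_.astype(np.float32)


def ar1_noise(shape, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-marginal-variance AR(1) noise along the last axis."""
    from scipy.signal import lfilter

    eps = rng.standard_normal(shape)
    if rho == 0:
        return eps
    out = lfilter([np.sqrt(1.0 - rho**2)], [1.0, -rho], eps, axis=-1)
    return out


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

def generate_motion(
    config: SimConfig, severity: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Random-walk 6-parameter rigid-body trace scaled by ``severity``.

    ``severity = 0`` yields the all-zero trace. The first volume is at the
    origin; steps are iid Gaussian with per-parameter scales
    ``motion_trans_step`` (mm) and ``motion_rot_step`` (radians).
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    if rng is None:
        rng = np.random.default_rng([config.seed, COHORT_STREAM, 7])
    steps = rng.standard_normal((config.n_volumes, 6))
    steps[:, :3] *= severity * config.motion_trans_step
    steps[:, 3:] *= severity * config.motion_rot_step
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def planted_masks(config: SimConfig) -> dict[str, np.ndarray]:
    """Ground-truth region masks for the three planted effects.

    Regions are clipped to the gray-matter (ellipsoid) mask, so effects
    are only ever planted inside analyzable tissue.
    """
    gm = ellipsoid_mask(config.grid_shape)
    masks, _ = roi_masks(config)
    lfcd = np.zeros(config.grid_shape, dtype=bool)
    for roi, m in zip(config.rois(), masks):
        if roi.network == 0:
            lfcd |= m
    dec_center, inc_center = config.sfcd_centers()
    return {
        "lfcd_decrease": lfcd & gm,
        "sfcd_decrease": gm & sphere_mask(
            config.grid_shape, dec_center,
            config.sfcd_sphere_radius_mm, config.voxel_size,
        ),
        "sfcd_increase": gm & sphere_mask(
            config.grid_shape, inc_center,
            config.sfcd_sphere_radius_mm, config.voxel_size,
        ),
    }


def generate_subject(
    config: SimConfig,
    index: int,
    group: str,
    severity: float,
    motion_severity: float = 1.0,
) -> tuple[BoldSeries, np.ndarray]:
    """One subject's BOLD series and motion trace.

    ``severity`` scales the planted deficits/gains (0 disables them, as
    for controls); the RNG substream is keyed ``[seed, index]`` so every
    subject is individually reproducible.
    """
    rng = np.random.default_rng([config.seed, index])
    _, net_id = roi_masks(config)
    planted = planted_masks(config)

    nets = sorted({roi.network for roi in config.rois()})
    net_sigs = {k: network_signal(config, rng) for k in nets}

    coupling = np.zeros(config.grid_shape, dtype=np.float32)
    base_c = config.coupling_strength[group]
    coupling[net_id >= 0] = base_c
    if group == "patient" and severity > 0:
        deficit = np.clip(1.0 - config.lfcd_deficit * severity, 0.0, 1.0)
        coupling[planted["lfcd_decrease"]] = base_c * deficit

    gain = np.full(config.grid_shape, config.local_gain[group], dtype=np.float32)
    if group == "patient" and severity > 0:
        # severity interpolates the gain multiplier away from 1
        dec = 1.0 + (config.sfcd_decrease_gain - 1.0) * severity
        inc = 1.0 + (config.sfcd_increase_gain - 1.0) * severity
        gain[planted["sfcd_decrease"]] *= max(dec, 0.0)
        gain[planted["sfcd_increase"]] *= inc

    data = np.zeros(config.grid_shape + (config.n_volumes,), dtype=np.float32)
    for k, sig in net_sigs.items():
        sel = net_id == k
        if sel.any():
            data[sel] += coupling[sel][:, None] * sig[None, :].astype(np.float32)
    if np.any(gain):
        data += gain[..., None] * local_field(config, rng)
    if config.snr > 0 and np.isfinite(config.snr):
        data += (ar1_noise(data.shape, config.noise_ar1, rng) / config.snr).astype(
            np.float32
        )
    t_centered = np.arange(config.n_volumes) - (config.n_volumes - 1) / 2.0
    data += (config.drift_slope * t_centered + config.baseline).astype(np.float32)

    motion = generate_motion(config, motion_severity, rng)
    return BoldSeries(data=data, affine=config.affine, tr=config.tr), motion


def generate_cohort(
    config: SimConfig,
) -> tuple[list[tuple[BoldSeries, np.ndarray]], pd.DataFrame, GroundTruth, np.ndarray]:
    """Generate the full two-group cohort.

    Returns ``(subjects, cohort, truth, gm_mask)`` where ``subjects`` is a
    list of ``(BoldSeries, motion_trace)`` ordered patients first, then
    controls; ``cohort`` the per-subject table (group, age, gender,
    clinical scores); ``truth`` the planted-effect ground truth; and
    ``gm_mask`` the boolean gray-matter mask.
    """
    n = config.n_per_group
    _, net_id = roi_masks(config)
    gm_mask = ellipsoid_mask(config.grid_shape)
    planted = planted_masks(config)
    for name, m in planted.items():
        if not (m <= gm_mask).all():
            raise ValueError(f"planted region {name!r} extends outside the gray-matter mask")

    crng = np.random.default_rng([config.seed, COHORT_STREAM])
    groups = ["patient"] * n + ["control"] * n
    severity = np.zeros(2 * n)
    severity[:n] = np.clip(
        crng.normal(config.severity_mean, config.severity_sd, size=n),
        *config.severity_clip,
    )
    ages = np.clip(crng.normal(config.age_mean, config.age_sd, size=2 * n), *config.age_range)
    n_female = int(round(config.female_fraction * n))
    gender_block = np.array(["F"] * n_female + ["M"] * (n - n_female))
    genders = np.concatenate([crng.permutation(gender_block), crng.permutation(gender_block)])
    motion_sev = np.clip(
        crng.normal(1.0, config.motion_severity_sd, size=2 * n), 0.2, None
    )

    subjects = []
    rows = []
    for i, group in enumerate(groups):
        series, motion = generate_subject(
            config, i, group, severity[i], motion_severity=motion_sev[i]
        )
        subjects.append((series, motion))
        row = {
            "subject": f"sub-{i:03d}",
            "group": group,
            "age": round(float(ages[i]), 1),
            "gender": genders[i],
        }
        for metric, model in config.clinical_model.items():
            if model.patients_only and group != "patient":
                row[metric] = np.nan
                continue
            raw = model.intercept + model.slope * severity[i] + crng.normal(0, model.noise_sd)
            row[metric] = float(np.clip(raw, model.lo, model.hi))
        row["mean_fd"] = np.nan  # filled by preprocessing
        rows.append(row)

    cohort = pd.DataFrame(rows)
    truth = GroundTruth(
        masks=planted,
        effects={
            "lfcd_decrease": config.lfcd_deficit,
            "sfcd_decrease": config.sfcd_decrease_gain,
            "sfcd_increase": config.sfcd_increase_gain,
        },
        severity=severity,
        network_id=net_id,
    )
    return subjects, cohort, truth, gm_mask


# ---------------------------------------------------------------------------
# on-disk outputs
# ---------------------------------------------------------------------------

def write_cohort(
    outdir,
    subjects,
    cohort: pd.DataFrame,
    truth: GroundTruth,
    gm_mask: np.ndarray,
    config: SimConfig,
) -> Path:
    """Write a generated cohort to ``outdir``.

    Layout: per-subject 4D NIfTI + whitespace-delimited 6-column motion
    text; ``gm_mask.nii.gz``; ``cohort.tsv``; ground-truth masks as NIfTI
    plus a JSON effect manifest.
    """
    from .niftiio import write_bold, write_nifti

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for row, (series, motion) in zip(cohort.itertuples(), subjects):
        write_bold(series, outdir / f"{row.subject}_bold.nii.gz")
        np.savetxt(outdir / f"{row.subject}_motion.txt", motion, fmt="%.8f")
    write_nifti(gm_mask, config.affine, outdir / "gm_mask.nii.gz")
    cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    truth_dir = outdir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    for name, m in truth.masks.items():
        write_nifti(m, config.affine, truth_dir / f"{name}.nii.gz")
    manifest = {
        "effects": truth.effects,
        "severity": truth.severity.tolist(),
        "seed": config.seed,
    }
    (truth_dir / "effects.json").write_text(json.dumps(manifest, indent=2))
    return outdir
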