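"""End-to-end orchestration: simulate -> preprocess -> FCD -> group -> seed iFC.

One :class:`RunConfig` drives a fully reproducible run on a synthetic
cohort: identical config + seed gives identical report. Each stage
records provenance (parameters, wall time); the report mirrors the usual
reporting of an FCD case-control study — a demographics table with group
tests, cluster tables per measure with peak coordinates and Cohen's d, a
clinical partial-correlation grid with BH-FDR q values, and seed-based
iFC difference tables.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import fcd as fcdmod
from . import preprocess as pre
from . import seed as seedmod
from . import simulate as sim
from . import stats as st

CLINICAL_METRICS = ("duration", "STAI_s", "STAI_t", "BDI_II", "PSQI")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    fcd: fcdmod.FCDConfig = field(default_factory=fcdmod.FCDConfig)
    alphasim: st.AlphaSimConfig = field(default_factory=st.AlphaSimConfig)
    n_discard: int = pre.N_DISCARD_DEFAULT
    band: tuple[float, float] = pre.BAND_DEFAULT
    onesample_p: float = 0.001
    #: smoothness fed to the Monte-Carlo null: "applied" uses the smoothing
    #: FWHM actually applied to the maps (the conventional choice);
    #: "estimate" measures it from the GLM residuals, which also captures
    #: the intrinsic spatial correlation of FCD counts
    smoothness: str = "applied"
    seed: int = 0
    #: stages to run; later stages are skipped when their inputs are missing
    stages: tuple[str, ...] = ("simulate", "preprocess", "fcd", "group", "seed_ifc")
    save_volumes: bool = False

    def __post_init__(self) -> None:
        # the global seed drives every stage's randomness
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.alphasim = dataclasses.replace(self.alphasim, seed=self.seed + 1)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.count_nonzero(a & b) / denom


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographics/clinical table with per-metric group tests.

    Continuous metrics get a pooled-variance two-sample t; gender gets a
    Pearson chi-square; patient-only metrics (duration) are summarized
    without a test.
    """
    pat = cohort[cohort["group"] == "patient"]
    con = cohort[cohort["group"] == "control"]
    rows = []
    metrics = ["age"] + [m for m in ("PSQI", "STAI_s", "STAI_t", "BDI_II", "duration", "mean_fd")
                         if m in cohort.columns]
    for metric in metrics:
        p_vals = pat[metric].dropna().to_numpy(dtype=float)
        c_vals = con[metric].dropna().to_numpy(dtype=float)
        row = {
            "metric": metric,
            "patient_mean": p_vals.mean() if p_vals.size else np.nan,
            "patient_sd": p_vals.std(ddof=1) if p_vals.size > 1 else np.nan,
            "control_mean": c_vals.mean() if c_vals.size else np.nan,
            "control_sd": c_vals.std(ddof=1) if c_vals.size > 1 else np.nan,
        }
        if p_vals.size > 1 and c_vals.size > 1:
            t, p = st.two_sample_t_summary(
                row["patient_mean"], row["patient_sd"], p_vals.size,
                row["control_mean"], row["control_sd"], c_vals.size,
            )
            row["stat"], row["p"] = t, p
        else:
            row["stat"], row["p"] = np.nan, np.nan
        rows.append(row)
    table = [
        [(pat["gender"] == "F").sum(), (pat["gender"] == "M").sum()],
        [(con["gender"] == "F").sum(), (con["gender"] == "M").sum()],
    ]
    chi2, p = st.chi_square_2x2(table)
    rows.append(
        {
            "metric": "gender_F/M",
            "patient_mean": table[0][0], "patient_sd": table[0][1],
            "control_mean": table[1][0], "control_sd": table[1][1],
            "stat": chi2, "p": p,
        }
    )
    return pd.DataFrame(rows)


def _records(df: pd.DataFrame) -> list[dict]:
    return json.loads(df.to_json(orient="records"))


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dumps succeeds."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the configured stages and return the run report (a dict).

    With ``outdir`` set, the report is written as ``report.json`` and
    each table as TSV; volumes are only written with
    ``config.save_volumes``.
    """
    report: dict = {"provenance": _provenance(config), "stages_run": []}
    stages = set(config.stages)
    timer: dict[str, float] = {}

    def tic(name):
        timer[name] = time.perf_counter()

    def toc(name):
        report["provenance"]["wall_time_s"][name] = round(
            time.perf_counter() - timer[name], 3
        )
        report["stages_run"].append(name)

    subjects = cohort = truth = gm_mask = None
    if "simulate" in stages:
        tic("simulate")
        subjects, cohort, truth, gm_mask = sim.generate_cohort(config.sim)
        toc("simulate")

    if "preprocess" in stages and subjects is not None:
        tic("preprocess")
        cleaned = []
        mean_fds = []
        motion_pass = []
        for series, motion in subjects:
            series_pp, fdres = pre.preprocess_subject(
                series, motion, n_discard=config.n_discard,
                low=config.band[0], high=config.band[1],
            )
            cleaned.append(series_pp)
            mean_fds.append(fdres.mean_fd)
            motion_pass.append(bool(pre.motion_exclusion(motion[config.n_discard:])))
        cohort["mean_fd"] = mean_fds
        cohort["motion_pass"] = motion_pass
        subjects = cleaned  # raw series no longer needed
        report["motion"] = {
            "n_pass": int(np.sum(motion_pass)),
            "n_total": len(motion_pass),
        }
        toc("preprocess")

    if cohort is not None:
        report["cohort_summary"] = _records(cohort_summary(cohort))

    fcd_maps = None
    if "fcd" in stages and subjects is not None and "preprocess" in stages:
        tic("fcd")
        per_subject = [
            fcdmod.compute_fcd_maps(series_pp, gm_mask, config.fcd)
            for series_pp in subjects
        ]
        fcd_maps = {
            "sfcd": {
                "z": np.stack([m.z_short for m in per_subject]),
                "norm": np.stack([m.norm_short for m in per_subject]),
                "k0": [m.k0_short for m in per_subject],
            },
            "lfcd": {
                "z": np.stack([m.z_long for m in per_subject]),
                "norm": np.stack([m.norm_long for m in per_subject]),
                "k0": [m.k0_long for m in per_subject],
            },
        }
        report["fcd"] = {
            meas: {"mean_k0": float(np.mean(fcd_maps[meas]["k0"]))}
            for meas in ("sfcd", "lfcd")
        }
        toc("fcd")

    affine = config.sim.affine
    surviving: dict[str, list[st.Cluster]] = {}
    if "group" in stages and fcd_maps is not None:
        tic("group")
        design, names = st.build_design(cohort)
        is_patient = cohort["group"].to_numpy() == "patient"
        rng = np.random.default_rng([config.seed, 17])
        report["group"] = {
            "alphasim": dataclasses.asdict(config.alphasim),
            "smoothness": config.smoothness,
            "design_columns": names,
        }
        extent_cache: dict[float, int] = {}
        estimate = config.smoothness == "estimate"
        for meas in ("sfcd", "lfcd"):
            statmap = st.fit_voxel_glm(fcd_maps[meas]["z"], design, gm_mask,
                                       keep_residuals=estimate, column_names=names)
            if estimate:
                fwhm = st.estimate_smoothness(statmap.residuals, gm_mask, affine)
                statmap.residuals = None
            else:
                fwhm = config.alphasim.fwhm
            key = round(fwhm, 2)
            if key not in extent_cache:
                ascfg = dataclasses.replace(config.alphasim, fwhm=key)
                extent_cache[key], _ = st.alphasim_extent(gm_mask, affine, ascfg, rng=rng)
            extent = extent_cache[key]
            tcrit = sstats.t.isf(config.alphasim.voxel_p / 2.0, statmap.df)
            clusters = st.label_clusters(
                statmap.t, tcrit, affine, rmm=config.alphasim.rmm, mask=gm_mask
            )
            surv = [c for c in clusters if c.size >= extent]
            surviving[meas] = surv
            table = st.cluster_report(
                clusters, extent, fcd_maps[meas]["norm"], is_patient, ~is_patient
            )
            report["group"][meas] = {
                "voxel_t_threshold": round(float(tcrit), 4),
                "df": statmap.df,
                "null_fwhm_mm": key,
                "extent_threshold": int(extent),
                "clusters": _records(table),
            }
        report["group"]["extent_threshold"] = report["group"]["sfcd"]["extent_threshold"]
        if truth is not None:
            report["group"]["recovery"] = _recovery(surviving, truth, gm_mask)
        # clinical partial correlations within patients, per surviving region
        report["correlations"] = _clinical_correlations(
            surviving, fcd_maps, cohort
        )
        toc("group")

    if "seed_ifc" in stages and surviving.get("lfcd") and subjects is not None:
        tic("seed_ifc")
        design, _ = st.build_design(cohort)
        is_patient = cohort["group"].to_numpy() == "patient"
        rng = np.random.default_rng([config.seed, 23])
        seeds = [
            seedmod.SeedSpec(c.mask(gm_mask.shape), label=f"lfcd_seed_{i + 1}")
            for i, c in enumerate(surviving["lfcd"])
            if c.sign < 0
        ]
        report["seed_ifc"] = {}
        for spec in seeds:
            z_maps = np.stack(
                [
                    seedmod.ifc_map(
                        s, seedmod.seed_timecourse(s, spec), gm_mask, label=spec.label
                    ).z
                    for s in subjects
                ]
            )
            masks = {
                grp: seedmod.group_onesample_map(
                    z_maps[sel], gm_mask, p_threshold=config.onesample_p
                )
                for grp, sel in (("patient", is_patient), ("control", ~is_patient))
            }
            _, table, extent = seedmod.group_difference_ifc(
                z_maps, design, gm_mask, affine, config.alphasim,
                voxel_p=config.alphasim.voxel_p, group1=is_patient,
                group2=~is_patient, rng=rng,
            )
            report["seed_ifc"][spec.label] = {
                "seed_size": int(spec.mask.sum()),
                "onesample_mask_voxels": {
                    g: int(m.sum()) for g, m in masks.items()
                },
                "difference_clusters": _records(table),
                "extent_threshold": int(extent),
            }
        toc("seed_ifc")

    report = _jsonable(report)
    if outdir is not None:
        _write_outputs(report, config, outdir, cohort, fcd_maps, gm_mask)
    return report


def _provenance(config: RunConfig) -> dict:
    import nibabel
    import scipy

    from . import __version__

    def as_jsonable(obj):
        if dataclasses.is_dataclass(obj):
            return {k: as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): as_jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [as_jsonable(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return {
        "seed": config.seed,
        "parameters": as_jsonable(config),
        "versions": {
            "fcdmap": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nibabel.__version__,
        },
        "wall_time_s": {},
    }


def _recovery(surviving, truth, gm_mask) -> dict:
    """Dice overlap of surviving clusters (by sign) with the planted masks."""
    shape = gm_mask.shape

    def union(measure, sign):
        out = np.zeros(shape, dtype=bool)
        for c in surviving.get(measure, []):
            if c.sign == sign:
                out |= c.mask(shape)
        return out

    return {
        "lfcd_decrease_dice": round(dice(union("lfcd", -1), truth.masks["lfcd_decrease"]), 4),
        "sfcd_decrease_dice": round(dice(union("sfcd", -1), truth.masks["sfcd_decrease"]), 4),
        "sfcd_increase_dice": round(dice(union("sfcd", +1), truth.masks["sfcd_increase"]), 4),
        "n_clusters": {m: len(cl) for m, cl in surviving.items()},
    }


def _clinical_correlations(surviving, fcd_maps, cohort) -> list[dict]:
    """Partial correlations (age + gender covariates) of per-region mean
    normalized FCD with each clinical metric, within patients; BH-FDR over
    the whole region-by-metric grid."""
    pat = cohort["group"].to_numpy() == "patient"
    if not pat.any():
        return []
    age = cohort.loc[pat, "age"].to_numpy(dtype=float)
    gender = (cohort.loc[pat, "gender"] == "F").to_numpy(dtype=float)
    cov = np.column_stack([age, gender])
    rows = []
    for meas in ("sfcd", "lfcd"):
        for i, c in enumerate(surviving.get(meas, [])):
            cmask = c.mask(fcd_maps[meas]["norm"].shape[1:])
            region_vals = fcd_maps[meas]["norm"][pat][:, cmask].mean(axis=1)
            for metric in CLINICAL_METRICS:
                if metric not in cohort.columns:
                    continue
                y = cohort.loc[pat, metric].to_numpy(dtype=float)
                ok = ~np.isnan(y)
                if ok.sum() < 6:
                    continue
                rho, p = st.partial_correlation(region_vals[ok], y[ok], cov[ok])
                rows.append(
                    {
                        "region": f"{meas}_cluster_{i + 1}",
                        "sign": c.sign,
                        "metric": metric,
                        "rho": round(rho, 4),
                        "p": p,
                    }
                )
    if rows:
        q = st.bh_fdr([r["p"] for r in rows])
        for r, qv in zip(rows, q):
            r["q"] = float(qv)
            r["p"] = float(r["p"])
    return rows


def _write_outputs(report, config, outdir, cohort, fcd_maps, gm_mask) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    if cohort is not None:
        cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
        pd.DataFrame(report.get("cohort_summary", [])).to_csv(
            outdir / "cohort_summary.tsv", sep="\t", index=False
        )
    if "group" in report:
        for meas in ("sfcd", "lfcd"):
            pd.DataFrame(report["group"][meas]["clusters"]).to_csv(
                outdir / f"clusters_{meas}.tsv", sep="\t", index=False
            )
    if report.get("correlations"):
        pd.DataFrame(report["correlations"]).to_csv(
            outdir / "clinical_correlations.tsv", sep="\t", index=False
        )
    if config.save_volumes and fcd_maps is not None:
        from .niftiio import write_nifti

        vol_dir = outdir / "maps"
        affine = config.sim.affine
        write_nifti(gm_mask, affine, vol_dir / "gm_mask.nii.gz")
        for meas in ("sfcd", "lfcd"):
            write_nifti(
                np.moveaxis(fcd_maps[meas]["z"], 0, -1), affine,
                vol_dir / f"{meas}_z_smoothed.nii.gz",
            )
            write_nifti(
                np.moveaxis(fcd_maps[meas]["norm"], 0, -1), affine,
                vol_dir / f"{meas}_norm.nii.gz",
            )
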