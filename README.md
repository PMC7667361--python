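# fcdmap

Voxel-wise **functional connectivity density (FCD) mapping** for
resting-state fMRI case-control studies, with the full inferential
chain around it: temporal preprocessing, Monte-Carlo cluster-extent
correction, clinical partial correlations, seed-based connectivity
backtracking — and a synthetic BOLD cohort simulator with planted group
effects so every stage is testable end to end without patient data.

## The measure and the pipeline

Treat the gray-matter voxels of a preprocessed BOLD series as nodes of a
graph with an edge wherever the Pearson correlation of two voxels' time
courses exceeds a threshold, r(i, j) > r₀ = 0.25 (positive correlations
only). The FCD of voxel i is its degree

    k(i) = #{ j ≠ i : r(i, j) > r₀ },

split by anatomical distance into **sFCD** (neighbours within a 12 mm
sphere — local connectivity) and **lFCD** (beyond 12 mm — remote
connectivity, sensitive to functional hubs), so k_short + k_long = k.
Counts are Z-scored over the mask and smoothed (6 mm FWHM) for
voxel-wise group statistics, and normalized by the whole-mask mean
degree (k/k₀) for ROI extraction and effect sizes.

Around the measure, the package implements the standard group-study
chain for two groups (e.g. chronic-insomnia patients vs good-sleeper
controls):

1. **preprocess** — discard 10 volumes, detrend + band-pass 0.01–0.1 Hz,
   regress the Friston-24 motion model; Jenkinson frame-wise
   displacement and the 2 mm / 2° motion screen;
2. **fcd** — blocked, memory-bounded edge counting (exact, verified
   against an exhaustive oracle);
3. **group** — voxel-wise GLM (group + age, gender, mean FD) at voxel
   p < .001 with an AlphaSim-style Monte-Carlo extent threshold
   (rmm = 5 mm, 1000 iterations), Cohen's d per cluster, demographic
   tests, partial correlations with clinical scores (BH-FDR);
4. **seed-ifc** — Fisher r-to-z seed connectivity of the altered-lFCD
   clusters: within-group positive-connectivity masks (FDR) and
   between-group difference tables.

The simulator (`fcdmap.simulate`) generates cohorts with known ground
truth: band-limited shared network signals (long-range edges), a
spatially smoothed local field (short-range edges), AR(1) noise + drift,
motion traces, and clinical scores driven by each patient's planted
effect severity. See `docs/methods.md` for the model and its limits.

## Worked example

```python
import pandas as pd
import fcdmap as fm

cfg = fm.RunConfig(
    sim=fm.SimConfig(grid_shape=(14, 14, 14), n_per_group=10),
    alphasim=fm.AlphaSimConfig(iterations=200),
    seed=42,
    stages=("simulate", "preprocess", "fcd", "group"),
)
report = fm.run_pipeline(cfg)
print("extent threshold:", report["group"]["lfcd"]["extent_threshold"], "voxels")
print(pd.DataFrame(report["group"]["lfcd"]["clusters"]).to_string(index=False))
print("Dice vs planted lFCD-decrease mask:",
      report["group"]["recovery"]["lfcd_decrease_dice"])
```

prints

```
extent threshold: 4 voxels
    label  size  peak_x_mm  peak_y_mm  peak_z_mm    peak_t  sign   cohen_d
cluster_1    17        4.5       -4.5       -4.5 -5.633597    -1 -2.849883
cluster_2    15        7.5        4.5       -4.5 -6.530377    -1 -3.509326
Dice vs planted lFCD-decrease mask: 0.4427
```

Two negative-t lFCD clusters survive the corrected threshold; they sit on
the network regions whose coupling the simulator reduced in patients
(peak coordinates are world-mm via the NIfTI affine), with large
negative Cohen's d of the extracted k/k₀ values, and they overlap the
planted ground-truth mask (Dice 0.44 at this small 10 + 10 cohort;
≈0.83 at the full 27 + 27 study scale — see `analysis/04_group_stats.py`).
The report also carries a demographics table; at this seed the simulated
sleep-quality scores separate as PSQI 12.28 ± 2.91 (patients) vs
1.11 ± 0.87 (controls), pooled t = 11.62.

## Analysis scripts

`analysis/01_simulate.py` … `06_null_calibration.py` run the full study
profile (27 + 27 subjects, 240 volumes at TR = 2 s, 16³ grid of 3 mm
voxels): cohort generation, preprocessing, FCD maps, group inference
with planted-mask recovery and clinical correlations, seed-iFC
backtracking, and family-wise-error calibration on null cohorts.
Volumes go to `scratch/`, tables to `results/`. A command-line interface
mirrors the stages (`fcdmap simulate|preprocess|fcd|group|seed-ifc|run|report`).

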