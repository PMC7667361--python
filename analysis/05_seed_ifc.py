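"""Seed-based iFC backtracking of the altered long-range FCD regions.

Seeds are the surviving negative lFCD clusters from the group stage.
For each: per-subject Fisher-z correlation maps, within-group positive
connectivity masks (BH-FDR, adjusted p < .001), and a between-group
difference table with the same GLM + extent correction as the FCD stage.
"""
import numpy as np
import pandas as pd
from scipy import stats as sstats

from common import ALPHASIM, COHORT_DIR, FCD_DIR, PREPROC_DIR, RESULTS
from fcdmap import niftiio, seed as seedmod, stats as st

cohort = pd.read_csv(PREPROC_DIR / "cohort.tsv", sep="\t")
gm_mask, affine = niftiio.read_nifti(COHORT_DIR / "gm_mask.nii.gz")
gm_mask = gm_mask > 0
design, names = st.build_design(cohort)
is_patient = cohort["group"].to_numpy() == "patient"

# rebuild the surviving negative lFCD clusters from the group stage
z = np.stack([niftiio.read_nifti(FCD_DIR / "z_long" / f"{s}.nii.gz")[0]
              for s in cohort["subject"]]).astype(float)
statmap = st.fit_voxel_glm(z, design, gm_mask)
tcrit = sstats.t.isf(ALPHASIM.voxel_p / 2.0, statmap.df)
extent, _ = st.alphasim_extent(gm_mask, affine, ALPHASIM)
clusters = [c for c in st.label_clusters(statmap.t, tcrit, affine,
                                         rmm=ALPHASIM.rmm, mask=gm_mask)
            if c.size >= extent and c.sign < 0]
print(f"{len(clusters)} lFCD-decrease seed(s)")

series_cache = [niftiio.read_bold(PREPROC_DIR / f"{s}_bold.nii.gz")
                for s in cohort["subject"]]
summary_rows = []
for i, cluster in enumerate(clusters):
    spec = seedmod.SeedSpec(cluster.mask(gm_mask.shape), label=f"lfcd_seed_{i+1}")
    z_maps = np.stack([
        seedmod.ifc_map(s, seedmod.seed_timecourse(s, spec), gm_mask).z
        for s in series_cache
    ])
    masks = {grp: seedmod.group_onesample_map(z_maps[sel], gm_mask)
             for grp, sel in (("patient", is_patient), ("control", ~is_patient))}
    _, table, ext = seedmod.group_difference_ifc(
        z_maps, design, gm_mask, affine, ALPHASIM,
        group1=is_patient, group2=~is_patient,
    )
    table.to_csv(RESULTS / f"05_seed{i+1}_difference_clusters.tsv", sep="\t", index=False)
    summary_rows.append({
        "seed": spec.label,
        "seed_voxels": int(spec.mask.sum()),
        "patient_mask_voxels": int(masks["patient"].sum()),
        "control_mask_voxels": int(masks["control"].sum()),
        "n_difference_clusters": len(table),
    })
    print(f"{spec.label}: one-sample masks patient/control = "
          f"{masks['patient'].sum()}/{masks['control'].sum()} voxels; "
          f"{len(table)} difference cluster(s)")
    print(table.to_string(index=False))

pd.DataFrame(summary_rows).to_csv(RESULTS / "05_seed_summary.tsv", sep="\t", index=False)
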