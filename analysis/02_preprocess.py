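"""Temporal preprocessing of every subject.

Discards the first 10 volumes, detrends and band-passes each voxel to
0.01-0.1 Hz, regresses out the band-passed Friston-24 motion model, and
summarizes head motion as Jenkinson FD plus the 2 mm / 2 degree screen.
Preprocessed series go to scratch; the motion table to results.
"""
import numpy as np
import pandas as pd

from common import COHORT_DIR, PREPROC_DIR, RESULTS
from fcdmap import niftiio, preprocess as pre

cohort = pd.read_csv(COHORT_DIR / "cohort.tsv", sep="\t")
rows = []
for subject in cohort["subject"]:
    series = niftiio.read_bold(COHORT_DIR / f"{subject}_bold.nii.gz")
    motion = np.loadtxt(COHORT_DIR / f"{subject}_motion.txt")
    cleaned, fd = pre.preprocess_subject(series, motion)
    screen = pre.motion_exclusion(motion[pre.N_DISCARD_DEFAULT:])
    niftiio.write_bold(cleaned, PREPROC_DIR / f"{subject}_bold.nii.gz")
    rows.append({
        "subject": subject,
        "mean_fd": round(fd.mean_fd, 4),
        "max_fd": round(float(fd.fd.max()), 4),
        "motion_pass": screen.passed,
    })

table = pd.DataFrame(rows)
cohort["mean_fd"] = table["mean_fd"]
cohort.to_csv(PREPROC_DIR / "cohort.tsv", sep="\t", index=False)
table.to_csv(RESULTS / "02_motion_fd.tsv", sep="\t", index=False)

print(table.describe().loc[["mean", "max"], ["mean_fd", "max_fd"]])
print(f"{int(table['motion_pass'].sum())}/{len(table)} subjects pass the motion screen")
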