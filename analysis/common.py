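"""Shared configuration of the analysis scripts.

The study profile: two groups of 27 subjects, 240 volumes at TR = 2 s,
with the default planted effects, on a 16^3 grid of 3 mm voxels (sized so
the full sequence runs in minutes on one CPU). Intermediate volumes live
under scratch/ (disposable); every reported table lands in results/.
"""
from pathlib import Path

from fcdmap import AlphaSimConfig, FCDConfig, SimConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 2024

SIM = SimConfig(grid_shape=(16, 16, 16), n_volumes=240, n_per_group=27, seed=SEED)
FCD = FCDConfig()  # r0 = 0.25, 12 mm cutoff, 6 mm smoothing
ALPHASIM = AlphaSimConfig(iterations=1000, seed=SEED + 1)

COHORT_DIR = SCRATCH / "cohort"
PREPROC_DIR = SCRATCH / "preprocessed"
FCD_DIR = SCRATCH / "fcd"

for d in (SCRATCH, RESULTS):
    d.mkdir(parents=True, exist_ok=True)
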