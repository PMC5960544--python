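"""Compute the seven voxelwise parameter maps for every patient.

PEAK, TME, AUC_ENH, WASHIN, WASHOUT from the dynamic series, ADC from
the two b-value DWI pair, T2SI pass-through.  Maps are written as NIfTI
under scratch/run/maps/.
"""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RUN_DIR, demo_config

from nacradiomics.pipeline import run_pipeline

if __name__ == "__main__":
    cfg = demo_config()
    cfg.stages = ("maps",)
    run_pipeline(cfg)
    n = len(list((RUN_DIR / "maps").glob("*.nii.gz")))
    print(f"wrote {n} parameter-map volumes (7 per patient) -> {RUN_DIR / 'maps'}")
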