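"""Pool each parameter map over the tumor VOI into first-order features.

23 statistics (13 percentiles, extremes, spread, central tendency,
shape, voxel count) x 7 maps = 161 columns per patient.  The table goes
to scratch/run/features.csv.
"""

import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RUN_DIR, demo_config

from nacradiomics.pipeline import run_pipeline

if __name__ == "__main__":
    cfg = demo_config()
    cfg.stages = ("features",)
    run_pipeline(cfg)
    table = pd.read_csv(RUN_DIR / "features.csv", index_col="patient_id")
    print(f"feature table: {table.shape[0]} patients x {table.shape[1]} features "
          f"-> {RUN_DIR / 'features.csv'}")
    print(table[["AUC_ENH_max", "TME_p75", "WASHOUT_p20"]].describe()
          .loc[["mean", "std"]].round(3).to_string())
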