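"""Classify therapy response from lesion diameters (RECIST 1.1).

Adds percent diameter change, the CR/PR/SD/PD label and the two
dichotomized endpoints (complete responder vs rest, nonresponder vs
rest) to the cohort table -> scratch/run/cohort_labeled.csv.
"""

import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RUN_DIR, demo_config

from nacradiomics.pipeline import run_pipeline

if __name__ == "__main__":
    cfg = demo_config()
    cfg.stages = ("respond",)
    run_pipeline(cfg)
    labeled = pd.read_csv(RUN_DIR / "cohort_labeled.csv")
    print(labeled["recist_label"].value_counts().to_string())
    print(f"nonresponders (endpoint positives): {labeled['is_NR'].sum()} "
          f"of {len(labeled)}")
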