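"""Univariate screening of all features against the nonresponder endpoint.

Per feature: Mann-Whitney AUC (direction-resolved), top-left-corner
optimal cutoff, confusion metrics at that cutoff, and a permutation p
(2000 relabelings).  The rendered summary mirrors the columns of the
motivating study's report table and is copied to
results/demo_univariate_report.csv.
"""

import shutil
import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, RUN_DIR, demo_config

from nacradiomics.pipeline import run_pipeline

if __name__ == "__main__":
    cfg = demo_config()
    cfg.stages = ("analyze",)
    run_pipeline(cfg)
    RESULTS.mkdir(exist_ok=True)
    shutil.copy(RUN_DIR / "report" / "report.csv",
                RESULTS / "demo_univariate_report.csv")
    report = pd.read_csv(RESULTS / "demo_univariate_report.csv")
    sig = report[report["p value"] < 0.05]
    print(f"{len(report)} features analyzed, {len(sig)} significant at p < 0.05")
    print("top of the report (sorted by permutation p):")
    print(report.head(10).to_string(index=False))
    print(f"\nfull table -> {RESULTS / 'demo_univariate_report.csv'}")
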