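"""Internal-consistency check of the motivating study's printed report.

From each printed sensitivity/specificity row and the 10-vs-59
nonresponder split, reconstruct the integer confusion table and
recompute PPV, NPV and accuracy; compare with the printed values after
two-decimal rounding.  Also re-derives the cohort percentages from the
33/26/10 response counts.  Writes results/reference_consistency.csv.
"""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS

from nacradiomics.reference import cohort_proportions, consistency_table

if __name__ == "__main__":
    table = consistency_table()
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "reference_consistency.csv", float_format="%.4f")
    ok = table[["ppv_ok", "npv_ok", "acc_ok"]].all(axis=None)
    print(table[["tp", "fp", "tn", "fn", "ppv_computed", "npv_computed",
                 "acc_computed", "ppv_ok", "npv_ok", "acc_ok"]]
          .round(3).to_string())
    print(f"\nall printed PPV/NPV/ACC reproduced after 2-dp rounding: {bool(ok)}")
    print(f"cohort percentages from 33/26/10 of 69: {cohort_proportions()}")
    print(f"table -> {RESULTS / 'reference_consistency.csv'}")
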