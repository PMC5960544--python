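"""Published summary data of the motivating clinical study, as input tables.

The clinical study this pipeline models analyzed 69 breast-cancer
patients before neoadjuvant chemotherapy: 33 complete responders, 26
partial responders and 10 nonresponders.  Its univariate report prints,
per discriminating feature, the optimal cutoff's sensitivity and
specificity together with PPV, NPV, accuracy, AUC and a permutation p,
all rounded to two decimals.  The raw images are not available, so the
printed summary rows are inputs here: from each row's sensitivity and
specificity and the 10-vs-59 nonresponder split, an integer 2x2 table
is reconstructed and the derived metrics (PPV, NPV, accuracy) are
recomputed, checking the report's internal arithmetic consistency.
"""

from __future__ import annotations

import pandas as pd

from .roc_stats import reconstruct_confusion

__all__ = [
    "GROUP_COUNTS",
    "N_PATIENTS",
    "REFERENCE_ROWS",
    "cohort_proportions",
    "consistency_table",
]

#: Complete / partial / non responders in the emulated cohort.
GROUP_COUNTS = {"CR": 33, "PR": 26, "NR": 10}
N_PATIENTS = 69

#: Printed univariate rows (nonresponder endpoint): feature ->
#: (threshold, sensitivity, specificity, PPV, NPV, ACC, AUC, p value).
REFERENCE_ROWS = {
    "AUC_MAX": (536645.51, 0.50, 0.88, 0.42, 0.91, 0.83, 0.71, 0.03),
    "AUC_RANGE": (534858.33, 0.50, 0.88, 0.42, 0.91, 0.83, 0.72, 0.03),
    "TME_75": (373.03, 0.80, 0.63, 0.27, 0.95, 0.65, 0.70, 0.05),
    "Washout_10": (0.01, 0.70, 0.68, 0.27, 0.93, 0.68, 0.70, 0.04),
    "Washout_20": (0.01, 0.70, 0.83, 0.41, 0.94, 0.81, 0.75, 0.01),
    "Washout_25": (0.03, 0.70, 0.81, 0.39, 0.94, 0.80, 0.75, 0.01),
}


def cohort_proportions() -> dict[str, float]:
    """Response-group percentages (one decimal) from the group counts."""
    return {g: round(100.0 * c / N_PATIENTS, 1) for g, c in GROUP_COUNTS.items()}


def consistency_table() -> pd.DataFrame:
    """Recompute PPV/NPV/ACC of every reference row from its sens/spec.

    For each printed row, rebuild the integer confusion table with the
    10 positive / 59 negative split and rederive the dependent metrics;
    ``*_ok`` columns compare them to the printed values after rounding
    to the printed two-decimal precision.
    """
    n_pos = GROUP_COUNTS["NR"]
    n_neg = N_PATIENTS - n_pos
    rows = []
    for name, (thr, sens, spec, ppv, npv, acc, auc, p) in REFERENCE_ROWS.items():
        tab = reconstruct_confusion(sens, spec, n_pos, n_neg)
        rates = tab.rates()
        rows.append({
            "feature": name,
            "tp": tab.tp, "fp": tab.fp, "tn": tab.tn, "fn": tab.fn,
            "sens_in": sens, "spec_in": spec,
            "ppv_computed": rates["ppv"],
            "npv_computed": rates["npv"],
            "acc_computed": rates["acc"],
            "ppv_printed": ppv, "npv_printed": npv, "acc_printed": acc,
            "ppv_ok": round(rates["ppv"], 2) == ppv,
            "npv_ok": round(rates["npv"], 2) == npv,
            "acc_ok": round(rates["acc"], 2) == acc,
        })
    return pd.DataFrame(rows).set_index("feature")
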