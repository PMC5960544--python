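"""RECIST 1.1 response classification from longest lesion diameters.

Classes from the percent change of the longest diameter between the
baseline and post-therapy examinations:

* CR — complete response: the lesion disappeared (100% reduction);
* PR — partial response: reduction of at least 30%;
* PD — progressive disease: increase of at least 20%;
* SD — stable disease: neither PR nor PD.

Boundaries are inclusive ("at least"), and CR requires a post-therapy
diameter of exactly zero (to a 1e-9 cm float tolerance).  The analysis
stage dichotomizes these labels into complete-responder-vs-rest and
nonresponder-vs-rest endpoints; nonresponder means SD or PD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ResponseAssessment", "classify_recist", "dichotomize", "label_cohort"]

CR_TOLERANCE_CM = 1e-9
ENDPOINTS = ("CR_vs_rest", "NR_vs_rest")


@dataclass(frozen=True)
class ResponseAssessment:
    diameter_pre: float  # cm, > 0
    diameter_post: float  # cm, >= 0
    percent_change: float  # negative = shrinkage
    label: str  # CR | PR | SD | PD

    @property
    def is_complete_responder(self) -> bool:
        return self.label == "CR"

    @property
    def is_nonresponder(self) -> bool:
        return self.label in ("SD", "PD")


def classify_recist(diameter_pre: float, diameter_post: float) -> ResponseAssessment:
    """Classify one lesion's response from its pre/post longest diameters (cm)."""
    if not diameter_pre > 0:
        raise ValueError(f"diameter_pre must be > 0, got {diameter_pre}")
    if diameter_post < 0:
        raise ValueError(f"diameter_post must be >= 0, got {diameter_post}")
    change = 100.0 * (diameter_post - diameter_pre) / diameter_pre
    if diameter_post <= CR_TOLERANCE_CM:
        label = "CR"
    elif change <= -30.0:
        label = "PR"
    elif change >= 20.0:
        label = "PD"
    else:
        label = "SD"
    return ResponseAssessment(float(diameter_pre), float(diameter_post),
                              float(change), label)


def dichotomize(
    assessments: Sequence[ResponseAssessment | str], endpoint: str
) -> np.ndarray:
    """Binary endpoint labels: 1 = positive class, 0 = rest.

    ``CR_vs_rest`` marks complete responders positive; ``NR_vs_rest``
    marks nonresponders (SD or PD) positive.  A single-class result is
    flagged in the log (ROC analysis is undefined downstream).
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    if len(assessments) == 0:
        raise ValueError("empty assessment list")
    labels = [a.label if isinstance(a, ResponseAssessment) else str(a)
              for a in assessments]
    bad = set(labels) - {"CR", "PR", "SD", "PD"}
    if bad:
        raise ValueError(f"unknown response labels {sorted(bad)}")
    if endpoint == "CR_vs_rest":
        y = np.array([lab == "CR" for lab in labels], dtype=int)
    else:
        y = np.array([lab in ("SD", "PD") for lab in labels], dtype=int)
    if y.min() == y.max():
        logger.warning("dichotomize: endpoint %s is single-class (all %d)",
                       endpoint, int(y[0]))
    return y


def label_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add percent_change, RECIST label and endpoint columns to a cohort table.

    Expects ``diameter_pre_cm`` and ``diameter_post_cm`` columns; returns
    a copy with ``percent_change``, ``recist_label``, ``is_CR`` and
    ``is_NR`` appended.
    """
    out = cohort.copy()
    assessments = [
        classify_recist(pre, post)
        for pre, post in zip(out["diameter_pre_cm"], out["diameter_post_cm"])
    ]
    out["percent_change"] = [a.percent_change for a in assessments]
    out["recist_label"] = [a.label for a in assessments]
    out["is_CR"] = [int(a.is_complete_responder) for a in assessments]
    out["is_NR"] = [int(a.is_nonresponder) for a in assessments]
    return out
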