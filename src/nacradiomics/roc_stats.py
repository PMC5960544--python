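"""Univariate ROC discrimination analysis with permutation inference.

Each candidate feature is scored against a binary endpoint by

* the Mann-Whitney AUC, P(score_pos > score_neg) + 0.5 * P(tie),
  computed by all-pairs counting (via midranks).  When the raw AUC is
  below 0.5 the feature discriminates with low values; the reported AUC
  is reflected to >= 0.5 and the direction recorded explicitly;
* an optimal cutoff by the top-left-corner rule — the operating point
  minimizing (1 - sensitivity)^2 + (1 - specificity)^2, i.e. closest to
  the ideal corner of the ROC plane (``literal_maximize=True`` instead
  maximizes that quantity, preserved for auditability of the
  alternative reading of the rule);
* confusion metrics (sensitivity, specificity, PPV, NPV, accuracy) at
  that cutoff;
* a permutation p-value for the two-sided statistic |AUC - 0.5| under
  random relabelling, exact by enumeration when the number of distinct
  labelings is small, otherwise Monte-Carlo with an add-one estimator.

A second, independent AUC route — trapezoidal area under the empirical
ROC curve — is kept in the module as a cross-check of the pair-counting
route; the two agree to machine precision by construction of the ROC.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "AucResult",
    "RocCurve",
    "RocReport",
    "ConfusionTable",
    "auc_mann_whitney",
    "auc_trapezoid",
    "topleft_cutoff",
    "confusion_at",
    "permutation_pvalue",
    "reconstruct_confusion",
    "analyze_feature_table",
    "render_report",
]

GREATER = "greater_is_positive"
LESS = "less_is_positive"


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


@dataclass(frozen=True)
class AucResult:
    auc: float  # reflected to >= 0.5
    direction: str  # GREATER or LESS
    auc_raw: float  # P(score_pos > score_neg) + 0.5 P(tie)


def _auc_raw(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs AUC via midranks: identical to the pair-count definition."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = sps.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_mann_whitney(scores, labels) -> AucResult:
    """Mann-Whitney AUC with automatic direction handling.

    Raw AUC < 0.5 means low scores mark the positive class; the report
    carries AUC reflected to >= 0.5 together with ``less_is_positive``.
    """
    scores, labels = _check_binary(scores, labels)
    raw = _auc_raw(scores, labels)
    if raw < 0.5:
        return AucResult(1.0 - raw, LESS, raw)
    return AucResult(raw, GREATER, raw)


@dataclass
class RocCurve:
    """Empirical ROC operating points as the decision threshold sweeps.

    ``thresholds`` holds -inf, the sorted unique score values, and +inf;
    a case is called positive when its score is strictly above (below,
    for ``less_is_positive``) the threshold.  ``cutpoints`` holds the
    representative numeric cutoff realizing each operating point: the
    midpoint between the straddled adjacent distinct scores (one unit
    beyond the extremes at the ends).
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    cutpoints: np.ndarray
    direction: str = GREATER

    @classmethod
    def from_scores(cls, scores, labels, direction: str = GREATER) -> "RocCurve":
        scores, labels = _check_binary(scores, labels)
        sgn = 1.0 if direction == GREATER else -1.0
        s = sgn * scores
        u = np.unique(s)
        n_pos = labels.sum()
        n_neg = labels.size - n_pos
        thr = np.concatenate(([-np.inf], u, [np.inf]))
        sens = np.empty(thr.size)
        spec = np.empty(thr.size)
        for i, t in enumerate(thr):
            call = s > t
            sens[i] = (call & (labels == 1)).sum() / n_pos
            spec[i] = (~call & (labels == 0)).sum() / n_neg
        mid = 0.5 * (u[:-1] + u[1:]) if u.size > 1 else np.empty(0)
        cut = np.concatenate(([u[0] - 1.0], mid, [u[-1] + 1.0, u[-1] + 1.0]))
        return cls(sgn * thr, sens, spec, sgn * cut, direction)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under the empirical ROC curve (TPR vs FPR)."""
    fpr = 1.0 - curve.spec
    # ascending (fpr, tpr): vertical runs ordered bottom-up so diagonal
    # tie segments connect the correct staircase corners
    order = np.lexsort((curve.sens, fpr))
    return float(np.trapezoid(curve.sens[order], fpr[order]))


def topleft_cutoff(
    curve: RocCurve, literal_maximize: bool = False
) -> tuple[float, float, float]:
    """Optimal cutoff by the top-left-corner rule.

    Returns ``(cutoff, sensitivity, specificity)`` at the operating
    point minimizing (1-sens)^2 + (1-spec)^2.  Ties go to the point
    with higher specificity, then to the lower numeric cutoff.
    """
    d = (1.0 - curve.sens) ** 2 + (1.0 - curve.spec) ** 2
    key = -d if literal_maximize else d
    best = None
    for i in range(d.size):
        cand = (key[i], -curve.spec[i], curve.cutpoints[i], i)
        if best is None or cand < best:
            best = cand
    i = best[3]
    return float(curve.cutpoints[i]), float(curve.sens[i]), float(curve.spec[i])


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    def rates(self) -> dict[str, float]:
        """sens/spec/ppv/npv/acc; NaN where a denominator is zero."""
        def frac(a: int, b: int) -> float:
            return a / b if b else float("nan")

        return {
            "sens": frac(self.tp, self.tp + self.fn),
            "spec": frac(self.tn, self.tn + self.fp),
            "ppv": frac(self.tp, self.tp + self.fp),
            "npv": frac(self.tn, self.tn + self.fn),
            "acc": frac(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn),
        }


def confusion_at(scores, labels, cutoff: float, direction: str = GREATER
                 ) -> tuple[ConfusionTable, dict[str, float]]:
    """Confusion table calling positive above (or below) ``cutoff``."""
    scores, labels = _check_binary(scores, labels)
    if direction == GREATER:
        call = scores > cutoff
    elif direction == LESS:
        call = scores < cutoff
    else:
        raise ValueError(f"unknown direction {direction!r}")
    tab = ConfusionTable(
        tp=int((call & (labels == 1)).sum()),
        fp=int((call & (labels == 0)).sum()),
        tn=int((~call & (labels == 0)).sum()),
        fn=int((~call & (labels == 1)).sum()),
    )
    return tab, tab.rates()


def _null_aucs(ranks: np.ndarray, pos_idx: np.ndarray, n_pos: int, n_neg: int
               ) -> np.ndarray:
    r_sum = ranks[pos_idx].sum(axis=1)
    return (r_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def permutation_pvalue(scores, labels, n_perm: int = 10000, seed: int = 0
                       ) -> float:
    """Two-sided permutation p-value for the statistic |AUC - 0.5|.

    Labelings are enumerated exhaustively when C(n, n_pos) <= n_perm
    (exact p = hit fraction); otherwise ``n_perm`` uniform label
    permutations are drawn and the add-one estimator
    (1 + hits) / (n_perm + 1) keeps p strictly positive.
    """
    scores, labels = _check_binary(scores, labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = labels.size
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    ranks = sps.rankdata(scores)
    obs = abs(_auc_raw(scores, labels) - 0.5)
    tol = 1e-12
    total = math.comb(n, n_pos)
    if total <= n_perm:
        pos_idx = np.array(list(itertools.combinations(range(n), n_pos)))
        null = np.abs(_null_aucs(ranks, pos_idx, n_pos, n_neg) - 0.5)
        return float((null >= obs - tol).sum() / total)
    rng = np.random.default_rng(seed)
    pos_idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_pos]
    null = np.abs(_null_aucs(ranks, pos_idx, n_pos, n_neg) - 0.5)
    return float((1 + (null >= obs - tol).sum()) / (n_perm + 1))


def reconstruct_confusion(sens: float, spec: float, n_pos: int, n_neg: int
                          ) -> ConfusionTable:
    """Integer 2x2 table consistent with reported sensitivity/specificity.

    tp = round(sens * n_pos) and tn = round(spec * n_neg) with
    round-half-up; warns when the re-derived rates differ from the
    inputs by more than half a count (the reported rates cannot then
    come from these group sizes).
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("rates must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    tp = int(math.floor(sens * n_pos + 0.5))
    tn = int(math.floor(spec * n_neg + 0.5))
    tab = ConfusionTable(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
    if abs(tp / n_pos - sens) > 0.5 / n_pos or abs(tn / n_neg - spec) > 0.5 / n_neg:
        warnings.warn(
            f"reconstructed table (tp={tp}, tn={tn}) is inconsistent with "
            f"sens={sens}, spec={spec} at n_pos={n_pos}, n_neg={n_neg}",
            stacklevel=2,
        )
    return tab


@dataclass
class RocReport:
    """Full univariate result for one feature."""

    feature_name: str
    auc: float
    direction: str
    cutoff: float
    sens: float
    spec: float
    ppv: float
    npv: float
    acc: float
    p_perm: float
    n_perm: int
    seed: int
    n_pos: int
    n_neg: int
    n_missing: int = 0
    significant: bool = False


def analyze_feature_table(
    features: pd.DataFrame,
    labels,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    literal_maximize: bool = False,
    benjamini_hochberg: bool = False,
) -> tuple[list[RocReport], pd.DataFrame]:
    """ROC + cutoff + permutation analysis of every feature column.

    Missing values are dropped per feature (count logged); constant
    features are skipped.  Reports come back sorted by permutation p.
    No multiple-testing correction is applied by default;
    ``benjamini_hochberg=True`` adds a ``q_value`` column.
    """
    y = np.asarray(labels).ravel().astype(int)
    if y.size != len(features):
        raise ValueError("labels length must match the number of rows")
    if y.min() == y.max():
        raise ValueError("endpoint is single-class; ROC analysis undefined")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 patients per class")

    children = np.random.SeedSequence(seed).spawn(features.shape[1])
    reports: list[RocReport] = []
    for j, col in enumerate(features.columns):
        x = features[col].to_numpy(dtype=float)
        keep = np.isfinite(x)
        n_missing = int((~keep).sum())
        xv, yv = x[keep], y[keep]
        if n_missing:
            logger.info("analyze: %s: dropped %d missing values", col, n_missing)
        if xv.size == 0 or yv.min() == yv.max() or np.all(xv == xv[0]):
            logger.info("analyze: %s skipped (constant or degenerate)", col)
            continue
        res = auc_mann_whitney(xv, yv)
        curve = RocCurve.from_scores(xv, yv, res.direction)
        cutoff, sens, spec = topleft_cutoff(curve, literal_maximize)
        _, rates = confusion_at(xv, yv, cutoff, res.direction)
        feat_seed = int(children[j].generate_state(1)[0] % (2**31))
        p = permutation_pvalue(xv, yv, n_perm=n_perm, seed=feat_seed)
        reports.append(RocReport(
            feature_name=str(col), auc=res.auc, direction=res.direction,
            cutoff=cutoff, sens=rates["sens"], spec=rates["spec"],
            ppv=rates["ppv"], npv=rates["npv"], acc=rates["acc"],
            p_perm=p, n_perm=n_perm, seed=feat_seed,
            n_pos=int((yv == 1).sum()), n_neg=int((yv == 0).sum()),
            n_missing=n_missing, significant=p < alpha,
        ))
    reports.sort(key=lambda r: (r.p_perm, r.feature_name))
    frame = pd.DataFrame([vars(r) for r in reports])
    if benjamini_hochberg and len(frame):
        frame["q_value"] = sps.false_discovery_control(frame["p_perm"], method="bh")
    return reports, frame


def render_report(reports: list[RocReport]) -> pd.DataFrame:
    """Human-readable summary table (rates and AUC rounded to 2 decimals)."""
    rows = []
    for r in reports:
        rows.append({
            "Parameter": r.feature_name,
            "Threshold": float(f"{r.cutoff:.6g}"),
            "Direction": "higher" if r.direction == GREATER else "lower",
            "Sensitivity": round(r.sens, 2),
            "Specificity": round(r.spec, 2),
            "PPV": round(r.ppv, 2) if np.isfinite(r.ppv) else float("nan"),
            "NPV": round(r.npv, 2) if np.isfinite(r.npv) else float("nan"),
            "ACC": round(r.acc, 2),
            "AUC": round(r.auc, 2),
            "p value": round(r.p_perm, 4),
        })
    return pd.DataFrame(rows)
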