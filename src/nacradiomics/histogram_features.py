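"""Volumetric first-order histogram features of a parameter map over a VOI.

All statistics are functions of the multiset of valid voxel values
inside the tumor mask — no spatial information is used.  Conventions
(documented because vendor software rarely states its own):

* percentiles: linear interpolation between order statistics at rank
  (n - 1) * p / 100 (zero-based);
* standard deviation: n - 1 denominator;
* skewness: Fisher-Pearson g1 = m3 / m2^1.5 (biased moments);
* kurtosis: excess, m4 / m2^2 - 3 (``excess=False`` switches to the
  non-excess convention);
* mode: center of the most populated of ``mode_bins`` equal-width bins
  spanning [min, max], lowest-valued bin on ties; the single value when
  the VOI is constant.

A constant VOI has sd = 0 and undefined (NaN) skewness and kurtosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .param_maps import ParameterMap

logger = logging.getLogger(__name__)

__all__ = [
    "VoiMask",
    "FeatureRecord",
    "EmptyVoiError",
    "PERCENTILES",
    "STAT_NAMES",
    "percentile",
    "extract_features",
    "feature_table",
]

#: Percentile grid reported per map.
PERCENTILES = (5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95)

#: Canonical per-map statistic order (23 columns per map).
STAT_NAMES = tuple(f"p{p}" for p in PERCENTILES) + (
    "max", "min", "range", "sd", "mean", "median", "mode",
    "skewness", "kurtosis", "n_voxels",
)


class EmptyVoiError(ValueError):
    """Raised when a VOI contains no valid voxel for a map."""


@dataclass
class VoiMask:
    """Binary lesion mask; shape must match the maps it is applied to."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("VOI mask must be 3D")
        if not self.values.any():
            raise ValueError("VOI mask must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class FeatureRecord:
    """First-order statistics of one map over one VOI."""

    map_name: str
    percentiles: dict[int, float]
    max: float
    min: float
    range: float
    sd: float
    mean: float
    median: float
    mode: float
    skewness: float
    kurtosis: float
    n_voxels: int

    def to_dict(self) -> dict[str, float]:
        """Flatten into canonical ``<MAP>_<stat>`` columns."""
        out = {f"{self.map_name}_p{p}": self.percentiles[p] for p in PERCENTILES}
        for stat in STAT_NAMES[len(PERCENTILES):]:
            out[f"{self.map_name}_{stat}"] = getattr(self, stat)
        return out


def percentile(values: np.ndarray, p: float) -> float:
    """Linear-interpolation percentile at zero-based rank (n-1)*p/100."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("percentile of an empty sample is undefined")
    if not 0 <= p <= 100:
        raise ValueError("p must be in [0, 100]")
    return float(np.percentile(values, p))


def _mode(values: np.ndarray, bins: int) -> float:
    """Histogram mode; exact multiset mode when the data are discrete.

    With at most ``bins`` distinct values the histogram would only
    smear exact repeats, so the most frequent value itself is returned
    (lowest on ties).  Otherwise: center of the most populated of
    ``bins`` equal-width bins over [min, max], lowest bin on ties.
    """
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size <= bins:
        return float(uniq[np.argmax(counts)])
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    k = int(np.argmax(counts))  # first maximum -> lowest-valued bin on ties
    return float(0.5 * (edges[k] + edges[k + 1]))


def extract_features(
    pmap: ParameterMap,
    mask: VoiMask | np.ndarray,
    mode_bins: int = 64,
    excess_kurtosis: bool = True,
    lesion_id: str = "",
) -> FeatureRecord:
    """First-order statistics of ``pmap`` over the valid voxels of ``mask``."""
    m = mask.values if isinstance(mask, VoiMask) else np.asarray(mask, dtype=bool)
    if m.shape != pmap.values.shape:
        raise ValueError("mask shape must match map shape")
    vals = pmap.values[m & pmap.valid]
    if vals.size == 0:
        raise EmptyVoiError(
            f"no valid voxel for map {pmap.name!r}"
            + (f" in lesion {lesion_id!r}" if lesion_id else "")
        )
    vmin, vmax = float(vals.min()), float(vals.max())
    constant = vmin == vmax
    if constant:
        skew = kurt = float("nan")
        logger.info("extract_features: %s constant over VOI%s; skewness/kurtosis undefined",
                    pmap.name, f" {lesion_id}" if lesion_id else "")
    else:
        skew = float(sps.skew(vals, bias=True))
        kurt = float(sps.kurtosis(vals, fisher=excess_kurtosis, bias=True))
    pcts = dict(zip(PERCENTILES, np.percentile(vals, PERCENTILES).astype(float)))
    return FeatureRecord(
        map_name=pmap.name,
        percentiles=pcts,
        max=vmax,
        min=vmin,
        range=vmax - vmin,
        sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        mean=float(np.mean(vals)),
        median=pcts[50],
        mode=_mode(vals, mode_bins),
        skewness=skew,
        kurtosis=kurt,
        n_voxels=int(vals.size),
    )


def feature_table(
    maps_by_patient: dict[str, dict[str, ParameterMap]],
    masks_by_patient: dict[str, VoiMask | np.ndarray],
    mode_bins: int = 64,
    excess_kurtosis: bool = True,
) -> pd.DataFrame:
    """One row per patient, one column per (map, statistic) pair.

    Column order is deterministic: maps in the order of the first
    patient's map dict, statistics in :data:`STAT_NAMES` order.  A
    missing or failing map yields NaN cells for that patient; failures
    are collected and summarized in the log rather than aborting.
    """
    if not maps_by_patient:
        raise ValueError("no patients provided")
    first = next(iter(maps_by_patient.values()))
    map_names = list(first)
    columns = [f"{m}_{s}" for m in map_names for s in STAT_NAMES]
    rows, errors = {}, []
    for pid, maps in maps_by_patient.items():
        row: dict[str, float] = {}
        for name in map_names:
            try:
                rec = extract_features(maps[name], masks_by_patient[pid],
                                       mode_bins=mode_bins,
                                       excess_kurtosis=excess_kurtosis,
                                       lesion_id=pid)
                row.update(rec.to_dict())
            except (KeyError, EmptyVoiError) as exc:
                errors.append((pid, name, repr(exc)))
        rows[pid] = row
    if errors:
        logger.warning("feature_table: %d (patient, map) failures: %s",
                       len(errors), errors[:5])
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(columns=columns)
    table.index.name = "patient_id"
    return table
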