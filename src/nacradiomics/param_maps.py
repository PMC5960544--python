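"""Voxelwise semi-quantitative parameter maps from DCE, DWI and T2 volumes.

From the dynamic series the module derives relative enhancement
E(t) = (S(t) - S(0)) / S(0) per voxel and summarizes it into five maps:

* ``PEAK``     — maximum post-contrast enhancement (dimensionless);
* ``TME``      — time of that maximum, first occurrence on ties (s);
* ``AUC_ENH``  — trapezoidal integral of E over the acquisition window (s);
* ``WASHIN``   — mean uptake slope PEAK / TME (1/s);
* ``WASHOUT``  — mean post-peak decline (PEAK - E(t_last)) / (t_last - TME)
  (1/s), defined as 0 when the peak falls on the last acquisition.

ADC comes from the two-point mono-exponential fit
``ln(S_b0 / S_b900) / b`` and the T2 map is an identity pass-through, so
histogram features see raw T2 intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DceSeries",
    "ParameterMap",
    "MAP_UNITS",
    "relative_enhancement",
    "dce_maps",
    "adc_map",
    "t2_map",
    "all_maps",
    "write_map",
    "read_map",
    "read_dce",
]

MAP_UNITS = {
    "ADC": "mm^2/s",
    "T2SI": "a.u.",
    "PEAK": "dimensionless",
    "AUC_ENH": "s",
    "TME": "s",
    "WASHIN": "1/s",
    "WASHOUT": "1/s",
}

MAP_NAMES = tuple(MAP_UNITS)


@dataclass
class DceSeries:
    """Dynamic contrast-enhanced acquisition: 4D signal + time vector."""

    signal: np.ndarray  # (x, y, z, t), a.u., >= 0
    times: np.ndarray  # seconds, times[0] = 0 (pre-contrast)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, t)")
        if self.times.ndim != 1 or self.times.size != self.signal.shape[-1]:
            raise ValueError("times length must match the dynamic dimension")
        if self.times.size < 3:
            raise ValueError("need at least 3 acquisitions (1 pre + 2 post)")
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValueError("signal must be finite and nonnegative")


@dataclass
class ParameterMap:
    """A named 3D voxel map with units and a validity mask."""

    name: str
    values: np.ndarray
    units: str = ""
    valid: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ParameterMap values must be 3D")
        if not self.units:
            self.units = MAP_UNITS.get(self.name, "")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape must match values")


def relative_enhancement(
    series: DceSeries, epsilon_s0: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel relative enhancement E(t) = (S(t) - S(0)) / S(0).

    Voxels whose pre-contrast signal is at or below ``epsilon_s0``
    (default: 1e-6 of the 99th-percentile pre-contrast signal) are
    marked invalid — the normalization is undefined there.
    """
    s0 = series.signal[..., 0]
    if epsilon_s0 is None:
        epsilon_s0 = 1e-6 * float(np.percentile(s0, 99))
    valid = s0 > epsilon_s0
    if not valid.any():
        logger.warning("relative_enhancement: no voxel has usable baseline signal")
    safe_s0 = np.where(valid, s0, 1.0)
    enh = (series.signal - safe_s0[..., None]) / safe_s0[..., None]
    enh[~valid] = np.nan
    return enh, valid


def dce_maps(series: DceSeries, epsilon_s0: float | None = None) -> dict[str, ParameterMap]:
    """Compute the five kinetic maps (PEAK, TME, AUC_ENH, WASHIN, WASHOUT)."""
    enh, valid = relative_enhancement(series, epsilon_s0)
    times = series.times
    post = np.nan_to_num(enh[..., 1:], nan=0.0)

    peak = post.max(axis=-1)
    # argmax returns the first occurrence -> earliest peak on ties
    tme = times[1:][np.argmax(post, axis=-1)]
    e_full = np.nan_to_num(enh, nan=0.0)
    auc = np.trapezoid(e_full, times, axis=-1)
    washin = peak / tme
    last = e_full[..., -1]
    dt = times[-1] - tme
    washout = np.where(dt > 0, (peak - last) / np.where(dt > 0, dt, 1.0), 0.0)

    out = {}
    for name, vals in (("PEAK", peak), ("TME", tme), ("AUC_ENH", auc),
                       ("WASHIN", washin), ("WASHOUT", washout)):
        v = np.where(valid, vals, np.nan)
        out[name] = ParameterMap(name, v, MAP_UNITS[name], valid.copy())
    return out


def adc_map(s_b0: np.ndarray, s_b900: np.ndarray, b: float = 900.0) -> ParameterMap:
    """Two-point apparent diffusion coefficient: ln(S_b0/S_bhigh) / b.

    Voxels where either signal is non-positive are invalid.  Negative
    ADC values (noise floor pushing S_bhigh above S_b0) are retained
    and counted in the log.
    """
    s_b0 = np.asarray(s_b0, dtype=float)
    s_b900 = np.asarray(s_b900, dtype=float)
    if s_b0.shape != s_b900.shape:
        raise ValueError("b=0 and high-b volumes must share a shape")
    if b <= 0:
        raise ValueError("b must be > 0")
    valid = (s_b0 > 0) & (s_b900 > 0)
    adc = np.full(s_b0.shape, np.nan)
    adc[valid] = np.log(s_b0[valid] / s_b900[valid]) / b
    n_neg = int((adc[valid] < 0).sum())
    if n_neg:
        logger.info("adc_map: %d voxels with negative ADC retained (noise floor)", n_neg)
    return ParameterMap("ADC", adc, MAP_UNITS["ADC"], valid)


def t2_map(t2_volume: np.ndarray) -> ParameterMap:
    """Identity pass-through of raw T2 intensities (non-finite -> invalid)."""
    vol = np.asarray(t2_volume, dtype=float)
    return ParameterMap("T2SI", vol, MAP_UNITS["T2SI"], np.isfinite(vol))


def all_maps(series: DceSeries, s_b0: np.ndarray, s_b900: np.ndarray,
             t2_volume: np.ndarray, b: float = 900.0,
             epsilon_s0: float | None = None) -> dict[str, ParameterMap]:
    """All seven parameter maps for one patient, keyed by map name."""
    maps = dce_maps(series, epsilon_s0)
    maps["ADC"] = adc_map(s_b0, s_b900, b)
    maps["T2SI"] = t2_map(t2_volume)
    return maps


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_map(pmap: ParameterMap, path: str | Path,
              affine: np.ndarray | None = None) -> Path:
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(pmap.values.astype(np.float32),
                          np.eye(4) if affine is None else affine)
    img.header["descrip"] = f"{pmap.name} [{pmap.units}]".encode()[:79]
    nib.save(img, path)
    return path


def read_map(path: str | Path, name: str) -> ParameterMap:
    import nibabel as nib

    vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    return ParameterMap(name, vol, MAP_UNITS.get(name, ""))


def read_dce(path: str | Path, times: np.ndarray) -> DceSeries:
    import nibabel as nib

    sig = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    return DceSeries(sig, np.asarray(times, dtype=float))
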