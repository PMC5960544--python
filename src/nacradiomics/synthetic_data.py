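"""Digital multiparametric breast-MRI phantoms and synthetic NAC cohorts.

Every downstream stage of the pipeline (parameter maps, histogram
features, response labels, ROC statistics) is exercised against cohorts
produced here, with known per-voxel ground truth.  A phantom is an
ellipsoidal "tumor" embedded in a uniform background, partitioned into
concentric subregions (hypervascular rim, fibrotic band, necrotic core)
whose voxels carry semi-quantitative kinetic parameters:

* a piecewise-linear relative-enhancement curve — linear rise from 0 to
  ``amplitude`` at time ``tme``, then linear decline at
  ``washout_slope`` (floored at zero);
* a mono-exponential diffusion signal ``s0 * exp(-b * adc)`` at two
  b-values (0 and 900 s/mm^2), acquired as ``dwi_averages`` averaged
  magnitude samples (diffusion gradients along x, y and z);
* a T2 signal intensity.

Noise is Rician (magnitude MRI).  All randomness flows from a single
integer seed, so identical specs produce bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "KineticParams",
    "SubregionSpec",
    "PhantomSpec",
    "EffectSpec",
    "SyntheticPatient",
    "enhancement_forward",
    "make_phantom",
    "make_cohort",
    "default_subregions",
    "write_cohort",
]

RESPONSE_LABELS = ("CR", "PR", "SD", "PD")
SUBTYPE_LABELS = ("LuminalA", "LuminalB", "TripleNegative", "HER2")

#: Histological-subtype frequencies of the emulated cohort
#: (6/24/21/18 of 69: Luminal A / Luminal B / triple-negative / HER2).
SUBTYPE_PROBS = (6 / 69, 24 / 69, 21 / 69, 18 / 69)

DEFAULT_TIMES = (0.0, 90.0, 180.0, 270.0, 360.0, 450.0)


@dataclass(frozen=True)
class KineticParams:
    """Noiseless voxel-level signal model parameters.

    amplitude : peak relative enhancement (dimensionless, >= 0)
    tme : time to maximal enhancement (s, > 0)
    washout_slope : post-peak enhancement decline rate (1/s, >= 0)
    adc : apparent diffusion coefficient (mm^2/s, > 0)
    t2si : T2 signal intensity (a.u., >= 0)
    s0 : baseline pre-contrast signal (a.u., > 0)
    """

    amplitude: float
    tme: float
    washout_slope: float
    adc: float
    t2si: float
    s0: float

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        for name, v in vals.items():
            if not math.isfinite(v):
                raise ValueError(f"KineticParams.{name} must be finite, got {v}")
        if self.amplitude < 0 or self.washout_slope < 0 or self.t2si < 0:
            raise ValueError("amplitude, washout_slope and t2si must be >= 0")
        if self.tme <= 0 or self.adc <= 0 or self.s0 <= 0:
            raise ValueError("tme, adc and s0 must be > 0")


@dataclass(frozen=True)
class SubregionSpec:
    """One tumor compartment: label, volume fraction and parameter distribution.

    ``spread`` maps KineticParams field names to normal standard
    deviations; omitted fields get zero spread.  Subregions listed first
    occupy the outermost shell of the lesion.
    """

    label: str
    fraction: float
    mean: KineticParams
    spread: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("hypervascular", "necrotic", "fibrotic"):
            raise ValueError(f"unknown subregion label {self.label!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("subregion fraction must be in [0, 1]")
        unknown = set(self.spread) - set(dataclasses.asdict(self.mean))
        if unknown:
            raise ValueError(f"spread refers to unknown fields {sorted(unknown)}")


def default_subregions(
    amplitude_shift_sd: float = 0.0,
    tme_shift_sd: float = 0.0,
    washout_shift_sd: float = 0.0,
) -> tuple[SubregionSpec, ...]:
    """Default three-compartment tumor, optionally shifted for nonresponders.

    Rim-to-core order: hypervascular (50%), fibrotic (30%), necrotic
    (20%).  Shifts are expressed in units of the corresponding
    compartment spread: amplitude and TME shifts act on the
    hypervascular rim (driving the enhancement-AUC maximum and upper
    TME percentiles), the washout shift acts (negatively) on the
    necrotic core, the low-washout compartment that dominates the low
    washout percentiles.
    """
    hyper = SubregionSpec(
        "hypervascular",
        0.5,
        KineticParams(
            amplitude=2.0 + 0.35 * amplitude_shift_sd,
            tme=180.0 + 60.0 * tme_shift_sd,
            washout_slope=1.5e-3,
            adc=0.9e-3,
            t2si=300.0,
            s0=500.0,
        ),
        {"amplitude": 0.35, "tme": 60.0, "washout_slope": 4e-4,
         "adc": 1e-4, "t2si": 40.0, "s0": 40.0},
    )
    fibro = SubregionSpec(
        "fibrotic",
        0.3,
        KineticParams(
            amplitude=0.9,
            tme=270.0 + 60.0 * tme_shift_sd,
            washout_slope=5e-4,
            adc=1.2e-3,
            t2si=250.0,
            s0=450.0,
        ),
        {"amplitude": 0.2, "tme": 60.0, "washout_slope": 2e-4,
         "adc": 1.5e-4, "t2si": 30.0, "s0": 40.0},
    )
    necro = SubregionSpec(
        "necrotic",
        0.2,
        KineticParams(
            amplitude=0.4,
            tme=360.0,
            washout_slope=max(8e-4 - 3e-4 * washout_shift_sd, 1e-5),
            adc=2.2e-3,
            t2si=600.0,
            s0=420.0,
        ),
        {"amplitude": 0.15, "tme": 60.0, "washout_slope": 3e-4,
         "adc": 2e-4, "t2si": 60.0, "s0": 40.0},
    )
    return (hyper, fibro, necro)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to synthesize one patient's image set."""

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 2.2)
    acquisition_times: tuple[float, ...] = DEFAULT_TIMES
    b_values: tuple[float, float] = (0.0, 900.0)
    subregions: tuple[SubregionSpec, ...] = field(default_factory=default_subregions)
    noise_sigma: float = 0.0
    dwi_averages: int = 3
    seed: int = 0
    background_s0: float = 60.0
    background_adc: float = 2.0e-3
    background_t2si: float = 80.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive integers")
        t = np.asarray(self.acquisition_times, dtype=float)
        if t.size < 3 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError(
                "acquisition_times must start at 0, be strictly increasing, length >= 3"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.dwi_averages < 1:
            raise ValueError("dwi_averages must be >= 1")
        total = sum(r.fraction for r in self.subregions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subregion fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class EffectSpec:
    """Group-level kinetic shift applied to nonresponders, in spread units."""

    amplitude_sd: float = 1.5
    tme_sd: float = 1.0
    washout_sd: float = 1.0

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(0.0, 0.0, 0.0)


@dataclass
class SyntheticPatient:
    """One simulated patient: images, mask, per-voxel truth and metadata."""

    patient_id: str
    dce: np.ndarray  # 4D (x, y, z, t)
    times: np.ndarray  # seconds, times[0] = 0
    dwi_b0: np.ndarray
    dwi_b900: np.ndarray
    t2: np.ndarray
    mask: np.ndarray  # 3D bool
    truth: dict[str, np.ndarray]  # per-voxel noiseless parameters (NaN outside)
    region_labels: np.ndarray  # 3D int, -1 outside, else index into subregions
    spec: PhantomSpec
    diameter_pre: float = 3.8  # cm
    diameter_post: float = 0.0  # cm
    response_label: str = "CR"
    subtype_label: str = "LuminalB"

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if self.dce.shape[:3] != self.mask.shape:
            raise ValueError("dce and mask must share the spatial grid")
        if self.diameter_pre <= 0 or self.diameter_post < 0:
            raise ValueError("diameters must be > 0 (pre) and >= 0 (post)")


def enhancement_forward(params: KineticParams, times: Sequence[float]) -> np.ndarray:
    """Evaluate the piecewise-linear relative-enhancement curve at ``times``.

    E(t) rises linearly from 0 at t=0 to ``amplitude`` at t=``tme``,
    then declines at ``washout_slope`` per second, floored at zero.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be 1D and strictly increasing")
    if t[0] != 0:
        raise ValueError("times[0] must be 0 (pre-contrast acquisition)")
    rise = params.amplitude * t / params.tme
    fall = params.amplitude - params.washout_slope * (t - params.tme)
    return np.where(t <= params.tme, rise, np.maximum(fall, 0.0))


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float,
            averages: int = 1) -> np.ndarray:
    """Magnitude-MRI noise: mean of ``averages`` Rician samples of ``signal``."""
    if sigma == 0:
        return signal.astype(float, copy=True)
    acc = np.zeros_like(signal, dtype=float)
    for _ in range(averages):
        re = signal + rng.normal(0.0, sigma, size=signal.shape)
        im = rng.normal(0.0, sigma, size=signal.shape)
        acc += np.hypot(re, im)
    return acc / averages


def _ellipsoid_mask(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Centered ellipsoid mask plus normalized squared radius (for shells)."""
    center = [(s - 1) / 2.0 for s in shape]
    semi = [max(0.38 * s, 1.0) for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    r2 = np.asarray(r2, dtype=float)
    return r2 <= 1.0, r2


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by the largest-remainder method."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _snap_tme(tme: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Snap continuous TME draws to the post-contrast acquisition grid.

    The enhancement curve is only observed at the acquisition times, so
    a peak between samples is not identifiable; snapping keeps the
    stored truth recoverable exactly from noiseless data.
    """
    post = times[1:]
    idx = np.argmin(np.abs(tme[:, None] - post[None, :]), axis=1)
    return post[idx]


def make_phantom(
    spec: PhantomSpec,
    patient_id: str = "P000",
    diameter_pre: float = 3.8,
    diameter_post: float = 0.0,
    response_label: str = "CR",
    subtype_label: str = "LuminalB",
) -> SyntheticPatient:
    """Synthesize one patient's DCE + DWI + T2 volumes with known truth.

    Deterministic given ``spec`` (which carries the seed).  The tumor is
    a centered ellipsoid; subregions are concentric shells assigned by
    descending ellipsoidal radius (rim first) in the order listed in
    ``spec.subregions``, with voxel counts apportioned by largest
    remainder and seeded tie-breaking on the radius ranking.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.acquisition_times, dtype=float)
    mask, r2 = _ellipsoid_mask(spec.grid_shape)
    n = int(mask.sum())
    if n < 0.05 * np.prod(spec.grid_shape):  # pragma: no cover - geometry guard
        raise ValueError("tumor occupies < 5% of the grid")

    flat_idx = np.flatnonzero(mask.ravel())
    # rim-to-core ordering; random jitter breaks exact radius ties reproducibly
    order = np.argsort(-(r2.ravel()[flat_idx] + rng.uniform(0, 1e-12, size=n)),
                       kind="stable")
    fractions = np.array([r.fraction for r in spec.subregions])
    counts = _largest_remainder(fractions, n)

    region = np.full(np.prod(spec.grid_shape), -1, dtype=int)
    start = 0
    for k, c in enumerate(counts):
        region[flat_idx[order[start:start + c]]] = k
        start += c
    region = region.reshape(spec.grid_shape)

    fields = ("amplitude", "tme", "washout_slope", "adc", "t2si", "s0")
    truth = {f: np.full(spec.grid_shape, np.nan) for f in fields}
    for k, sub in enumerate(spec.subregions):
        sel = region == k
        m = int(sel.sum())
        means = dataclasses.asdict(sub.mean)
        for f in fields:
            sd = float(sub.spread.get(f, 0.0))
            draw = rng.normal(means[f], sd, size=m) if sd > 0 else np.full(m, means[f])
            truth[f][sel] = draw
    inside = region >= 0
    # enforce physical ranges, identifiability of TME and nonnegative E(t_last)
    # floor keeps every tumor voxel minimally enhancing, so the sampled
    # curve has a unique peak and TME stays identifiable
    truth["amplitude"][inside] = np.clip(truth["amplitude"][inside], 0.05, None)
    truth["adc"][inside] = np.clip(truth["adc"][inside], 1e-5, None)
    truth["s0"][inside] = np.clip(truth["s0"][inside], 1.0, None)
    truth["t2si"][inside] = np.clip(truth["t2si"][inside], 0.0, None)
    truth["tme"][inside] = _snap_tme(truth["tme"][inside], times)
    # washout is unidentifiable (and defined 0) when the peak falls on the
    # last acquisition; elsewhere cap it so E stays >= 0 over the window
    dt_last = times[-1] - truth["tme"][inside]
    max_slope = np.where(
        dt_last > 0,
        truth["amplitude"][inside] / np.where(dt_last > 0, dt_last, 1.0),
        0.0,
    )
    truth["washout_slope"][inside] = np.clip(
        truth["washout_slope"][inside], 0.0, max_slope
    )

    # noiseless signals
    s0_vol = np.where(inside, truth["s0"], spec.background_s0)
    adc_vol = np.where(inside, truth["adc"], spec.background_adc)
    t2_vol = np.where(inside, truth["t2si"], spec.background_t2si)

    tt = times[None, None, None, :]
    amp = np.where(inside, truth["amplitude"], 0.0)[..., None]
    tme = np.where(inside, truth["tme"], times[1])[..., None]
    slope = np.where(inside, truth["washout_slope"], 0.0)[..., None]
    enh = np.where(tt <= tme, amp * tt / tme,
                   np.maximum(amp - slope * (tt - tme), 0.0))
    dce = s0_vol[..., None] * (1.0 + enh)

    b_lo, b_hi = spec.b_values
    dwi_b0_clean = s0_vol * np.exp(-b_lo * adc_vol)
    dwi_b900_clean = s0_vol * np.exp(-b_hi * adc_vol)

    dce = _rician(rng, dce, spec.noise_sigma)
    dwi_b0 = _rician(rng, dwi_b0_clean, spec.noise_sigma, spec.dwi_averages)
    dwi_b900 = _rician(rng, dwi_b900_clean, spec.noise_sigma, spec.dwi_averages)
    t2 = _rician(rng, t2_vol, spec.noise_sigma)

    return SyntheticPatient(
        patient_id=patient_id,
        dce=dce,
        times=times,
        dwi_b0=dwi_b0,
        dwi_b900=dwi_b900,
        t2=t2,
        mask=mask,
        truth=truth,
        region_labels=region,
        spec=spec,
        diameter_pre=diameter_pre,
        diameter_post=diameter_post,
        response_label=response_label,
        subtype_label=subtype_label,
    )


def _draw_diameters(rng: np.random.Generator, label: str) -> tuple[float, float]:
    """Baseline diameter (cm) and post-therapy diameter consistent with ``label``.

    Baseline sizes follow a lognormal clipped to 1.1-10.0 cm with mean
    ~3.8 cm, matching the emulated cohort's size distribution.
    """
    pre = float(np.clip(rng.lognormal(mean=np.log(3.4), sigma=0.45), 1.1, 10.0))
    if label == "CR":
        post = 0.0
    elif label == "PR":
        post = pre * (1.0 + rng.uniform(-0.90, -0.35))
    elif label == "SD":
        post = pre * (1.0 + rng.uniform(-0.25, 0.15))
    elif label == "PD":
        post = pre * (1.0 + rng.uniform(0.25, 0.60))
    else:  # pragma: no cover
        raise ValueError(f"unknown response label {label!r}")
    return pre, float(post)


def make_cohort(
    n_patients: int,
    response_mix: Sequence[float] = (0.478, 0.377, 0.145),
    effect: EffectSpec | None = None,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    noise_sigma: float = 0.0,
    nr_label: str = "SD",
    acquisition_times: Sequence[float] = DEFAULT_TIMES,
) -> list[SyntheticPatient]:
    """Simulate a cohort with a CR/PR/NR mix and a nonresponder kinetic shift.

    ``response_mix`` gives (CR, PR, NR) proportions; group sizes come
    from largest-remainder apportionment, so the default mix at n=69
    yields the emulated study's 33/26/10 split.  Nonresponders receive
    ``effect``-shifted kinetic means: higher hypervascular amplitude
    (hence higher enhancement-AUC maxima), longer TME, lower necrotic
    washout.  ``effect=EffectSpec.null()`` gives label-independent
    kinetics for null calibration.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    mix = np.asarray(response_mix, dtype=float)
    if mix.size != 3 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("response_mix must be 3 nonnegative proportions summing to 1")
    if nr_label not in ("SD", "PD"):
        raise ValueError("nr_label must be SD or PD")
    if effect is None:
        effect = EffectSpec()

    counts = _largest_remainder(mix, n_patients)
    if np.any((mix > 0) & (counts == 0)):
        raise ValueError("every nonzero response group needs at least one patient")
    labels = (["CR"] * counts[0] + ["PR"] * counts[1] + [nr_label] * counts[2])

    children = np.random.SeedSequence(seed).spawn(n_patients + 1)
    meta_rng = np.random.default_rng(children[0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in children[1:]]

    base_regions = default_subregions()
    nr_regions = default_subregions(
        amplitude_shift_sd=effect.amplitude_sd,
        tme_shift_sd=effect.tme_sd,
        washout_shift_sd=effect.washout_sd,
    )

    patients = []
    for i, label in enumerate(labels):
        regions = nr_regions if label in ("SD", "PD") else base_regions
        spec = PhantomSpec(
            grid_shape=grid_shape,
            acquisition_times=tuple(acquisition_times),
            subregions=regions,
            noise_sigma=noise_sigma,
            seed=child_seeds[i],
        )
        pre, post = _draw_diameters(meta_rng, label)
        subtype = str(meta_rng.choice(SUBTYPE_LABELS, p=SUBTYPE_PROBS))
        patients.append(
            make_phantom(
                spec,
                patient_id=f"P{i:03d}",
                diameter_pre=pre,
                diameter_post=post,
                response_label=label,
                subtype_label=subtype,
            )
        )
    return patients


def _affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.diag(list(spec.voxel_size) + [1.0])
    return aff


def write_cohort(patients: Sequence[SyntheticPatient], outdir: str | Path,
                 save_truth: bool = False) -> Path:
    """Write a cohort to disk: NIfTI volumes, cohort CSV and truth sidecar.

    Layout: ``dce_<id>.nii.gz`` (4D), ``dwi_b0/dwi_b900/t2/mask_<id>.nii.gz``
    (3D), ``cohort.csv`` and ``truth.json`` (acquisition times, seeds and
    per-region parameter means; full per-voxel truth maps as NIfTI when
    ``save_truth``).
    """
    import nibabel as nib
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    sidecar: dict = {"patients": {}}
    for p in patients:
        aff = _affine(p.spec)
        nib.save(nib.Nifti1Image(p.dce.astype(np.float32), aff),
                 outdir / f"dce_{p.patient_id}.nii.gz")
        for name, vol in (("dwi_b0", p.dwi_b0), ("dwi_b900", p.dwi_b900),
                          ("t2", p.t2)):
            nib.save(nib.Nifti1Image(vol.astype(np.float32), aff),
                     outdir / f"{name}_{p.patient_id}.nii.gz")
        nib.save(nib.Nifti1Image(p.mask.astype(np.uint8), aff),
                 outdir / f"mask_{p.patient_id}.nii.gz")
        if save_truth:
            for f, vol in p.truth.items():
                nib.save(nib.Nifti1Image(vol.astype(np.float32), aff),
                         outdir / f"truth_{f}_{p.patient_id}.nii.gz")
        rows.append(
            dict(patient_id=p.patient_id,
                 diameter_pre_cm=round(p.diameter_pre, 4),
                 diameter_post_cm=round(p.diameter_post, 4),
                 response_label=p.response_label,
                 subtype_label=p.subtype_label)
        )
        sidecar["patients"][p.patient_id] = {
            "seed": p.spec.seed,
            "acquisition_times_s": list(p.times),
            "b_values": list(p.spec.b_values),
            "noise_sigma": p.spec.noise_sigma,
            "region_means": {
                sub.label: dataclasses.asdict(sub.mean)
                for sub in p.spec.subregions
            },
        }
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return outdir
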