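"""Shared configuration for the numbered analysis scripts.

The demonstration cohort: 60 patients with the emulated response mix,
a strong (2 SD) nonresponder shift of the hypervascular enhancement
amplitude, 12 x 12 x 10 voxel grids and mild Rician noise (2% of the
hypervascular baseline).  Heavy intermediates (NIfTI volumes, the full
feature table) go under scratch/; small summary tables under results/.
"""

from pathlib import Path

from nacradiomics.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def demo_config(seed: int = 7) -> RunConfig:
    return RunConfig(
        outdir=str(RUN_DIR),
        seed=seed,
        n_patients=60,
        effect_amplitude_sd=2.0,
        effect_tme_sd=1.0,
        effect_washout_sd=1.0,
        grid_shape=(12, 12, 10),
        noise_sigma=10.0,
        n_perm=2000,
    )
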