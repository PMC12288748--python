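"""Quantify measurement noise with replicate photographs.

Simulates duplicate photos per view under realistic jitter (illumination
gain, sub-pixel shift, small rotation), measures every replicate, and
reports within-individual CVs (replicate noise), across-individual CVs
(true variation) and their ratio — the fraction of apparent
between-individual variability that is really measurement noise.
"""

import tempfile

import scutepattern as sp
from scutepattern.measures import SymmetrySearchGrid
from scutepattern.pipeline import PipelineConfig, run_pipeline, simulate_dataset

with tempfile.TemporaryDirectory() as tmp:
    manifest = simulate_dataset(
        tmp, n_turtles=4, replicates=2, seed=1, views=("top", "left")
    )
    config = PipelineConfig(
        symmetry_grid=SymmetrySearchGrid(angle_step=30, refine_angle_step=None)
    )
    bundle = run_pipeline(config, manifest, tmp + "/results", image_root=tmp)

cv = bundle["cv"].sort_values("noise_ratio")
print(cv.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nwithin_cv: replicate-to-replicate CV (photo noise); across_cv:"
      "\nbetween-turtle CV of replicate means; noise_ratio = within/across —"
      "\nvalues above 0.10 flag measures whose apparent variation is"
      "\nsubstantially contaminated by measurement noise.")
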