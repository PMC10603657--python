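"""Evaluate a trained checkpoint with the number-of-clicks (NoC) protocol.

The protocol mimics a user: first click at the object's interior-most
pixel, then corrective clicks at the centre of the largest error region,
until IoU reaches the threshold or the 20-click cap. mNoC is the mean
click count over the dataset - the headline metric of an interactive
segmentation model (lower is better; 1.0 is perfect).

Run examples/03_train_small_model.py first to produce the checkpoint.
"""

from pathlib import Path

import numpy as np

from clickseg.evaluation import mnoc, reached_fraction
from clickseg.io import load_checkpoint
from clickseg.network import predict_mask
from clickseg.synthetic import SynthConfig, generate_instance

ckpt = Path("scratch/example_run/checkpoint.npz")
if not ckpt.exists():
    raise SystemExit("run examples/03_train_small_model.py first")

model, _ = load_checkpoint(ckpt)

cfg = SynthConfig(
    image_size=64, blob_area_fraction_range=(0.08, 0.3),
    boundary_roughness=0.12, seed=7,
)
root = np.random.default_rng(7)
samples = [
    (s.image, s.mask)
    for s in (
        generate_instance(cfg, np.random.default_rng(int(root.integers(2**31))))
        for _ in range(8)
    )
]


def predictor(image, clicks):
    return predict_mask(model, image, clicks)[0]


for threshold in (0.85, 0.90):
    mean, records = mnoc(predictor, samples, threshold)
    print(f"mNoC@{int(threshold * 100)} = {mean:.2f}  "
          f"({reached_fraction(records) * 100:.0f}% of instances reached the threshold)")
# On the memorised training instances the model needs very few clicks;
# instances that never reach the threshold would be counted at the cap (20).
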