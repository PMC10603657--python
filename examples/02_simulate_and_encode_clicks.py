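"""Simulate user clicks on one instance and encode them as guidance maps.

Positive clicks land well inside the object (margin P1 from the background,
P2 from each other); negative clicks land in a band around it (distance to
the object in (N1, N2), margin N3 apart). Each polarity becomes a map of
per-pixel Euclidean distance to the nearest click, truncated at 255 - the
two extra channels the network sees besides RGB.
"""

import numpy as np

from clickseg.clicks import ClickGenParams, encode_click_set, simulate_clicks
from clickseg.synthetic import SynthConfig, generate_instance

cfg = SynthConfig(image_size=96, blob_area_fraction_range=(0.15, 0.25), seed=5)
sample = generate_instance(cfg, np.random.default_rng(5))

rng = np.random.default_rng(11)
# ClickGenParams.draw(rng) samples the margins from their pools; the pool
# values suit full-size (512 px) frames, so this small demo fixes margins
# that leave room for a negative band inside a 96 px image.
params = ClickGenParams(p1=5, p2=7, n1=15, n2=80, n3=10)
clicks = simulate_clicks(sample.mask, params, n_pos=3, n_neg=3, rng=rng)

print(f"margins: P1={params.p1} P2={params.p2} "
      f"N1={params.n1} N2={params.n2} N3={params.n3}")
print(f"positive clicks: {[(c.row, c.col) for c in clicks.positives]}")
print(f"negative clicks: {[(c.row, c.col) for c in clicks.negatives]}")

d_pos, d_neg = encode_click_set(clicks, 96, 96)
r, c = clicks.positives[0].row, clicks.positives[0].col
print(f"guidance maps: shape {d_pos.shape}, range [{d_pos.min():.0f}, {d_pos.max():.1f}]")
print(f"positive map at first click ({r},{c}): {d_pos[r, c]:.0f}  (zero by construction)")
# Each map entry is the distance in pixels to the nearest click of that
# polarity; far-field values saturate at the truncation ceiling (255).
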