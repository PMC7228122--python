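"""Crop the black aperture margin and remove the burned-in timestamp.

The black border is found by thresholding luminance (default > 10 of
255) and taking the bounding box of the first/last bright row and
column; the timestamp is zero-filled in a fixed bottom-right region
(bottom 8% of height, right 25% of width).
"""

import numpy as np

from otolookup import SynthSpec, crop_roi, find_roi, generate_dataset, remove_timestamp
from otolookup.synthetic import inner_box

spec = SynthSpec(n_per_class=1, margin_fraction=0.15, seed=4)
img = generate_dataset(spec)[0]
truth = inner_box(spec)

box = find_roi(img)
print(f"input image        : {img.height}x{img.width}")
print(f"detected ROI       : rows [{box.row_start},{box.row_stop}), cols [{box.col_start},{box.col_stop})")
print(f"generator's truth  : rows [{truth.row_start},{truth.row_stop}), cols [{truth.col_start},{truth.col_stop})")
assert box == truth  # the margin is exactly black, so recovery is exact

crop = crop_roi(img, box)
print(f"after margin crop  : {crop.height}x{crop.width}")

white_before = int(np.all(crop.pixels == 255, axis=2).sum())
clean = remove_timestamp(crop)
white_after = int(np.all(clean.pixels == 255, axis=2).sum())
print(f"solid-white pixels : {white_before} before timestamp removal, {white_after} after")
# 0 after: the generator places its timestamp inside the default removal region.
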