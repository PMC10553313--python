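"""The differentiable crop: smooth boxcar mask, corners, and zoom.

Builds a box, prints its corners, shows that the smooth mask approaches the
hard 0/1 indicator as the steepness grows, and crops-and-zooms a synthetic
image to the network input size.
"""

import numpy as np

from pestnet import AttentionBox, CropConfig, SceneSpec
from pestnet.attention import attention_mask, box_corners, crop_and_zoom, mask_gradient_signs
from pestnet.synthetic import generate_scene

box = AttentionBox(tx=100, ty=80, tl=30)
print("corners (x_tl, y_tl, x_br, y_br):", box_corners(box))  # (70, 50, 130, 110)

im = generate_scene(SceneSpec(seed=3), class_id=2, rng=np.random.default_rng(3))
b = im.truth_box
for k in (1, 10, 1e4):
    m = attention_mask(b, im.pixels.shape[:2], steepness=k)
    print(f"steepness {k:>6}: mask at patch center {m[int(b.ty), int(b.tx)]:.4f}, "
          f"5px outside {m[int(b.ty), max(0, int(b.tx - b.tl) - 5)]:.2e}")

crop = crop_and_zoom(im.pixels, b, CropConfig(steepness=10, out_size=64))
print("crop shape:", crop.shape, "zoom factor: %.1fx" % (64 / (2 * b.tl)))

signs = mask_gradient_signs(b, [b.tx - b.tl, b.tx, b.tx + b.tl], steepness=10)
print("dM/dtx signs at [left edge, center, right edge]:", signs)
# The negative/zero/positive pattern is the gradient signal that pulls a
# trained attention head's box edges toward informative pixels.
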