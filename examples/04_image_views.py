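"""Image-derived views: paired pixel rows and quadrant multiview splits.

Uses a synthetic stack of Gaussian-random-field images whose pixel
correlations decay with distance.  Splitting each image into four
quadrants makes the pixels at the shared corner — the image center —
the most correlated across views, so the multiview neuron's weights
should concentrate there.
"""

import numpy as np

import neurocca as nc
from neurocca.multiview import variance_contribution

images = nc.make_correlated_images(T=3000, H=8, W=8, length_scale=2.0, seed=10)

# paired views from one pixel row
row_ds = nc.split_image_rows(images, row_index=4, cols_x=(0, 4), cols_y=(4, 8))
rho1 = nc.solve_cca(row_ds, d=1).rho[0]
print(f"top canonical correlation of adjacent row halves = {rho1:.3f}")

# multiview from quadrants
mv = nc.split_image_quadrants(images)
state, trace = nc.train_multiview(mv, n_steps=1_500_000, seed=11, metric_every=100_000)
print(f"final absolute objective across quadrants        = "
      f"{trace.final_window_mean('absolute_objective'):.3f}")

contrib = variance_contribution(state, mv)
center = {0: (3, 3), 1: (3, 0), 2: (0, 3), 3: (0, 0)}   # pixel touching the center
far = {0: (0, 0), 1: (0, 3), 2: (3, 0), 3: (3, 3)}      # opposite corner
for v in range(4):
    u = contrib[v].reshape(4, 4)
    print(f"view {v}: variance contribution center-adjacent {u[center[v]]:.3f} "
          f"vs far corner {u[far[v]]:.3f}")
# The contribution at each quadrant's center-adjacent pixel should
# dominate its far corner: the neuron picks the mutually closest, most
# correlated pixels.
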