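"""List-mode MLEM tomography of the spherical source.

Iterates the multiplicative update
    lambda_j <- lambda_j / s_j * sum_i t_ij / (sum_k t_ik lambda_k)
from a flat start. Around 50 iterations give a clean sphere; pushing to high
iteration counts develops speckle ("granularity") inside the source, which
the coefficient-of-variation metric quantifies.

Runs a few minutes at this event count (sparse system matrix on the full
100^3 grid).
"""

import numpy as np

import bnctcam as bc

config = bc.SimulationConfig(phantom=bc.PhantomGeometry.air(), seed=3)
events = bc.generate_true_events(config, 600)
grid = bc.VoxelGrid()

run = bc.mlem_reconstruct(events, grid, n_iter=150, snapshot_every=50)
truth = bc.truth_mask_3d(grid, config.source)
region = truth[:, :, grid.origin_index]

for it in sorted(run.image_history):
    img = run.image_history[it]
    sl = img.intensity[:, :, grid.origin_index]
    ii, jj = np.indices(sl.shape)
    w = sl / sl.sum()
    cx = grid.lower + ((ii * w).sum() + 0.5) * grid.voxel_side
    cy = grid.lower + ((jj * w).sum() + 0.5) * grid.voxel_side
    cv = bc.granularity_metric(img, region)
    print(f"iter {it:3d}: XY centroid ({cx:+.2f}, {cy:+.2f}) mm, "
          f"in-source speckle CV = {cv:.2f}")
# The centroid stays within a voxel or two of the origin while the speckle
# CV grows monotonically with iterations - the reason to stop around 50.
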