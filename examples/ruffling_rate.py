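"""Measure the ruffling rate of a synthetic actin movie.

Builds a movie of one cell with stress fibers plus transient edge ruffles
covering on average 8% of the cell area, runs the full ruffling-rate
pipeline (rolling temporal median -> percent ratio -> multi-scale adaptive
segmentation -> cell segmentation -> per-frame percentage), and compares
the measured rate to the planted truth.
"""

import numpy as np

from bampquant import synthetic as syn
from bampquant.ruffle import ruffling_rate_pipeline

rng = np.random.default_rng(42)
scene = syn.SceneSpec(n_frames=60, noise_sd=10.0, seed=42)  # noise at 5% of signal
ruffles = syn.plan_ruffle_events(target_fraction=0.08, n_frames=60, rng=rng)
fibers = syn.StaticStructureSpec([syn.Fiber((40, 40), (90, 90), 3, 150)])

movie, truth = syn.generate_ruffle_movie(scene, ruffles, fibers)
planted = 100 * float(
    (truth.ruffle_masks.sum(axis=(1, 2)) / truth.cell_masks.sum(axis=(1, 2))).mean()
)

result = ruffling_rate_pipeline(movie)

print(f"planted time-averaged ruffle area: {planted:.2f} % of cell area")
print(f"measured ruffling rate:            {result.mean_rate_percent:.2f} % of cell area")
print(f"frames scored: {np.isfinite(result.per_frame_percent).sum()} / {movie.n_frames}")
# The measured rate is the per-video readout: the time-averaged percentage
# of the cell area occupied by fast-moving (high temporal frequency) actin
# regions. Static fibers contribute nothing because the rolling median
# absorbs them.
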