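"""Quantify reporter enrichment in newly formed protrusions.

Builds a two-channel movie (reporter + membrane marker) of a cell growing
a protrusive rim where the planted reporter:membrane ratio is 2.0 versus
1.0 in the cell body, then recovers the enrichment ratio: the mean
membrane-normalized reporter intensity inside protrusions (pixels present
at T1 but not T0) divided by that outside them.
"""

import numpy as np

from bampquant import synthetic as syn
from bampquant.enrichment import EnrichmentParams, enrichment_pipeline

h = w = 128
rr, cc = np.ogrid[:h, :w]
d2 = (rr - 64) ** 2 + (cc - 64) ** 2
spec = syn.ProtrusionSceneSpec(
    base_mask=d2 <= 30**2,
    full_mask=d2 <= 42**2,
    reporter_ratio_protrusive=2.0,
    reporter_ratio_body=1.0,
    noise_sd=5.0,  # 5% of the 100 AU membrane signal
    seed=7,
)
reporter, membrane, truth = syn.generate_protrusion_movie(spec)

params = EnrichmentParams(seg_threshold=50.0, t0_frame=0, t1_frame=spec.n_frames - 1,
                          membrane_floor=20.0)
result, partition, _ = enrichment_pipeline(reporter, membrane, params)

print(f"planted enrichment ratio:  {truth.reporter_ratio_protrusive / truth.reporter_ratio_body:.2f}")
print(f"measured enrichment ratio: {result.enrichment_ratio:.3f}")
print(f"mean normalized intensity: protrusive {result.mean_protrusive:.3f} "
      f"({result.n_px_protrusive} px), body {result.mean_non_protrusive:.3f} "
      f"({result.n_px_non_protrusive} px)")
# A ratio above 1 means the reporter concentrates in the new protrusions
# beyond what membrane geometry alone would produce.
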