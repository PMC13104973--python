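# bampquant

Quantification of **branched-actin membrane protrusions (BAMPs)** — ruffles
and lamellipodia — in fluorescence microscopy, for cell biologists studying
how protrusive actin structures relate to oncogenic signaling (e.g. KRAS
nanocluster/effector biology). The package implements five image-analysis
pipelines plus a synthetic-data generator that plants exact ground truth, so
every stage can be validated offline without any microscope data.

## What it computes

**Ruffling rate.** Ruffles move fast; stress fibers do not. At every pixel
of an actin movie the low-frequency baseline is the rolling temporal median
over ±25 frames (±50 s at a 2 s frame interval),

&nbsp;&nbsp;&nbsp;&nbsp;B(x, t) = median{ I(x, s) : |s − t| ≤ 25 },&nbsp;&nbsp;
R(x, t) = 100 · I(x, t) / B(x, t),

so static structure sits at R = 100 % and transient ruffles spike above it.
High-ratio regions are delineated per frame by multi-scale locally adaptive
(tile-Otsu) thresholding, related to the cell area segmented separately in
the raw movie, and the per-frame percentages are averaged over time:

&nbsp;&nbsp;&nbsp;&nbsp;rate = mean_t [ 100 · |ruffle_t ∩ cell_t| / |cell_t| ].

**Subcellular enrichment.** For a reporter (e.g. tagged KRAS-G12V) imaged
with a uniform membrane marker, N = reporter/membrane cancels membrane-fold
geometry. Cells are threshold-segmented at a baseline frame T0 and the
maximal-protrusion frame T1; protrusive pixels are mask(T1) \ mask(T0),
non-protrusive are mask(T0) ∩ mask(T1), and

&nbsp;&nbsp;&nbsp;&nbsp;enrichment = mean(N | protrusive) / mean(N | non-protrusive).

**3D PLA spot counting.** Proximity-ligation puncta in a z-stack: the
volume is resampled to isotropic voxels, intensities normalized to [0, 1]
between the 2nd and 99.8th percentiles, spots detected by
difference-of-Gaussians (min_sigma = 3, max_sigma = 6, threshold = 0.01),
and detections outside the cell removed using an actin-channel mask
(3-class Otsu keeping the brightest class → largest component → closing
(ball r = 3) → hole filling → erosion (ball r = 1)). Compartment density =
spot count / compartment area.

**Simplified 3D cell segmentation.** Gamma correction (γ = 0.8), 3×3×3
median filter, isotropization, percentile normalization, 1/4 downsampling;
per-slice Otsu in the x-y, x-z and y-z orthoviews with a 0.2 intensity
floor; majority-vote fusion of the three views and largest-component
selection (a documented simplification of gradient-flow consensus methods).

**Scalar readouts.** EdU proliferation = 100 · (EdU⁺ pixels)/(DAPI⁺ pixels)
with thresholds shared across compared samples; total cell fluorescence =
integrated density inside an ROI on a z sum-projection; blot densitometry =
(band/solvent-control band)/(loading/control loading), with band densities
integrated above a straight-line baseline of the lane profile.

## Worked example

```bash
python examples/ruffling_rate.py
```

```
planted time-averaged ruffle area: 7.96 % of cell area
measured ruffling rate:            8.27 % of cell area
frames scored: 60 / 60
```

The generator planted transient edge ruffles occupying on average 7.96% of
the cell area in a noisy 60-frame movie that also contains a bright static
stress fiber; the pipeline recovers 8.27% — the fiber contributes nothing
because the rolling median absorbs static signal. The other examples
(`enrichment.py`, `spot_counting.py`, `segmentation3d.py`,
`scalar_readouts.py`) follow the same pattern: build a scene with known
truth, run the pipeline, print measured vs planted.

Each stage is also exposed as a shell command on TIFF/CSV inputs:

```bash
bamp simulate --spec scene.yaml --out sim/ --seed 1
bamp ruffle-rate --movie sim/movie.tif --out results/
bamp enrich --reporter rep.tif --membrane mem.tif --threshold 50 --t1 19 --out results/
bamp spots --spot-channel pla.tif --actin-channel actin.tif --out results/
bamp density --spots results/spots.csv --mask roi.tif --out results/
bamp segment3d --volume stack.tif --out results/
bamp edu --edu edu.tif --dapi dapi.tif --threshold-edu 80 --threshold-dapi 80 --out results/
bamp densitometry --lanes lanes.csv --control DMSO --out results/
```

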