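# octlayers

Automatic annotation of retinal layers in optical coherence tomography
(OCT) B-scans. Given a single grayscale B-scan (rows = axial depth,
columns = lateral position), `octlayers` extracts the 8 interfaces that
delimit 7 retinal layers — ILM, NFL-GCL, IPL-INL, INL-OPL, OPL-ONL, IS-OS,
OS-RPE and RPE-Choroid, ordered from the vitreous to the choroid — fully
automatically, and scores segmentations against ground truth. It is aimed
at ophthalmic image-analysis researchers who need repeatable layer
boundaries (e.g. nerve-fibre-layer thickness for glaucoma monitoring)
without manual delineation.

## Method

**1. Fuzzy histogram hyperbolization (FHH).** OCT speckle is
multiplicative, non-Gaussian and spatially correlated, so the image is
first remapped through a fuzzy membership function and a hyperbolic
transform:

```
mu(g) = (g - g_min) / (g_max - g_min)
g'    = (L - 1)/(e^{-1} - 1) * (e^{-mu(g)^beta} - 1)
```

The fuzzifier `beta` is chosen per image from the linear index of
fuzziness `gamma(I) = 2/(MN) * sum min(mu, 1 - mu)`, scaled, shifted by a
stabilizer constant and clamped to an admissible window — small `beta`
behaves like histogram equalization, large `beta` quantizes towards a
segmentation.

**2. Gradient-polarity pixel graphs.** Each interface is either a
dark→bright or a bright→dark axial transition. Two sparse 8-connected
graphs are built over the pixels with edge weights

```
w_ab = 2 - g_a - g_b + w_min
```

where `g` is the min–max normalized vertical gradient of the matching
polarity. Weights are then re-fuzzified (`w'' = w'^{beta_w}` after min–max
normalization), which preserves their order but pushes boundary edges
further below interior edges. One virtual column of `w_min` edges is
appended on each lateral side so a path can enter and leave at any row.

**3. Sequential shortest paths.** Dijkstra's algorithm extracts one
minimum-weight lateral path at a time in the order ILM, IS-OS,
RPE-Choroid, NFL-GCL, OS-RPE, INL-OPL, IPL-INL, OPL-ONL, each later search
restricted between previously found boundaries (the anatomical prior that
interfaces are weakly depth-ordered and span the full width). The two
strongest dark→bright paths are labeled ILM/IS-OS by their mean row.

**4. Evaluation.** Boundary agreement is scored by MAD (symmetric mean
nearest-pixel distance) and per-column RMSE; layer masks by the Dice
coefficient; the nerve-fibre band (RNFLT, between ILM and NFL-GCL)
additionally by pixel accuracy, sensitivity (TPR) and error rate (FPR).

Because no public ground-truth dataset ships with the package, a phantom
generator renders layered B-scans with known boundaries, gamma-distributed
correlated speckle and vessel shadows, so the whole pipeline is testable
end to end (see `docs/methods.md`).

## Worked example

```sh
octlayers simulate --out scan.tiff --gt gt.csv --seed 7
octlayers segment scan.tiff --out-boundaries boundaries.csv --out-overlay overlay.png
octlayers eval --seg boundaries.csv --gt gt.csv --image-shape 256x512 --report report.json
```

Output of the run above:

```
phantom 256x512 seed=7 -> scan.tiff, truth -> gt.csv
segmented scan.tiff: beta=2.358 ordering_ok=True -> boundaries.csv
report -> report.json
```

`beta=2.358` is the fuzzifier selected for this scan from its fuzziness
index; `ordering_ok=True` confirms the 8 boundaries came out weakly
ordered top-to-bottom in every column. The report for this scan contains,
among others:

```
ILM MAD 0.018 | IS-OS MAD 0.034           # pixels, sub-pixel agreement
RNFLT {'accuracy': 0.9998, 'sensitivity': 0.9968,
       'error_rate': 0.0,  'dice': 0.9984}
```

i.e. the segmented nerve-fibre band overlaps the true band almost
perfectly despite 4-look speckle and two vessel shadows. Boundary CSVs are
0-based, top-left origin, one row per image column, in original
(pre-crop) coordinates; by default 15% of the image height is cropped from
the top before processing to discard the low-signal vitreous region.

The same pipeline is available from Python:

```python
from octlayers import PhantomSpec, simulate_bscan, run_pipeline, evaluate_result

image, truth = simulate_bscan(PhantomSpec(seed=7))
result, info = run_pipeline(image)
report = evaluate_result(result, truth)
```

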