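# Methods

This note documents the model, the parameters that matter, the synthetic
data the pipeline is validated on, and the numerical choices made where
the design was genuinely open.

## Enhancement: fuzzy histogram hyperbolization

Every pixel's grey level is mapped to a membership value by global
min–max normalization, `mu(g) = (g - g_min)/(g_max - g_min)`, and then
through the hyperbolic transform
`g' = (L-1)/(e^{-1}-1) * (e^{-mu^beta} - 1)`. The transform is monotone
non-decreasing in `mu`, attains 0 and `L-1` exactly at `mu = 0` and
`mu = 1` (computed in `expm1` ratio form so the endpoints are exact in
floating point), and its curvature is controlled by the fuzzifier `beta`:
near 0 it approximates histogram equalization, at 5 and above it behaves
like a quantization. The same min–max membership is used inside the
fuzziness index.

`beta` is selected per image as `beta = clamp(k * gamma(I) + C,
T_min, T_max)` where `gamma(I) = 2/(MN) * sum min(mu, 1-mu)` is the
linear index of fuzziness. The scaling `beta_0 = k * gamma` is this
package's design choice: the fuzziness index is the only image-derived
fuzzy statistic available at this stage, and scaling it gives the
per-image adaptivity the selection rule is meant to provide. The shift
`C` ("stabilizer") is applied once, not iterated. Defaults:

| parameter | default | meaning |
|---|---|---|
| `k` | 4.0 | fuzziness-to-fuzzifier scale |
| `C` | 0.5 | stabilizer shift |
| `T_min`, `T_max` | 0.5, 5.0 | admissible fuzzifier window |

With these defaults a typical retinal B-scan yields `beta` close to 2.2,
inside the window where the remap stretches the bright-band/dark-band
contrast without quantizing. `beta_override` bypasses selection (and the
clamp) entirely.

Intensities stay continuous throughout the pipeline; rounding to the
native bit depth happens only when an image is written to disk. 16-bit
input is processed at `L = 65536` rather than being rescaled — the
formulas are bit-depth-agnostic.

## Graph construction

The vertical gradient is the first difference along depth,
`D(r,c) = I(r,c) - I(r-1,c)` (positive = brighter below), the simplest
operator that distinguishes the two transition polarities; the top row,
which has no predecessor, gets a raw difference of 0. `D` is min–max
rescaled to [0,1] globally to give the dark→bright map; the
bright→dark map is its pointwise complement. A constant image produces a
flat 0.5 map and a warning rather than an error, so degenerate tiles fail
softly.

Edge weights over the 8-connected pixel grid are
`w_ab = 2 - g_a - g_b + w_min`, spanning `[w_min, 2 + w_min]`.
8-connectivity is the default (configurable to 4) because sloped
boundaries need diagonal steps to advance one column per edge.
`w_min = 1e-5` — small against any interior weight, strictly positive as
Dijkstra requires, and the exact cost of every virtual-column edge.

Weight fuzzification normalizes all edge weights of one graph globally to
[0,1] and raises them to `beta_w = 2.0` (a constant rather than an
image-derived value: the edge set is ~8x the pixel count and a fixed
exponent avoids a second fuzziness pass). The map is monotone, so edge
ranking is unchanged. Because the global minimum normalizes to exactly 0,
`w_min` is added back after the power map — a zero-weight edge inside the
image would otherwise create free detours and break shortest-path
semantics.

One virtual column per side is appended (two in total), all incident
edges at `w_min`; traversing a whole column costs `(H-1) * w_min`,
negligible against a single interior edge, so a path effectively enters
and exits at whatever rows suit it.

## Sequential segmentation

Dijkstra (scipy's sparse implementation, fixed row-major node order, so
results are deterministic; among exactly tied paths the choice is
implementation-defined but stable) runs from the top of the left virtual
column to the top of the right one. The search region is restricted by
node masking — excluded pixels are simply absent from the assembled
matrix — rather than by weight inflation, with a margin of 1 row on each
side of a delimiting boundary so the delimiter cannot be re-found. The
path is converted to one row per column; when 8-connectivity makes a path
visit several rows of the same column, the last-visited row is kept,
which yields single-valued boundaries.

Order of extraction and polarity:

1. **ILM** — dark→bright, whole image (the vitreous→NFL step is the
   strongest such transition and lies above all vessel shadows);
2. **IS-OS** — dark→bright, below the first path; the two paths are then
   assigned ILM/IS-OS by mean row (smaller mean = ILM), which absorbs the
   case where the first search latched onto the IS-OS;
3. **RPE-Choroid** — bright→dark over the whole image (it is the global
   bright→dark optimum; a config flag `rpe_below_isos` restricts the
   search below the IS-OS for very noisy data);
4. **NFL-GCL** — bright→dark between ILM and IS-OS;
5. **OS-RPE** — dark→bright between IS-OS and RPE-Choroid;
6. **INL-OPL** — dark→bright between NFL-GCL and IS-OS;
7. **IPL-INL** — bright→dark between NFL-GCL and INL-OPL;
8. **OPL-ONL** — bright→dark between INL-OPL and IS-OS.

A stage whose region is empty or disconnected aborts with the stage name.
A violated top-to-bottom weak ordering of the final 8 boundaries is
*flagged* on the result (`ordering_ok = False`), never silently repaired:
an inverted result is diagnostic information.

Before any processing, 15% of the image height is cropped from the top
(configurable), and all exported rows are shifted back into original
coordinates (0-based, row 0 at the top).

## Evaluation metrics

* **MAD**: `0.5 * (mean_{p in GT} d(p, SEG) + mean_{p in SEG} d(p, GT))`
  with 2D Euclidean pixel distances (the nearest-pixel metric is not
  otherwise constrained; Euclidean is the natural choice and makes MAD
  symmetric and bounded by the image diagonal). Accepts boundary
  polylines or binary masks.
* **RMSE**: per-column root mean squared row difference, reported in raw
  pixels.
* **Dice**: `2|GT ∩ SEG| / (|GT| + |SEG|)` on layer masks. Layer masks
  are half-open bands `[upper boundary, lower boundary)` per column, so
  the 7 layers exactly partition the ILM..RPE-Choroid band; the RNFLT
  band used for the confusion metrics is the set of pixels strictly
  between ILM and NFL-GCL.
* **Accuracy / sensitivity (TPR) / error rate (FPR)** from the pixel
  confusion counts; each ratio raises an explicit error when its
  denominator is degenerate instead of returning NaN.
* Aggregation over an image set is per-image metrics followed by mean and
  sample standard deviation.

## Synthetic phantoms

The generator renders a piecewise-constant axial reflectivity profile per
column from 8 smooth interface curves, then applies vessel shadows and
speckle in that (physical) order. Defaults define the standard validation
conditions: 256×512 pixels, 8-bit range, interfaces at gently sloped
quadratic curves (per-interface tilt ≤ 3 px and curvature ≤ 2 px across
the width, drawn once from the seed, so adjacent columns never differ by
more than one row; an optional foveal dip is off by default), mean
reflectivities

```
vitreous 20 | NFL 200 | GCL+IPL 100 | INL 60 | OPL 120
ONL+IS 55   | OS 185  | RPE 240     | choroid 70
```

chosen so each interface exhibits the transition polarity and relative
strength that the extraction order relies on in real scans — ILM the
strongest dark→bright step, IS-OS second, RPE-Choroid the strongest
bright→dark drop — and verified (numerically, across the whole
`[T_min, T_max]` fuzzifier window) to keep those orderings after the
monotone FHH remap. A boundary row is defined as the first row of the
deeper layer, the same row at which the axial first difference peaks, so
a perfect segmentation reproduces the ground truth exactly.

**Speckle** is multiplicative unit-mean gamma noise (shape = number of
"looks", default 4, i.e. σ/μ = 0.5 before correlation), smoothed with a
σ = 0.75 px Gaussian kernel before multiplication to mimic the
neighbourhood correlation of real speckle — the simplest model that is
simultaneously non-Gaussian, multiplicative and correlated. Smoothing
preserves the unit mean; the product is clipped to the valid grey range,
which slightly trims the brightest tail. **Vessel shadows** (default two:
centers at 0.3 and 0.7 of the width, 12 and 16 px wide, attenuations 0.55
and 0.65) multiply everything below the NFL-GCL interface by their
attenuation, at full strength inside the band with a cosine flank taper.

What the phantom does *not* emulate: pathology (drusen, edema, cysts),
the foveal pit's layer thinning by default, depth-dependent signal decay,
motion artefacts, or vendor-specific noise floors. Passing the phantom
benchmarks therefore demonstrates correctness of the algorithmic chain
and robustness to the dominant noise sources, not clinical-grade accuracy
on diseased eyes.

## Problem sizes and expected numbers

The validation suite uses 256×512 phantoms (after the 15% crop the graph
has ~112k nodes and ~900k directed edges; a full 8-boundary segmentation
takes well under a second). The standard speckled benchmark averages 20
phantoms at the default noise settings; on it the pipeline achieves mean
boundary MAD below 0.1 px for the three strong interfaces (ILM, IS-OS,
RPE-Choroid) and below 0.6 px for the inner interfaces, with RNFLT Dice
above 0.99 — the noise-free step phantom is recovered exactly (MAD =
RMSE = 0, Dice = 1). These are the quantities `scripts/acceptance.py`
recomputes.

## Known limitations

* Global min–max gradient normalization is sensitive to single extreme
  pixels; on real scans with hot pixels a robust percentile rescale may
  be preferable.
* The mean-row disambiguation assumes the two strongest dark→bright
  paths are the ILM and IS-OS; severe shadowing of the photoreceptor
  band could violate this.
* RMSE is reported in raw pixels by design; published per-layer RMSE
  figures for this family of methods are sometimes on a different,
  unstated normalization scale and are not directly comparable.
* Region limitation assumes the delimiting boundaries are correct;
  an early-stage error propagates to dependent stages (flagged by the
  ordering check rather than corrected).
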