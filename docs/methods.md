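# Methods

## Segmentation model and conventions

The pipeline assumes DAB (brown) chromogen on cytokeratin-positive tumour
with a haematoxylin (blue-purple) counterstain. Brown is the darkest
signal in the blue channel while the counterstain and bare glass are both
pale there, so segmentation runs on blue alone; red and green are
discarded.

**Thresholding.** The default method is iterated intermeans (isodata):
`t ← floor((mean(levels ≤ t) + mean(levels > t)) / 2)` on the 256-bin
histogram, iterated upward from the darkest occupied level. The step map
is monotone, so this converges to the *least* fixed point — the split
between dark objects and everything pale, even when the pale side has two
close modes (counterstain next to glass). Starting from the overall mean
instead can land on the counterstain/glass fixed point and flood the whole
spot; starting low is therefore a correctness choice, not a convention.
`t` is clamped to keep both classes non-empty; a constant image raises a
degenerate-histogram error, which the pipeline records as a weak-staining
QC exclusion. Otsu is available via `threshold.method: otsu`.

**Connectivity.** Foreground components are 8-connected and background
regions 4-connected (the complementary pair avoids topological
paradoxes — a diagonal foreground chain cannot be crossed by a diagonal
background chain). Labels are numbered in raster-scan order of each
component's first pixel so outputs are reproducible byte for byte.

**Holes and the size filter.** A hole is a 4-connected background region
not reaching the image border; it takes the label of its enclosing
particle (majority label on its rim in the pathological multi-particle
case). Holes are filled *before* the ≥ 30 px² size filter, so the filter
sees filled areas; 30 px² is just above a single cell at the intended
magnification, and the boundary is inclusive (area 30 kept, 29 discarded).
Both filling and filtering are idempotent.

**QC.** A pixel counts as tissue when `min(R, G, B) < 220` (configurable);
spots under 50% tissue are excluded, boundary inclusive. This is an
explicit numeric surrogate for what is normally a visual check, and it is
deliberately crude: it asks "is there enough non-glass material", not "is
this tumour".

## Morphometry conventions

- **Area** = pixel count, holes included (filled upstream).
- **Perimeter** = number of border pixels: particle pixels with at least
  one 4-neighbour outside the particle, the image edge counting as
  outside. A pixel only diagonally adjacent to background is not border.
  For a solid w×h rectangle this gives exactly 2(w+h) − 4. This
  border-count definition is used consistently for synthetic ground truth
  too, so recovery tests can demand exact equality.
- **Circularity** = 4πA/P², capped at 1 because small discrete particles
  exceed 1 under the raw formula (a 3×3 square scores 1.77); the cap can
  be disabled for diagnostics. Under the border-count perimeter the
  uncapped value of rasterized discs approaches its large-radius limit
  (~1.26) from above, so capped discs score exactly 1 at every radius.
- **Roundness** (default `feret_ratio`) = max Feret diameter over min
  Feret width, computed on pixel centres by rotating calipers on the
  convex hull; the minimum width is floored at 1 px so 1-pixel-thick lines
  get the finite value length−1, and a single pixel scores 1. Values are
  ≥ 1, larger = more elongated. An ImageJ-style alternative,
  4A/(π·major²) in (0, 1], is selectable (`convention="imagej"`); note the
  two orientations are reciprocal, so effect directions flip between them.

Spot-level features are N and the five aggregates; means are NaN (never 0)
when N = 0 and the spot is flagged rather than dropped.

## Association analysis

Size-like features (areas, perimeters) are log-transformed; counts and
shape indices are not. Standardization to unit SD happens on the analysis
subset *after* subgroup filtering and complete-case exclusion, so "per SD"
always means the SD of the data actually modelled; the per-SD effect
equals the per-unit effect raised to the SD (an exact identity, tested).
Tertiles cut at the 1/3 and 2/3 linear-interpolation quantiles and enter
as codes 0/1/2.

Logistic models (nodal status) use all patients; Cox models (BCSS, TTDM)
use chemotherapy-naive patients only, with Breslow tie handling and Wald
CIs/p-values. Adjustment is age (years), grade (numeric 1–3) and tumour
size (cm); a covariate constant within a subgroup (grade inside grade
subgroups) is dropped from that fit and the result records the adjustment
actually used. Deaths from other causes censor BCSS — competing risks are
deliberately not modelled, matching a cause-specific definition. Grid
cells that cannot be estimated (n below the configurable floor of 30, no
events, zero-variance feature, separation) appear in the output with a
status string; nothing is silently omitted. No multiple-testing
correction is applied.

The default subgroup grid is: all; four ER/HER2 combinations; three
grades; and the twelve ER/HER2 × grade crossings. Multiple spots per
patient are combined by per-patient means before modelling (configurable
to spot-level rows), since nothing in the data dictates a different
pooling rule.

## Synthetic data: what it emulates and what it does not

**Spots.** Ellipses with uniformly sampled semi-axes (default 3–12 px) and
orientation, placed by rejection sampling wholly inside a circular tissue
disc with pairwise Chebyshev separation > 3 px — enough to guarantee nests
never 8-connect, so the drawn geometry is the segmentation ground truth.
Optional central lumina (scaled concentric ellipses kept strictly
interior) exercise hole filling. The stain model is flat colour plus
Gaussian noise (default SD 3, foreground blue ≈ 55, background blue
≈ 235): with any realistic noise level the classes are many SDs apart, so
thresholding is exact and recovery tests can assert exact equality of
counts, areas and perimeters. Real histology has texture, stain gradients,
touching nests, DCIS and normal ducts — none of which is modelled, so
passing recovery tests demonstrate correctness of the chain, not
performance on real slides.

**Cohorts.** Features are log-normal with an exchangeable correlation
(ρ = 0.3) on the log scale; effects (per-SD log-OR/log-HR) act on the
population-standardized log features, so the planted per-SD effect is the
exact estimand of the fits. Covariates: age ~ N(53.5, 9²) years, grade
multinomial (0.20/0.45/0.35), size log-normal around 2 cm; nodal status
from a logistic model (default covariate effects of roughly OR 1.3 per
grade unit and OR 2 per cm, in line with published adjusted estimates for
these covariates); BCSS and TTDM from Weibull proportional-hazards models
(shape 1.3; scales 180 and 150 months) with administrative censoring at
240 months plus uniform dropout; chemotherapy assigned by grade
(10/25/50%). `effect_subgroup` confines feature effects to one subgroup to
exercise the subgroup grid.

`make_paper_like_cohort` is a demo cohort of n = 696 whose marginals match
published-style descriptives: ER/HER2 mix 72/9/8/11% assigned as exact
largest-remainder counts (a deterministic design choice — at n = 696 a
multinomial draw would miss 3% bands too often for a convenience
generator), mean size 20.3 mm via the log-normal mean identity, and a node
intercept calibrated by bisection so the expected prevalence is 43%. It is
explicitly not a reconstruction of any real patient series.

## Problem sizes and numerical choices

The test suite and acceptance script use: 200 random 64×64 masks for
oracle equivalence; 50 random histograms for threshold checks; 100
rendered 512×512 spots (5–50 nests, noise SD 3–5) for geometry recovery;
1000 replicates of n = 2000 for null calibration and 200 replicates of
n = 5000 for effect recovery (planted OR 1.4, HR 1.25). These sizes give
simulation SEs well below the asserted bands (e.g. ±0.7% on a 5% rejection
rate) while keeping a full run in the minutes range on one CPU.

Other numerics: survival times are floored at 10⁻³ months to keep the
partial likelihood defined; logistic fits are flagged non-converged when
Newton fails, separation is detected, or the Wald SE exceeds 50 on the log
scale (a CI spanning >40 orders of magnitude is not a result); rejection
sampling for nest placement errors out after 500 attempts per nest rather
than looping forever.

## Known limitations

- No colour deconvolution or stain normalisation; heavily counterstained
  or faded slides will shift the threshold.
- Touching nests merge into one particle by construction; the synthetic
  generator avoids this, real tissue does not.
- Pathologist-level exclusions (normal ducts, DCIS) are out of scope and
  must happen upstream.
- The roundness printed by default is the diameter-ratio convention; when
  comparing against tools reporting ImageJ-style roundness, use the
  `imagej` convention or invert the interpretation.
- Competing risks and multi-feature prognostic indices are out of scope.
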