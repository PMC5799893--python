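# nestmorph

Tumour-nest morphometry and prognostic association analysis for
cytokeratin-stained breast-cancer tissue-microarray (TMA) spots.

Invasive breast carcinomas grow as "nests" — connected clusters of tumour
cells — and the geometry of those nests (how many, how large, how ragged
their outline) carries prognostic information beyond grade and size.
`nestmorph` quantifies that microarchitecture from per-spot RGB images and
relates it to nodal status and survival, for pathologists and biostatisticians
who want an auditable, scriptable version of the classic ImageJ
particle-analysis workflow.

## What it computes

**Segmentation.** Each spot image is split into RGB channels and only the
blue channel kept (DAB-brown tumour is dark in blue, the pale haematoxylin
counterstain is not). An automatic histogram threshold *t* (iterated
intermeans / isodata by default, Otsu optional) binarizes the channel with
foreground = intensity ≤ *t*. Maximal 8-connected foreground components are
the candidate nests; internal holes (lumina) are filled and assigned to
their enclosing particle, and particles with filled area < 30 px² are
discarded as sub-cellular debris.

**Morphometry.** For each nest with area *A* (pixel count) and perimeter
*P* (count of border pixels, i.e. particle pixels with a 4-neighbour outside):

- circularity `C = min(1, 4πA / P²)` — 1 for a smooth compact outline;
- roundness = max Feret diameter / min Feret width (rotating calipers on
  the convex hull of pixel centres, min width floored at 1 px) — ≥ 1,
  larger = more elongated.

Spot-level features: nest count N, total and mean area, total and mean
perimeter, mean circularity, mean roundness.

**Association.** Each feature (log-transformed where right-skewed, then
standardized) enters a logistic regression of nodal status and Cox
proportional-hazards models of breast cancer-specific survival (BCSS) and
time to distant metastasis (TTDM), adjusted for age, grade (1–3, numeric)
and tumour size (cm); survival models are restricted to patients without
chemotherapy. Effects are odds/hazard ratios per 1 SD with Wald 95% CIs,
repeated across ER/HER2 subgroups, grade subgroups and their crossings,
plus tertile-based Kaplan–Meier summaries.

**Synthetic data.** Because every stage needs a ground truth,
`nestmorph.synthetic_data` renders spots with known nest geometry (the
truth uses the package's own area/perimeter/Feret conventions, so recovery
is exact) and simulates cohorts from explicit logistic/Weibull models with
known per-SD effects.

## Worked example

```python
import math
from nestmorph import (SpotSpec, render_spot, segment_spot, spot_features,
                       CohortSpec, WeibullModel, simulate_cohort,
                       FeatureSpec, fit_cox)

spot = render_spot(SpotSpec(seed=42, n_nests=12))
feats = spot_features(segment_spot(spot.image))
print(f"nests={feats.n_nests}  total_area={feats.total_area} px^2  "
      f"mean_area={feats.mean_area:.1f} px^2")

cohort, truth = simulate_cohort(CohortSpec(
    seed=42, n_patients=5000,
    bcss=WeibullModel(log_hr={"total_perimeter": math.log(1.25)}),
))
r = fit_cox(cohort, FeatureSpec("total_perimeter", transform="log"), "bcss")
print(f"HR per SD log(total perimeter) = {r.effect:.2f} "
      f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f}, n={r.n_used})")
```

prints

```
nests=12  total_area=2641 px^2  mean_area=220.1 px^2
HR per SD log(total perimeter) = 1.28 (95% CI 1.22-1.34, n=3473)
```

The 12 rendered nests are recovered exactly (count, areas, perimeters),
and the Cox fit on 5000 simulated patients recovers the planted hazard
ratio of 1.25 per SD within its confidence interval — the CI covers the
truth, and the point estimate 1.28 reflects one simulation draw.

A command-line interface wraps the same pipeline:

```
nestmorph simulate --seed 1 --n-spots 5 --out spots/
nestmorph extract spots/ --out run/
nestmorph analyze --features run/features.csv --patients patients.csv --out results/
nestmorph demo --seed 1 --out demo/       # full synthetic end-to-end
```

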