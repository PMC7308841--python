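# phenocloud

Morphometric trait extraction and evaluation for 3D plant point clouds —
the processing back end of a low-cost turntable photogrammetry
(structure-from-motion) phenotyping rig, plus a synthetic canopy generator
that makes every stage testable at desk scale with exact ground truth.

**Who it is for.** Plant scientists and phenotyping engineers who already
have organ-segmented, gravity-aligned, metrically scaled point clouds of
single potted plants (from any multi-view reconstruction pipeline) and
want reproducible, scriptable trait measurements and goodness-of-fit
scoring against manual reference measurements.

## What it computes

From a cloud partitioned into principal stem, petioles/branches and single
leaves:

| Trait | Definition | Unit |
|---|---|---|
| PH | straight-line distance from the lowest cloud point *p1* to the highest stem point *p3* | cm |
| BH | straight-line distance from *p1* to the lowest point of each petiole/branch | cm |
| BD, HD, AD | stem diameter at the basal, mid and apical positions: `min(range_x, range_y)` of stem points in a horizontal ring (slab) around *p1*, the mid-stem point *p2*, and *p3* | mm |
| BI | zenith angle of a petiole/branch principal axis, oriented stem → tip | deg |
| LI | angle between a leaf's total-least-squares plane normal and the zenith, folded into [0, 90] | deg |
| LA | area of the 2-D convex hull of the leaf's points projected onto their fitted plane (interior voids included) | cm² |

Predicted vs. observed trait series are scored with R² (`1 − SS_res/SS_tot`,
with the raw-ratio convention also available), relative RMSE
(`RMSE / mean(O) × 100`, banded excellent ≤ 10% < good ≤ 20% < fair ≤ 30% <
poor), AIC under a Gaussian residual likelihood (`n ln(2π·SS/n) + n + 2k`),
and a completeness weighting `Sw = S·(1 − mv/n)` that penalizes statistics
computed on reconstructions with missing organs.

Upstream helpers cover marker-based metric rescaling, chroma-key background
masking of turntable images, and k-NN statistical outlier removal. The
synthetic module generates three canopy archetypes (erect monocot,
petiolate herb, woody evergreen) with per-point organ labels and analytic
or high-density-oracle ground truth, and degrades them along two
acquisition axes — image *quality* (sampling density + geometric noise:
presets H/M/L) and image *quantity* (number of camera azimuths: presets
90/45/30, via view-coverage culling).

## Worked example

```python
from phenocloud import (default_spec, generate_plant, degradation_for,
                        degrade, extract_traits, evaluate_series)

plant, truth = generate_plant(default_spec("tomato_like", seed=7))
noisy = degrade(plant, degradation_for("L", 30, seed=7))
rec = extract_traits(noisy)

print(f"PH  {rec.ph:.1f} cm   (truth {truth.record.ph:.1f} cm)")
print(f"BD  {rec.bd:.1f} mm   (truth {truth.record.bd:.1f} mm)")
stats = evaluate_series(truth.record.la, rec.la, trait="LA")
print(f"LA  rRMSE {stats.rrmse:.2f}%  band {stats.band}")
```

prints

```
PH  39.5 cm   (truth 39.1 cm)
BD  11.8 mm   (truth 8.6 mm)
LA  rRMSE 10.36%  band good
```

Plant height survives even the worst acquisition preset almost unchanged;
the basal diameter — a coordinate-range estimate over a thin slab of noisy
points — is inflated by millimetres, and leaf areas drift by around ten
percent. That ordering (heights easiest, diameters hardest) is the
robust qualitative outcome of the degradation experiments; run
`phenocloud grid --archetype tomato_like --reps 5 --seed 1 --out surface.csv`
for the full quantity × quality response table.

The same pipeline is available from the shell:

```bash
phenocloud simulate --archetype tomato_like --seed 7 \
    --out-cloud plant.ply --out-labels labels.json --out-truth truth.csv
phenocloud extract --cloud plant.ply --labels labels.json --out traits.csv
phenocloud evaluate --observed truth.csv --predicted traits.csv --out stats.csv
```

Every command writes a `*.meta.json` sidecar with its parameters and seed;
identical invocations produce byte-identical outputs.

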