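# choromap

High-density spatial mapping of choroidal structure and vascularity from OCT
macular cube scans.

The choroid — the vascular layer between the retinal pigment epithelium (RPE)
and the sclera — remodels in early and intermediate age-related macular
degeneration, but coarse whole-scan or sector averages blur the spatially
selective pattern of that remodeling. `choromap` quantifies, for every B-scan
of a macular cube, the choroid band between the RPE and the choroidoscleral
junction, separates hypo-reflective vessel lumen from hyper-reflective stroma,
and maps four metrics onto a fovea-centred 60 × 60 grid of 120 µm cells
covering 7200 × 7200 µm:

* **CT** — choroidal thickness, `(csj − rpe) · axial_resolution` (µm);
* **LA / SA** — luminal and stromal cross-sectional area per cell (µm²);
* **CVI** — choroidal vascularity index, `CVI = LA / (LA + SA)`.

Group differences (e.g. intermediate AMD vs controls) are expressed per cell
as a **symmetric percent change** of the group medians,

```
Δ% = 100 · (x_iAMD − x_control) / ((x_iAMD + x_control) / 2),
```

which is antisymmetric under group swap and bounded in (−200, 200), and are
then analysed with an ETDRS sector template (1/3/6-mm rings plus a
near-periphery ring, quadrants at the 45° diagonals) and with 0.05-mm
eccentricity bins, where the per-bin medians `y(r)` are fitted by linear and
quadratic least squares, `y = m·r + k` or `y = a·r² + b·r + c`, the model with
the materially better R² being reported together with its geometric features
(sign-change eccentricity, vertex location, extremal value).

Because patient volumes cannot ship with the code, the package includes a
synthetic macular-cube generator that emulates the acquisition protocol
(61 B-scans, 8.6 mm scan length, 1.8 mm depth, 3.9 µm axial resolution) with
per-pixel ground truth — bimodal lumen/stroma texture with a controlled lumen
fraction, retinal-vessel shadow bands, additive noise — and a grid-level
cohort generator that embeds known eccentricity effect profiles. Every stage
of the pipeline is tested against this ground truth.

## Worked example

```python
import numpy as np
from choromap import analysis, quant, synthetic

# one noiseless synthetic cube with 65% lumen fraction, quantified end to end
scene = synthetic.SceneParams(lumen_fraction=0.65, noise_sd=0.0,
                              n_shadow_columns=0, seed=7)
volume, truth = synthetic.generate_volume(scene)
grid = quant.quantify_volume(volume)
print(f"valid cells: {grid.valid_mask.sum()} / {grid.cvi.size}")
print(f"median cell CVI: {np.nanmedian(grid.cvi[grid.valid_mask]):.3f}")
print(f"median cell CT:  {np.nanmedian(grid.ct_um[grid.valid_mask]):.1f} um")

# a 40-vs-40 eye cohort with an embedded quadratic CVI effect, recovered
spec = synthetic.CohortSpec(
    n_per_group=40, between_eye_sd=3.0, cell_sd_pct=2.0, seed=1,
    effect_profile={"CVI": synthetic.quadratic_profile(4.0, -20.0, 16.0)})
iamd, control, _ = synthetic.generate_cohort(spec)
dmap = analysis.difference_map(iamd, control, "CVI")
fit = analysis.fit_eccentricity_model(dmap)
a, b, c, r2 = fit.quadratic
print(f"chosen model: {fit.chosen}")
print(f"y = {a:.2f}x^2 {b:+.2f}x {c:+.2f}   (R^2 = {r2:.3f})")
print("features:", analysis.model_features(fit).report())
```

prints

```
valid cells: 3600 / 3600
median cell CVI: 0.649
median cell CT:  300.0 um
chosen model: quadratic
y = 4.03x^2 -20.08x +15.01   (R^2 = 0.999)
features: {'crossover_mm': (0.9,), 'vertex_mm': 2.5, 'extremal_value_pct': -10.0}
```

The quantified CVI recovers the requested lumen fraction (0.649 vs 0.65) on
all 3600 grid cells, and the embedded quadratic group effect (4, −20, 16) is
recovered by the full difference-map → eccentricity-regression path; the
reported features say the fitted difference curve changes sign at 0.9 mm and
reaches its extremum of −10% at 2.5 mm eccentricity.

A command-line interface mirrors the library:
`choromap simulate | qc | quantify | analyze | report` (see `choromap --help`).

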