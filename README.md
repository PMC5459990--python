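# firesavanna

Tools for studying why tropical tree cover looks bimodal — dense forest and
open savanna occurring under apparently identical climates — and how much of
that pattern is explained by spatial heterogeneity and human edge effects
rather than by large-scale bistability and hysteresis.

The package is aimed at spatial ecologists and modellers. It provides, as a
single tested pipeline that runs entirely on synthetic landscapes:

* a **synthetic landscape generator** (rainfall gradient with correlated
  noise, opposing seasonality gradient, topsoil texture/density fields, an
  agricultural mask biased toward drier cells, distance-to-agriculture, and
  the three-class human-impact map with a 3 km transition zone);
* the **climatic–edaphic forest suitability** statistic (CEFS): a ridge
  logistic regression of forest occurrence whose fitted log-odds

  θ₀ + θ₁·sand + θ₂·clay + θ₃·ρ + θ₄·clay·ρ + θ₅·M + θ₆·P

  measures distance from the forest/non-forest decision boundary (CEFS = 0 ⇔
  50% forest probability). A reference Amazon-basin coefficient set ships
  with the package;
* a **stochastic lattice fire–vegetation model** with five cover fractions
  per cell (forest tree F, savanna tree T, sapling S, grass G, bare soil B)
  on the unit simplex, a competitive colonisation hierarchy, Bernoulli fire
  driven sigmoidally by the fire-prone cover C = G + S, nearest-neighbour
  fire spread D∇²f, distance-decaying logging, and Euler–Maruyama stepping;
* the **Maxwell-point machinery**: (δ, P) phase diagrams, per-column Maxwell
  point location, the exponential curve P_MP(δ) = P∞ + A·exp(−δ/ℓ), the
  treeless boundary of the local model, and prediction of the whole state
  map from P, M, δ and soil suitability alone;
* **analysis procedures**: CEFS-stratified sampling, 2-D binned median
  tree-cover change, forest/savanna overlap ranges per impact class, fire
  frequency versus tree cover, and a Monte-Carlo site-percolation estimator
  behind the 40% forest/savanna cut.

The mechanism the pipeline reproduces: with spatial interaction there is no
wide hysteresis loop — a sharp forest–savanna front sits at the Maxwell
point, which climate, soils and distance to agriculture shift predictably.
Tree-cover bimodality away from that front is concentrated in the ≤ 3 km
transition zone around agriculture and requires *both* logging and fire
spread; either mechanism alone fails to produce it.

## Worked example

```python
import numpy as np
from firesavanna import (ModelParams, run_pipeline, estimate_percolation_threshold,
                         tree_cover_fire_threshold, run_phase_grid, locate_maxwell,
                         fit_maxwell_curve, treeless_boundary)

res = run_pipeline(seed=1)                       # 96 x 96 km synthetic landscape
tc = res.tree_cover()
print(f"mean tree cover after 500 yr: {tc.mean():.1f}%")
print(f"forest / savanna / treeless cells: "
      f"{(tc > 40).mean():.2f} / {((tc >= 5) & (tc <= 40)).mean():.2f} / {(tc < 5).mean():.2f}")
print("CEFS overlap of forest and savanna states per impact class:")
for cls in ("natural", "transition"):
    print(f"  {cls:10s} {res.overlaps[cls]}")

params = ModelParams()
diagram = run_phase_grid(params, delta_values=[0.5, 1.0, 1.5, 2.0, 3.0, 5.0],
                         P_values=np.arange(1000., 2251., 50.),
                         lattice_n=24, seed=3)
curve = fit_maxwell_curve(locate_maxwell(diagram))
print(f"Maxwell curve: P_MP(delta) = {curve.P_inf:.0f} "
      f"+ {curve.A:.0f} * exp(-delta/{curve.ell:.2f} km)")
print(f"treeless boundary: {treeless_boundary(params, (300., 1500.)):.0f} mm/yr")

est = estimate_percolation_threshold(256, 200, np.random.default_rng(1))
print(f"site-percolation threshold: {est.density:.4f} +/- {est.se:.4f}"
      f"  -> tree-cover fire cut {tree_cover_fire_threshold(est.density)}%")
```

prints

```
mean tree cover after 500 yr: 47.7%
forest / savanna / treeless cells: 0.58 / 0.19 / 0.23
CEFS overlap of forest and savanna states per impact class:
  natural    (-0.25, 0.5)
  transition (0.25, 1.25)
Maxwell curve: P_MP(delta) = 1672 + 3436 * exp(-delta/0.45 km)
treeless boundary: 880 mm/yr
site-percolation threshold: 0.5933 +/- 0.0003  -> tree-cover fire cut 41%
```

Reading this: after 300 years of natural dynamics plus 200 years of human
impact, forest and savanna coexist only in a narrow CEFS band around the
decision boundary in areas far from agriculture (a sharp front near
CEFS = 0), while within 3 km of agriculture the coexistence band is wider
and shifted into climates that would naturally hold forest. The Maxwell
curve says a cell 1 km from agriculture needs roughly 370 mm/yr more
effective rainfall to keep forest than a cell far away; its large-δ
asymptote (~1670 mm/yr) is the natural forest–savanna boundary, and below
~880 mm/yr even savanna trees drop out. The percolation threshold of the
grass layer (59% of cells) motivates classifying cells with more than
100 − 59 = 41 ≈ 40% tree cover as fire-immune forest.

A thin CLI mirrors the main steps:

```sh
firesavanna generate --seed 1 --out fields.nc
firesavanna simulate --fields fields.nc --seed 1 --out run.nc
firesavanna phase-diagram --lattice 24 --seed 3 --out phase.nc
firesavanna percolation --n 256 --reps 200 --seed 1
```

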