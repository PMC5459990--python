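# Methods

This note documents the models implemented in `firesavanna`, the reasoning
behind parameter defaults, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## 1. Suitability model (CEFS)

Forest occurrence is modelled as Bernoulli with logistic probability
F(y) = [1 + exp(−θ·y)]⁻¹ over the predictor vector
y = (1, sand, clay, ρ, clay·ρ, M, P) with units % / % / g cm⁻³ / — / mm yr⁻¹.
The log-odds θ·y is the climatic–edaphic forest suitability (CEFS); its zero
level is the decision boundary (50% probability), and forest is predicted
strictly beyond it (log-odds exactly 0 classifies as non-forest).

The packaged reference coefficients are

| i | term          | θ (raw)   | θ (standardized) |
|---|---------------|-----------|------------------|
| 0 | intercept     | 4.16      | 1.80             |
| 1 | sand          | 2.38e−2   | 0.608            |
| 2 | clay          | −1.88e−1  | 1.10             |
| 3 | density       | −5.99     | −9.09e−2         |
| 4 | clay·density  | 1.83e−1   | 0.479            |
| 5 | MSI           | −7.05     | −1.09            |
| 6 | MAR           | 2.90e−3   | 2.29             |

The raw-to-standardized ratios fix the predictor units: sand raw 2.38e−2 vs
0.608 standardized implies a predictor SD of ≈ 25.5, consistent only with a
percent scale. The standardized clay entry is positive while the raw one is
negative; since z-scoring cannot flip a sign, the standardized column is
shipped as published but all quantitative tests compare against standardized
values recomputed from the raw θ and the simulated predictor SDs.

**Soil suitability** π is the soil block of the linear predictor,
θ₁·sand + θ₂·clay + θ₃·ρ + θ₄·clay·ρ − π_c. The centring constant π_c
defaults to the soil block evaluated at the landscape's median soils, so
π = 0 means "typical soil". (The functional form is a package reconstruction
of a formula available only descriptively.)

**Fitting.** `RidgeLogistic` maximises the L2-penalised Bernoulli
log-likelihood (scikit-learn LBFGS behind the class surface). The penalty is
per sample, so duplicating every observation leaves the fit unchanged; ridge
is applied on the standardized scale with an unpenalised intercept, and raw
coefficients are recovered by rescaling. The default penalty is chosen by
5-fold cross-validated deviance. The interaction is standardized as its own
derived column, so a separate standardized θ₄ can be reported.
Individual soil coefficients are weakly identified (clay, density and
clay·density are nearly collinear), which is why consistency is assessed on
the fitted linear predictor, not coefficient-by-coefficient.

**Agreement.** Cohen's κ with marginal-product expected agreement; when both
maps are constant and identical (p_e = 1) κ = 1 by convention. The
implementation is independent of scikit-learn's and cross-checked against it
in the tests.

## 2. Climatological indices

MAR is the mean over years of the annual sums of a monthly climatology
(mm/yr). MSI is Markham's resultant-vector seasonality index: each calendar
month m contributes a vector of magnitude p̄_m (multi-year mean monthly
rainfall) and phase mπ/6; MSI is the resultant magnitude divided by Σp̄_m.
It is 0 for uniform rainfall, 1 when all rain falls in one month, and
invariant under cyclic rotation of months (the absolute phase convention is
irrelevant to the magnitude — property-tested). MSI is undefined (raises)
when MAR = 0.

## 3. Synthetic landscape generator

The generator emulates the statistical structure of a subcontinental
moist-tropics study region on a km-scale grid (default 96 × 96 km):

* rainfall: linear gradient 800 → 2600 mm/yr across the grid plus a
  spatially correlated Gaussian field (SD 150 mm, correlation length 5 km);
* seasonality: opposing gradient 0.65 → 0.10 (the dry side is the seasonal
  side) plus correlated noise, clipped to [0, 1];
* topsoil sand/clay/bulk density: independent correlated fields around
  40% / 30% / 1.3 g cm⁻³, clipped to physical ranges;
* agriculture: the top `agri_fraction` (default 7%) of a score
  `dryness_bias·(−z(P)) + noise` — drier cells are favoured (bias 1.0), but
  the noise term places some agriculture in wet areas, as observed in real
  land-use patterns;
* δ: Euclidean distance transform of the mask (scipy EDT, km). "No
  agriculture anywhere" is encoded as the documented sentinel `inf`, never 0;
* impact classes: agricultural cells; transition within 3 km of them
  (inclusive, reading "not further than 3 km" literally); natural beyond.

Correlated fields are Gaussian-kernel-smoothed white noise with kernel width
L/2, giving autocorrelation e⁻¹ at lag L (tested empirically). Same seed ⇒
bit-identical output.

What the generator does **not** emulate: cloud/QA artefacts, wetlands and
altitude exclusions, anisotropic orographic rainfall, spatially structured
soil–climate correlations, or the CART-induced discontinuities of satellite
tree-cover products. Passing tests therefore demonstrate internal
consistency of the mechanism, not agreement with any real raster.

## 4. Lattice fire–vegetation model

Per cell, five cover fractions (F, T, S, G, B) on the unit simplex evolve by

    dF = g_F·F·(S+T+G) − m_F·F − b·f·F − r_F·F
    dT = q·S − m_T·T − g_F·F·T − r_TS·T,      q = q0·(1 − d·f)
    dS = g_T·T·G − q·S − m_S·S − g_F·F·S − r_TS·S
    dB = m_GB·G − g_G·G·B
    dG = −(dF + dT + dS + dB)

with grass the default (slack) type. The equation set is a reconstruction
from the stated colonisation hierarchy (F colonises S, T, G; S colonises G;
G colonises B), conversion rules (non-competitive tree mortality returns
space to grass), fire effects (burns remove a fraction b of forest and cut
recruitment by d) and exact conservation; it reduces to the familiar
savanna–forest demographic architecture of nonspatial fire-feedback models.

**Fire.** Each year each cell draws f_local ~ Bernoulli(p) with
p = (1/I)·[1 + exp(−k_f·(C − C_c))]⁻¹, C = G + S the fire-prone cover.
Spread adds D times the nearest-neighbour differences
(f_eff = f + D·Σ(f_j − f_i), clipped to [0, 1]; 4D ≤ 1 enforced). The
critical cover C_c = clip(0.59 + s_C·(P_eff − 1700), 0.4, 0.8) falls with
dryness — the percolation-threshold motivation for C₀ = 0.59 at reference
climate, with effective fuel connectivity increasing as the climate dries.
Fire acts within the same step on forest removal and recruitment. In the
*deterministic local model* (used for attractor analysis, the treeless
boundary and front initialisation) the Bernoulli draw is replaced by its
expectation p.

**Climate aggregation.** Seasonality and soils enter as rainfall
equivalents through the CEFS coefficient ratios:
P_eff = P + (θ₅/θ₆)·(M − M_ref) + π/θ₆ (a reconstruction; the identity
P_eff = P holds at M = M_ref, π = 0). All growth/mortality rates are
functions of P_eff: saturating growth g_i = g_max,i·P/(P + h_i) and
drought-threshold mortality m_i = m0_i + md_i·[1 + exp(k_m·(P − P_crit,i))]⁻¹,
with savanna trees the more drought-resistant type (h_T < h_F,
P_crit,T < P_crit,F, and the savanna mortality increment never exceeding the
forest one at any P_eff). The grass→bare rate m_GB rises continuously with
dryness (no grass–bare bistability), strongly enough that desert cells
become bare-dominated and non-flammable.

**Humans.** During the impact window (t ∈ [300, 500] by default) managed
(agricultural) cells remove trees and saplings at r0; elsewhere edge logging
removes forest only, at r0·exp(−δ/λ_r).

**Noise and stepping.** Euler–Maruyama with Δt = 1 yr. Gaussian noise
σ√Δt·ξ is added to F, T, S, B, each scaled by the relative availability of
space that type can colonise (S+T+G for F; S for T; G for S and B), with G
absorbing the complement; negatives are clipped and the cell renormalised,
so Σ covers = 1 to machine precision at every step (tested to < 1e−9 over
500 noisy steps). With the defaults the worst-case simultaneous outflow
(burn + clearcut) can exceed 1·Δt; this is flagged by a warning and handled
by the projection. Grid is row-major with a 4-neighbour stencil; no-flux
boundaries by default (missing neighbours contribute zero difference),
periodic available and used for phase diagrams. Initial cover is
Dirichlet(1,…,1) over all five types, or over (F, T, S, B) with G = 0 for
the phase-diagram protocol.

### Parameter defaults and calibration

The demographic and fire constants are not published values; they were
calibrated once, via the local-model and front analyses below, to satisfy
the study conditions, and then frozen:

| parameter | default | role / rationale |
|---|---|---|
| g_max_F, h_F | 0.35 yr⁻¹, 900 mm | forest growth; equilibrium F* = 1 − m_F/g_F ≈ 0.75–0.80 in wet climates |
| g_max_T, h_T | 0.45 yr⁻¹, 500 mm | savanna-tree growth holds up at lower rainfall than forest |
| g_max_G, h_G | 0.50 yr⁻¹, 600 mm | grass recolonisation of bare soil |
| m0_F, md_F, P_crit_F | 0.05, 0.40, 900 mm | forest mortality rises steeply below ~900 mm |
| m0_T, md_T, P_crit_T | 0.15, 0.40, 400 mm | savanna trees persist to ~880 mm (treeless boundary) |
| m_S, k_m | 0.05 yr⁻¹, 0.01 mm⁻¹ | sapling mortality; mortality-threshold steepness |
| m_B0, P_crit_B, k_B | 0.30 yr⁻¹, 700 mm, 0.01 mm⁻¹ | bare soil dominates deserts, making them non-flammable |
| q0, d | 0.10 yr⁻¹, 0.9 | recruitment, and its suppression in burnt cells — keeps savanna tree cover in the 5–40% band |
| I, k_f, C0, s_C | 5 yr, 20, 0.59, 1e−4 mm⁻¹ | fire ceiling 1/I; steep sigmoid at the percolation-motivated critical cover |
| b | 0.9 | forest removal per burn; large enough that fire blocks forest invasion of burning savanna (the basis of bistability) |
| D | 0.1 | fire-spread strength (4D ≤ 1) |
| r0, λ_r | 0.3 yr⁻¹, 0.4 km | clearcut rate and edge-logging decay; logging alone clears only a sub-km fringe, so degradation of the full 3 km transition band requires fire spread — the "either mechanism alone fails" property |
| σ | 0.04 | demographic noise; below ~0.02 discrete-lattice fronts pin and no Maxwell point is observable, 0.04 de-pins them while leaving both states metastable |
| M_ref | 0.5 | chosen so CEFS = 0 corresponds to P_eff ≈ 1620 mm — the natural Maxwell point of this parameter set — i.e. the simulated front sits at the suitability decision boundary |

With these defaults the deterministic local model is bistable for P_eff
roughly between 1150 and 1750 mm/yr (forest-heavy and grass-heavy starts
reach attractors ~75–79% vs ~10% tree cover), overlapping the observed
1400–1900 mm bimodality range; the savanna attractor's fire-prone cover sits
near 0.9 so fires recur at close to the 1/I ceiling.

## 5. Maxwell point and phase diagram

For each (δ, P) combination a homogeneous lattice (periodic boundaries,
random initial cover over F, T, S, B) runs 300 natural steps, then 200 with
humans on, storing the fraction of cells with tree cover > 40% at t = 300
and t = 500. All combinations are advanced together as one batched array.
The Maxwell point per δ column is where the late-minus-early difference
crosses zero while the final fraction is neither ~0 nor ~1 (linear
interpolation between P rows; per-column interpolation rather than a 2-D
contour, for testability). Because convergence near the MP is slow, the
fallback tolerance on |diff| scales with lattice size (2/n + 0.01).

The located points are summarised by P_MP(δ) = P∞ + A·exp(−δ/ℓ), fitted by
least squares; the exponential form matches the exponential logging decay
that generates the shift. The operational meaning of the MP is verified
directly: a half-forest/half-savanna lattice front retreats for P below the
located MP and advances above it, with speed increasing monotonically with
|P − P_MP| (tested over six rainfall values around the MP).

The treeless boundary is the largest P_eff at which the local model's
steady-state savanna tree cover is zero (bisection with Brent's method on
the deterministic local model; T* threshold 1e−3, P tolerance 2 mm); it must
and does lie dry-ward of P∞.

`predict_state_map` classifies each cell from P, M, δ and π alone: treeless
below the treeless boundary, forest above P_MP(δ), savanna between,
agricultural cells overriding. Against the full stochastic simulation on the
default synthetic landscape this reaches κ > 0.9 (forest vs non-forest,
non-agricultural cells); the acceptance bar is κ ≥ 0.8. Mismatches
concentrate near the front, where fronts are slow and noise decides.

## 6. Bimodality and fire analyses

Sampling follows the CEFS-stratified protocol: up to 100 draws without
replacement from each of 50 consecutive CEFS intervals between −7.5 and 5,
separately per impact class. Binned median change uses (CEFS, tree-cover)
bins of (0.25, 3%), with medians reported only for bins holding ≥ 200 cells.

"Overlap" of the forest (> 40%) and savanna (5–40%) states is
operationalised as the maximal contiguous run of CEFS bins in which each
state holds at least `min_frac` = 10% of the bin's samples — a scatterplot
coexistence criterion made explicit. The reported intervals shrink as
`min_frac` grows (a stricter presence requirement); 10% is low enough to
register a genuine minority state in a 100-sample bin while ignoring
single-cell noise. On the seeded default run the natural-class interval
straddles CEFS = 0 and is strictly narrower than the transition-class one;
removing logging (r0 = 0) or fire spread (D = 0) collapses the
transition-class excess — with D = 0 at the cost of frozen salt-and-pepper
bimodality from unresolved initial conditions, exactly the artefact that
ignoring spatial interaction produces.

Fire frequency per 3% tree-cover bin counts cell-years with f_eff above 0.5
(f_local is binary; spread adds fractional amounts, so 0.5 separates "this
cell burnt" from "a neighbour burnt" — configurable). The resulting curve
has an interior maximum inside the 5–40% band: deserts lack fuel, closed
canopies suppress it.

The site-percolation estimator generates random occupancy lattices
(4-neighbour connectivity, open boundaries), tests top-to-bottom spanning by
connected-component labelling, and locates the density with spanning
probability 0.5 by a short bisection followed by a logistic-curve fit of
spanning probability over a local density sweep (the curve fit is needed
because the finite-size transition width, ~n^(−3/4) ≈ 0.015 at n = 256, is
wider than the sub-percent precision required; the SE comes from the fit
covariance). At n = 256 with 200 replicates per density it reproduces the
known threshold 0.5927 to the nearest percent (59%), hence the
100 − 59 = 41 ≈ 40% tree-cover fire cut.

## 7. Problem sizes

The shipped analyses use desk-scale sizes chosen to keep the full suite
fast while leaving every qualitative result stable: 96² landscapes for
end-to-end runs, 64² for conservation, 24² lattices with a 8 × 26 (δ, P)
grid for phase diagrams, 24 × 64 strips for front speeds (3 seeds), and
256² lattices for percolation. Larger sizes (the 100 × 100 lattice /
100 × 100 parameter grid protocol) are reachable through the same function
arguments.

## 8. Known limitations

* All constants beyond the published regression coefficients are
  calibrated, not measured; only the qualitative regime structure
  (bistability window, hump, front reversal, edge-effect widening) should
  be read as results.
* Cover types do not diffuse (only fire does), fire spread is
  nearest-neighbour only, and climate is stationary within a run —
  interannual variability, long-range fire and vegetation–climate feedbacks
  are out of scope.
* The discrete-lattice front pins at low noise; Maxwell-point location
  therefore depends mildly on σ, and the stochastic-protocol MP
  (~1670 mm/yr) sits slightly above the front-reversal estimate.
* The overlap statistic is bin- and threshold-granular (0.25 CEFS bins, 10%
  presence); margins between classes are one to a few bins at desk scale.
* Real-raster quantities (κ against satellite maps, observed overlap ranges,
  the 1400–1900 mm bimodality interval itself) are not reproduced here —
  synthetic analogues with the same structure stand in for them.
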