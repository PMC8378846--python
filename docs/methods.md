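# Methods

## The measurement problem

Retinotopic maps assign every cortical vertex a preferred polar angle
(0° = upper vertical meridian, 90° = horizontal, 180° = lower vertical, per
hemisphere in the contralateral-hemifield convention) and eccentricity.
The quantity of interest is how much cortical surface area falls inside
visual-field wedges around the cardinal meridians, and the percent
asymmetries between matched wedges:

* HVA = Δ(horizontal area, vertical area),
* VMA = Δ(lower-vertical area, upper-vertical area),

with Δ(a₁, a₂) = 100·(a₁ − a₂)/mean(a₁, a₂). Δ is antisymmetric, bounded by
±200, and invariant to common rescaling, so it is comparable across subjects
with different total V1 sizes. Asymmetries are computed per subject (never on
group-mean areas) and aggregated as the median with a 68% percentile
bootstrap over subjects (16th/84th percentiles; the mean is selectable).

## Sector resampling

Raw per-vertex maps are too noisy to threshold directly into 10°-wide bins.
Instead, coarse sectors bounded by iso-angle and iso-eccentricity contours
(six per visual area per hemisphere: two angular bands × eccentricity bands
1–2°, 2–4°, 4–7°) are resampled one at a time:

1. **Relative distance.** For each axis, the geodesic distances d₁ and d₂
   from the two opposing boundary contours give r = (d₁ − d₂)/(d₁ + d₂),
   which is −1 on one boundary, +1 on the other, and varies smoothly.
   Geodesics are graph shortest paths over mesh edges with Euclidean edge
   weights (Dijkstra). Exact polyhedral geodesics would change d₁ and d₂ by
   a few percent, but only the ratio r is consumed, so the graph
   approximation is adequate and deterministic. Distances are computed on
   the subgraph induced by the sector's own vertices, so a neighbouring
   sector can never short-circuit the field.
2. **Monotone denoising.** Isotonic regression (pooled adjacent violators,
   orientation detected automatically) of the measured coordinate on r
   yields the best least-squares *monotone* relation; tied plateaus are
   spread over an epsilon ramp so the relation is strictly monotone and
   hence invertible in both directions.
3. **Binning.** Each vertex is assigned to exactly one bin by its fitted
   coordinate (half-open bins, last bin closed). Within a sector the bins
   partition the vertex set exactly, so fine-bin areas sum to the sector
   area to floating precision — a conservation law the test suite asserts
   for every sector, with and without measurement noise.

Polar angles outside [0, 180] (ipsilateral pRF centers, common near the
vertical meridians) are clamped to the nearest vertical meridian with a
logged count; they act as noise concentrated in the vertical wedges, which
is why narrow vertical-wedge estimates deserve caution on real data.

Numerical tie-break: a vertex whose fitted coordinate lands exactly on an
interior bin edge lies on the shared iso-contour; such vertices alternate
deterministically between the two adjacent bins so the shared row splits
evenly instead of inflating one side. With noisy data exact ties are
measure-zero; on synthetic noise-free meshes they occur whenever a vertex
row aligns with a bin edge, and one-sided assignment would bias narrow
wedges by several percent.

Across abutting sectors (which share their boundary contour, being closed
bands) the assembled fine grid deduplicates: the higher band claims the
shared row, keeping grid bins globally disjoint so ROI and band areas are
additive.

## Surface areas

Areas default to the mid-gray layer (white and pial selectable). Per-vertex
area is one third of each incident triangle's area — barycentric lumping,
which conserves total area exactly and makes region area a plain sum.
Degenerate faces are rejected. ROIs are unions of fine bins; the incremental
wedge at θ is the set difference cumulative(θ) \ cumulative(θ − 10°), so
incremental ROIs are pairwise disjoint and union exactly to the widest
cumulative ROI. Left and right hemisphere areas are summed per subject
before any asymmetry is formed; a bilateral ±θ wedge therefore spans 4θ of
visual-field angle, which is the convention under which the magnification
model reproduces its published predicted areas.

## The magnification reference

Horton–Hoyt areal magnification, m(ρ) = (17.3 mm/(ρ + 0.75°))², integrates
in closed form over a wedge (area element ρ dρ dθ, θ in radians):

    A = W · 17.3² · [ln((e₂+e₀)/(e₁+e₀)) + e₀(1/(e₂+e₀) − 1/(e₁+e₀))].

The closed form is verified against adaptive quadrature to 1e−9 relative and
against a brute-force Riemann sum. Because m is independent of polar angle,
its prediction must fall between the measured vertical and horizontal wedge
areas on any cortex with a positive HVA — asserted on the synthetic cortex.

## Synthetic ground truth

The generator builds one flat sheet per hemisphere (V1 spanning the
hemifield, flanked by mirrored ventral/dorsal V2 strips) as the image of the
visual-field polar grid under

    U(ρ) = 17.3·ln((ρ+e₀)/(ρ_min+e₀)),   V(ρ, θ) = 17.3·ρ/(ρ+e₀) · G(θ),

where G is the integral of the angular modulation
g(θ) = 1 − h·cos 2θ − v·cos θ (θ from the upper vertical meridian, radians).
The Jacobian per unit visual-field area is exactly m(ρ)·g(θ), so every wedge
has the closed-form area A = radial_integral(e₁, e₂)·(G(θ₂) − G(θ₁)) and the
true HVA/VMA are analytic. g is the minimal smooth form with independent
HVA (h) and VMA (v) knobs; it is this package's own validation model, not an
empirical claim about cortex. |h| + |v| < 1 keeps magnification positive.

Defaults: h = 0.3, v = 0.2 (asymmetries of roughly 35–60%, the order
observed in adult V1), eccentricity range 1–7° (covering the 4–7° coarse
band), mesh_step = 0.3 mm (≈30k vertices per hemisphere), polar-angle noise
SD 10°, eccentricity noise SD 0.25°, ipsilateral-spill probability 0.1
within 10° of a vertical meridian — magnitudes typical of pRF measurement
scatter. Optional sinusoidal folding displaces the white/pial layers along
vertex normals to exercise the three-layer machinery; the default sheet is
flat so closed forms stay exact. Radial rows are placed exactly on the
coarse-band knots so the synthetic "hand-drawn" contours are true
iso-curves; measured maps add noise on top of the exact coordinates.

Twin cohorts follow the shared-latent model x_ij = μ + b_j + e_ij with
var(b)/(var(b)+var(e)) equal to the pair-class correlation, so the
population ICC is the generator parameter; metadata (gender, age group,
family) is consistent within pairs for the unrelated-pair matching. Density
profiles share one cone-like radial falloff scaled per meridian, making the
meridional asymmetries closed-form scale expressions.

**What the synthetic validation shows — and does not.** Passing tests
establish that the geometry, resampling, ROI assembly and statistics are
implemented correctly at realistic problem sizes and noise levels. The
generator's cortex is flat, its magnification exactly Horton–Hoyt, its
angular modulation smooth and global, and its noise independent across
vertices; real cortex is folded, has spatially correlated map noise,
inter-subject magnification differences, and annotation error in the
hand-drawn contours. Results on real data inherit none of the synthetic
guarantees beyond algorithmic correctness.

## Twin intraclass correlation

For a 2×n pair matrix, MSr = 2/(n−1)·Σ(pair mean − grand mean)² and
MSw = (1/n)·ΣΣ(x − pair mean)², giving r_ICC = (MSr − MSw)/(MSr + MSw): the
standard one-way ANOVA form, which is exactly 1 for concordant pairs,
bounded in [−1, 1], member-order invariant, and consistent for the
population pair correlation under bivariate normality (all tested, including
a 68% CI coverage simulation). Bootstrap CIs resample *pairs*, never
individual subjects, preserving the within-pair dependence under study.
Unrelated pairs are every same-gender, same-age-group, different-family
subject pair, validated against brute-force enumeration.

## Retinal frame handling

Density profiles carry an explicit frame field. The eye's optics invert the
image vertically, so converting retinal ↔ visual-field swaps the superior
and inferior profiles (an involution); cone-like profiles that are denser in
the inferior retina therefore show a negative retinal VMA while favouring
the upper visual field. Band values use band-mean densities (matching how
cortical band areas enter the same comparison); the difference from
averaging pointwise asymmetries is second-order.

## Known limitations and quantization

Whole-vertex bin assignment quantizes areas at the scale of one vertex row.
At the default resolution this leaves ≈0.3% error on full wedges, a few
percent on ±10° wedges, and up to ~10% on single 1°-eccentricity-band ×
10°-wedge cells (the smallest ROIs measured); the errors shrink under mesh
refinement (asserted by a two-resolution convergence test) and largely
cancel in the asymmetry ratios, which recover closed-form values to well
under one percentage point at working resolution. Fractional (sub-vertex)
area splitting would reduce the band-level error but is deliberately
avoided: per-vertex bookkeeping keeps areas additive, auditable and exactly
conserved under partition.

Problem sizes used by the validation suite: ~3k-vertex hemispheres for unit
tests, ~30k for end-to-end recovery; 2000 pairs for ICC consistency; 200
repetitions × 400 bootstrap draws for CI coverage — sizes at which the
Monte-Carlo tolerances quoted in the tests hold with comfortable margin.
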