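# Methods

This note documents the models, estimators and numerical choices behind
`otomorph`, and what the synthetic-data experiments do and do not
demonstrate about real otolith data.

## Outline extraction

An otolith image is thresholded with Otsu's method. Foreground polarity is
resolved automatically: the minority-pixel side is taken as the otolith,
falling back (for near-even splits) to whichever side's largest connected
component lies closest to the image center. The largest foreground
component is hole-filled and its boundary traced as a sub-pixel closed
polygon (marching squares at level 0.5). Coordinates are converted to
mathematical axes (y upward) and oriented counter-clockwise. A component
touching the image border produces a warning — the otolith may be clipped —
but not an error, since a reviewer may still accept the outline.

The *radial profile* samples the centroid-to-boundary distance at
`n_angles = 2^J` equally spaced angles (default 512, θ = 0 along +x,
counter-clockwise). The centroid is the polygon **area** centroid (shoelace
moments), not the vertex mean, so it is invariant to vertex density. For
concave outlines the ray at each angle may cross the boundary more than
once; the **farthest** intersection is used, so indentations (the
excisurae) appear as radius minima and the profile is single-valued, which
the dyadic wavelet transform requires. If the centroid falls outside the
polygon (pathologically concave shapes) extraction fails with a message
advising manual review. Outline smoothing is not applied.

## Wavelet shape descriptors

The radial profile is decomposed with `pywt.wavedec` in **periodization**
mode: the radius function is circular, so periodic boundary handling is
exact rather than an approximation, and with an orthogonal filter the
transform is orthonormal — output length equals input length, energy is
conserved, and Euclidean distances between coefficient vectors equal
distances between radius vectors. The default filter is the
least-asymmetric Daubechies wavelet with 10 vanishing moments (`sym10`);
nothing downstream depends on the family and it is configurable. The
default depth is `pywt.dwt_max_level` (4 levels at length 512).

Each coefficient is annotated with its decomposition level (0 = smooth
band, 1 = finest detail … L = coarsest detail) and a center angle: position
k in a band of m coefficients gets 360·(k + 0.5)/m degrees. This mapping is
what allows variance decompositions to be drawn against position on the
outline. It assigns the smooth band angles too, although smooth-band
coefficients have broad support; the ICC profile should be read with that
in mind.

Coefficients are computed on raw radii in image units. Size is handled
downstream — by the allometry filter and by age stratification — rather
than by normalizing radii, so the descriptors retain size information that
the statistics can then model explicitly.

**Mean shapes** are per-population coefficient means inverted back to
radii. Because the transform is linear this equals averaging radii
directly; working in coefficient space keeps mean shapes consistent with
any coefficient filtering.

**ICC profile.** For each coefficient the proportion of variance between
populations is the one-way random-effects intraclass correlation estimated
from ANOVA mean squares with the standard unbalanced-design coefficient
n₀ = (N − Σnᵢ²/N)/(k − 1): σ²ᵦ = (MSB − MSW)/n₀ truncated at zero,
ICC = σ²ᵦ/(σ²ᵦ + MSW), clamped to [0, 1] for display. Populations with a
single specimen are dropped with a warning. The estimator variant matters
little at survey sample sizes; the truncated ANOVA estimator was chosen
because "proportion of variance among groups" names exactly this quantity.

## Allometry (ANCOVA) filter

Otolith size scales with fish length, and the scaling can differ between
populations. For each coefficient the model
`coef ~ length + population + length:population` is compared with the
no-interaction model by an F-test on residual sums of squares. A
significant interaction (default α = 0.05) means population differences in
that coefficient cannot be separated from population-specific allometry,
and the coefficient is excluded. P-values are per-coefficient with **no
multiple-testing correction** — the screen is deliberately conservative
about what it keeps, and under a global null it removes ≈ α of the
coefficients (verified by simulation). Populations with n < 3 cannot
support their own slope and intercept and are left out of the test with a
warning.

## CAP ordination and permutation tests

Canonical Analysis of Principal coordinates on Euclidean distances:

1. **PCoA** of the inter-specimen Euclidean distance matrix, computed via
   the SVD of the column-centered coefficient matrix (exact for Euclidean
   distances, and numerically stabler than double-centering a squared
   distance matrix). All axes with eigenvalue > 1e-10 × the largest are
   retained — no discriminant-style axis selection.
2. **Covariate conditioning** (optional): the coordinate scores are
   regressed on the covariate (age) with intercept and replaced by their
   residuals; the inertia removed is the *conditional* inertia.
3. **Constraint**: the (residualized) scores are projected onto population
   indicators — equivalently, replaced by group means. The SVD of the
   fitted matrix gives the canonical axes (CAP1, CAP2, …); site scores are
   projections of the residualized scores onto these axes, and group
   centroids are their per-population means.

Because the distance is Euclidean on orthonormal coefficients, the whole
construction is equivalent to redundancy analysis on the raw (filtered)
coefficients. Inertia is accounted exactly: total = conditional +
constrained + residual (checked to 1e-9 in the tests).

**Permutation test.** The statistic is
pseudo-F = (constrained/df_c)/(residual/df_r) with df_c = k − 1 and
df_r = n − 1 − df_c − df_cond. The null distribution permutes specimen rows
of the *residualized* scores (reduced-model permutation) — the standard
choice when conditioning. Sampled p-values use the add-one convention
p = (1 + b)/(1 + m), so p is never zero and its minimum is 1/(m + 1); ties
count as extreme (F ≥ F_obs within 1e-12). An exhaustive mode enumerates
all n! orderings for n ≤ 8 and returns the exact p with no add-one
adjustment. A-priori contrasts (one population versus a pooled set, region
versus region) are expressed as a mapping from population labels to
contrast levels; unmapped populations are excluded from that test.

**Within-population variance** per (population, age-group) cell is
Σᵢ<ⱼ d²ᵢⱼ/(n(n−1)) over pairwise Euclidean distances, which is
algebraically the trace of the within-cell covariance (the tests verify the
identity against an explicit pairwise-distance oracle). Cells with n < 2
are omitted. The **dispersion–age regression** is ordinary least squares of
a dispersion measure on age with the usual t-test p-value; per-cell
variances on age-band midpoints are the default input (per-specimen
distances to the group centroid are an accepted alternative — both are
"variation", and the cell-variance route matches how sparse survey tables
are summarized).

## Geographic distances and isolation by distance

Coastal populations are separated by distance *along the coast*, so
geographic distances accumulate great-circle segment lengths (haversine,
spherical Earth R = 6371.0 km) along an ordered waypoint path; each
population is anchored to its nearest waypoint (or an explicit index), and
the distance between two populations is the absolute difference of their
cumulative arc lengths — additive by construction. A geodesic (ellipsoidal)
Earth model would change hand-traced coastline distances by far less than
the tracing error, so the spherical model is used.

Shape distances are Euclidean between population centroids on the first two
canonical axes only — population shape summarized by its position in the
two dominant discriminating dimensions.

The **Mantel test** correlates the n(n−1)/2 upper-triangle entries; the
null permutes one matrix's labels (simultaneous row/column permutation).
The default alternative is one-sided positive — the isolation-by-distance
hypothesis is directional — with a two-sided option. For n ≤ 8 populations
all n! relabelings are enumerated exactly. The IBD report regresses shape
distance on geographic distance and flags pairs whose residual exceeds two
residual standard deviations (sample SD): the pairs more or less different
than their separation predicts.

## Synthetic data generator

The generator encodes the data-generating assumptions the analysis is
designed to detect. Specimen i of population p has radii

r(θ) = r₀·[1 + Σₛ a_{p,s}·exp(−Δ(θ, cₛ)²/(2wₛ²)) + εᵢ(θ)]

* **Deformation sites** (center cₛ, width wₛ, sign): defaults are a notch
  at 10° (width 20°) and a projection at 175° (width 15°) — the sectors of
  the otolith outline (excisura major; rostrum/excisura minor) where
  between-population variation concentrates in herring.
* **Gradient**: a_{p,s} = gradient_slope · coast_km_p · signₛ, i.e. shape
  diverges linearly with along-coast position. Default slope 8e-5 per km
  over 12 populations evenly spaced on 0–1650 km gives a maximum
  deformation of ~13 % of r₀ — strong enough to recover reliably at 30
  specimens per population, weak enough that individual outlines overlap
  heavily (Mantel r lands around 0.9–1.0 at the population level).
* **Individual noise** εᵢ: a mixture of circular harmonics of orders 1–8
  with iid normal coefficients scaled so the pointwise SD is exactly
  noise_sd · max(floor, 1 + age_variance_slope·(age − 3)); default 4 % of
  r₀ at age 3, shrinking 7 % per year of age, floored at 20 % of the base
  level. Harmonic (band-limited) noise keeps every outline a smooth simple
  polygon; including order 1 makes individual centroid placement noisy, as
  it is in real images.
* **Ages** uniform on 3–12; **length** = 18 + 1.2·age + N(0, 1) cm,
  mimicking length-at-age curves of small coastal herring.

All draws flow from a single `rng_seed`; equal configurations give bitwise
identical datasets. Configurations whose deformations drive any radius
non-positive fail loudly rather than generating invalid shapes.

`rasterize` renders an outline as an anti-aliased filled polygon (white on
black) by even-odd scanline filling at `supersample`× resolution and
block-averaging down; summed intensity tracks polygon area to ~0.1 %.

**What passing the synthetic experiments shows — and does not.** The
generator produces smooth, star-shaped, noise-free-background images with a
single otolith, deformations that are exactly Gaussian in angle, and a
noiselessly linear gradient. Success demonstrates that the pipeline's
machinery (extraction fidelity, transform exactness, test calibration,
gradient recovery) is correct, *not* that real otoliths carry a comparable
signal: real images add illumination gradients, debris, broken rostra and
orientation error, and real population structure is not one-dimensional.
The type-I-error and zero-gradient experiments guard the opposite failure:
the pipeline does not invent population structure or isolation by distance
where none exists.

## Problem sizes and numerical conventions

* Default analysis scale: 12 populations × 30 specimens, 512 angles —
  chosen so end-to-end experiments are comfortably reproducible on a
  laptop; the machinery is O(n·m) per permutation and scales to survey
  sizes (thousands of otoliths) without modification.
* Permutation counts default to 2000 (ANOVA-like tests) and 10000 (Mantel);
  the attainable minimum p-values are 1/2001 and 1/10001.
* PCoA eigenvalue floor 1e-10 × largest; permutation tie tolerance 1e-12;
  DWT/IDWT round trip is exact to ~1e-14 relative error.
* Coefficient CSVs are written with `%.17g` and parsed in round-trip mode,
  so persisted matrices are bitwise reproducible.
* Ambiguities resolved as package policy: age-group bounds are inclusive
  integers (3–5, 6–8, 9–12); the Mantel default is one-sided; temporal or
  contrast tests run without an age covariate unless one is passed; the
  optional `mirror` config flag standardizes left/right sagittae without
  presuming which side a given study imaged.

## Known limitations

* No multiple-testing correction across per-coefficient ANCOVA tests or
  a-priori contrasts (deliberate, but worth remembering when many
  coefficients or contrasts are screened).
* The farthest-intersection radial profile is a lossy description of
  strongly concave outlines; shapes whose centroid leaves the polygon are
  rejected rather than repaired.
* Smooth-band wavelet coefficients have broad angular support, so the
  ICC-versus-angle curve localizes detail-band structure better than
  smooth-band structure; measured (as opposed to analytic) radii also leak
  a small amount of between-population signal into all angles through
  centroid shifts.
* The coastline path is user input; no attempt is made to reproduce any
  particular published km values, which depend on how the coast was traced.
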