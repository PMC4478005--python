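# otomorph

Outline morphometrics of fish otoliths for population discrimination.

Sagittal otoliths — the calcium-carbonate ear stones of teleost fish — grow
throughout life and their outline shape records the environment a fish grew
up in. For species with weak genetic differentiation but strong site
fidelity (coastal herring is the canonical case), otolith shape is often the
most practical population marker. `otomorph` implements the full analysis
chain from otolith images to population-level inference:

1. **Outline extraction** — threshold a grayscale image (Otsu), trace the
   largest connected component as a closed sub-pixel polygon, and sample the
   *radial profile*: centroid-to-outline distance at 2^J equally spaced
   angles (default 512).
2. **Wavelet shape descriptors** — an orthonormal discrete wavelet transform
   (periodic boundary, default `sym10`) of the radial profile. Each
   coefficient is annotated with its decomposition level and the center
   angle of its support, so variance decompositions can be drawn *along the
   outline*. The intraclass correlation ICC = σ²between/(σ²between+σ²within)
   per coefficient localizes where on the outline populations differ
   (rostrum, excisura major/minor).
3. **Allometry filter** — per coefficient, an ANCOVA
   `coef ~ length + population + length:population`; coefficients with a
   significant length-by-population interaction are excluded because their
   population signal is confounded with population-specific growth.
4. **CAP ordination and permutation tests** — Canonical Analysis of
   Principal coordinates: PCoA of the Euclidean inter-specimen distance
   matrix, optional partialling-out of age, then a redundancy-style
   constrained ordination on population membership. Significance by an
   ANOVA-like permutation test on the pseudo-F statistic
   (constrained/df) / (residual/df), with exhaustive enumeration for tiny n
   and a-priori population contrasts.
5. **Isolation by distance** — Euclidean distances between population
   centroids on (CAP1, CAP2) against *along-coast* geographic distances
   (haversine arc length accumulated over an ordered waypoint path), tested
   with a one-sided Mantel permutation test; an OLS residual screen flags
   population pairs that deviate from the overall distance trend by more
   than two residual standard deviations.
6. **Synthetic data** — a generator producing populations of closed
   star-shaped outlines whose localized Gaussian deformations scale with
   along-coast position, with age-shrinking individual noise and
   length-age covariance, plus a rasterizer so the image stage is testable
   end to end against ground truth.

## Worked example

```python
import numpy as np
import otomorph as om

# 12 synthetic populations x 30 fish along a 1650 km coast
data = om.generate_dataset(om.SimConfig(rng_seed=1))

radii = {sid: om.radial_profile(ol, 512) for sid, ol in data.outlines.items()}
matrix = om.matrix_from_radii(radii)
group = data.meta["population_id"].to_numpy()
age = data.meta["age_years"].to_numpy(float)

keep = om.ancova_filter(matrix.values, data.meta["length_cm"].to_numpy(), group)
X = matrix.values[:, keep.kept]
print(f"retained {keep.n_kept} of {matrix.values.shape[1]} coefficients")

res = om.cap(X, group, covariate=age, n_perm=0)
test = om.permutation_anova(X, group, covariate=age, n_perm=2000, seed=2)
print(f"pseudo-F = {test['pseudo_F']:.2f}, p = {test['p_value']:.4g}")

pos = np.array(data.truth["config"]["coast_positions_km"])
d_shape = om.shape_distances(res.group_centroids[:, :2], labels=res.group_labels)
d_geo = om.DistanceMatrix(res.group_labels, np.abs(pos[:, None] - pos[None, :]))
r, p = om.mantel_test(d_shape, d_geo, n_perm=10000, seed=3)
print(f"Mantel r = {r:.3f}, p = {p:.4g}")
```

prints

```
retained 458 of 512 coefficients
pseudo-F = 6.27, p = 0.0004998
Mantel r = 0.970, p = 9.999e-05
```

The populations differ strongly in shape (p is the minimum attainable with
2000 permutations), and shape distance tracks along-coast distance almost
perfectly — the isolation-by-distance pattern the generator encodes, with
~10% of coefficients dropped by the allometry screen (close to the 5%
false-positive rate expected when few coefficients carry a real
length-by-population interaction).

A command-line interface covers the same pipeline for image folders:

```bash
otomorph simulate --config sim.yaml --out simdata/ --png
otomorph extract  --images simdata/images --meta simdata/meta.csv --out coefs.csv
otomorph analyze  --coefs coefs.csv --meta simdata/meta.csv --out results/
otomorph distance --results results/ --coastline coast.csv --meta simdata/meta.csv --out mantel.csv
```

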