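# Methods

## The system and the statistical model

The analysis targets a B73 × Mo17 intermated RIL population (89 lines)
grown under a face-centered response-surface design: five drought levels
(8, 20, 50, 80, 92 % of full pot weight) × five nitrogen levels (0, 2.5,
7.5, 12.5, 15 % fertilizer), realized as nine combinations — four extreme
corners, four face points (second/fourth level of one factor at the middle
level of the other), and the center — with replication concentrated at the
center (defaults 4 at corners/faces, 8 at the center). The trait is
`diff_height` = final − initial plant height (cm). Stress covariates are
recentred (water − 50, nitrogen − 7.5) so the design center is the origin
and the evaluation rectangle is [−42, 42] × [−7.5, 7.5].

The working model per record is a quadratic surface in (xw, xn) plus a line
random effect with covariance `sigma_line^2 * K` (K = allele-sharing
kinship) and i.i.d. Gaussian residuals. Assumptions worth stating: the
surface is globally quadratic (no higher-order bending), the line effect is
a pure intercept shift (no line × stress random slopes), and residual
variance is homoscedastic across stress combinations.

## Mixed-model estimation and the marker scan

Writing `V = sigma_e^2 (I + lambda Z K Z')` with `lambda =
sigma_line^2/sigma_resid^2`, the REML profile over `lambda` is evaluated
through the spectral decomposition of `Z K Z'` (eigendecomposition of K,
thin SVD of Z·K^{1/2}), so each REML step and every subsequent GLS fit is a
rank-L update costing O(n·L) — no n × n solve ever forms. `lambda` is
optimized on a log grid (coarse bracket on log-lambda in [−12, 8], then
bounded scalar minimization) with an explicit comparison against the
`lambda = 0` boundary.

Variance components are estimated **once**, on the all-inclusive pooled
model, and reused for every marker model. Rationale: the scan compares
residual sums of squares directly, which is only meaningful when all models
are whitened by the same covariance; re-estimating per marker at n = 89
lines is also unstable. For each marker, observations from lines with a
missing call are dropped and the pooled model's RSS is recomputed on the
same reduced set, so the F-test always compares nested models on identical
data. Degrees of freedom are (6, n − 12): the marker model adds one full
six-parameter coefficient set. Markers with fewer than `min_class_obs`
(default 10) phenotype records in either allele class are skipped and
flagged. When both models fit exactly (zero residual), F is defined as 0.

p-values are smoothed with a sliding Simes window (default 5 map-adjacent
markers, truncated at chromosome ends, never spanning chromosomes):
`smoothed_p = min_k (w * p_(k) / k)` over the sorted window values, capped
at 1. Multiplicity control is Benjamini–Hochberg FDR (via statsmodels) and
the Sidak experiment-wise threshold; QTL intervals are maximal runs of
map-adjacent significant markers (singletons allowed), each reporting its
bounding and best markers.

## Synthetic data

The generator emulates the study's statistical structure, not its biology:

* **Genotypes** — fully homozygous two-state Markov chains per chromosome;
  adjacent-marker recombination from Haldane's map function on the map
  distance × an *expansion factor* (default 4) standing in for the map
  expansion of the population's extra intermating generations. Defaults: 10
  chromosomes × 20 markers over 120 cM.
* **Kinship** — pairwise identity-in-state over mutually non-missing
  markers, diagonal 1. Pairwise-complete IBS can be indefinite under
  missing data (we observed a −0.4 eigenvalue at 8 % missingness), so the
  estimator projects onto the PSD cone (negative eigenvalues clipped, mean
  diagonal rescaled to 1) before the optional ridge (default 1e−6 in the
  GLS engine).
* **Phenotypes** — every line appears at every design combination at that
  combination's replicate count (40 records/line under the defaults; the
  per-combination allocation of the original experiment is not published,
  so this balanced reading is an assumption). `diff_height` = baseline
  (default 30 cm) + allele-matched producing-function values at the causal
  markers + line effect (one draw from N(0, sigma_line^2 K), default
  sigma_line = 2 cm) + residual (default sigma_resid = 3 cm); initial
  height N(15, 2²) cm. All randomness flows through one integer seed.

What the generator does **not** emulate: greenhouse spatial structure,
heteroscedasticity across stress levels, measurement error in image-based
height calls, segregation distortion, or epistasis. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data features.

The reference causal effect (used in the power checks and demo pipeline) is
the pair of illustrative producing-function surfaces — domed
(0.260, 0.305, −0.175, 2.575, 0.500) vs shallow trough
(0.0330, 0.4250, 0.0030, −0.0025, 0.5500). This is a very large effect: with
it, the planted locus is recovered essentially always, and weakly
kinship-correlated markers genome-wide also reach significance — the same
mechanism by which a small, related mapping population yields many
FDR-level QTL alongside a few experiment-wise ones.

## Surfaces, peaks and shape classes

Peaks are located by exhaustive grid search at step 0.5, not analytic
optimization, because reported peak coordinates are grid-quantized (the
analytic B73 optimum is (28.70, 4.59); the grid peak is (28.5, 4.5)). Ties
break toward smaller xw then smaller xn; reported values round to one
decimal.

Shape classes are assigned by a fixed rule: *trough* if the dominant
curvature (mean of the quadratic part over the grid — dominated by the
water term because that axis spans ±42 vs ±7.5) is concave upward;
otherwise *shoulder* if the peak's xw ≥ 36, *domed* if xw > 27, else
*hybrid*. The thresholds are conventions (category membership genuinely
depends on the criteria), are exposed as arguments, and an `ambiguous` flag
marks peaks within one grid step of a threshold.

## Producing-function fits

With `c` preset (−1 domed / +1 trough, chosen from the experimental
surface's dominant curvature), the fit is OLS of mesh z-values on
(c·xw², c·xn², xw, xn) with no intercept, via `numpy.linalg.lstsq` after an
explicit rank check. `s` = sqrt(residual sum of squares), unnormalized by
point count; `residual_norm` reports the solver's constraint violation,
identically 0 for this unconstrained problem, and is kept separate from
`s`. Only `c·a` and `c·b` are identifiable; `fit_producing` reports
a = product/c and b = product/c so that evaluating the returned parameters
reproduces the fitted surface.

One convention deserves care: in the bundled published parameter table, the
printed (a, b) columns are the identifiable *products* themselves.
`tables.published_model_surface()` converts a printed row into evaluable
parameters; the evidence for this reading is that the printed sign patterns
track surface convexity directly, and that only under it do the model
surfaces land where the published projections and exclusions put them.

## Meshes

*Relative mesh* — 10 points per ray at fractions k/10 of the clipped
segment from the peak to the first evaluation-plane edge, along 6 rays of
slopes {0, 0.05, 0.099, 0.175, 0.32, 0.75}. Dome-type surfaces send rays
leftward-downward (direction (−1, −slope)); trough-type surfaces rightward
with negated slopes (direction (+1, −slope)). Uniform k/10 spacing is the
simplest reading of "same relative distances"; the spacing choice only
rescales band positions, not the scores' identities. Rays of zero clipped
length collapse onto the peak and are flagged.

*Absolute mesh* — rays at {0, ±15, ±30, ±45}° about the surface's local
axis (Hessian eigenvector of smaller-magnitude eigenvalue for elliptic
quadratic parts; asymptote bisector for hyperbolic ones; water component
≥ 0), intersected with contours at fractions {0.05, 0.15, 0.30, 0.50} of
the peak-to-ray-end z drop. The contour fractions are this package's
choice — they concentrate points in the central, best-determined region —
and are exposed in `MeshSpec`; the originally used contour levels and
angles are not part of the printed record, which is why exact published
parameter values (and their `s`) are not bit-reproducible. Intersections
are found by bracketing on 256 probes plus bisection to |Δz| < 1e−6
(far below phenotype noise); rays with no crossing are flagged per
(ray, contour), not invented.

## Shape similarity

ρ = sign(z_s − z_e) · 3-D distance between corresponding mesh points (the
sign is taken from the z displacement — the interpretable direction);
θ = signed angle at the evaluation-plane origin between the projected
points (origin-subtended, because rays anchored at each surface's own peak
would make peak shifts invisible); δzr = difference of discrete z-gradients
along rays, each normalized by the surface's own grid amplitude
|zmax − zmin| so the score reflects shape, not scale. Score matrices order
columns as concentric rings (all rays at position 1, then position 2, …).

A simulated surface is excluded from comparison when it is displaced too
far in the evaluation plane to carry a comparable mesh: concretely, when
its grid peak sits on an edge that blocks its ray fan (any ray collapses),
or when a definite-maximum paraboloid peaks outside the plane inflated by
10 % (configurable). On the bundled published rows this admits 6 of 8 model
surfaces.

## Problem sizes and numerical choices

The test suite's simulation checks use 89 lines × the default design
(3560 records): null calibration pools raw p-values over 200 replicate
scans of 20 markers each (Kolmogorov–Smirnov uniformity and Sidak
family-wise error), and power uses 20 seeds × 200 markers; these sizes give
stable Monte-Carlo estimates while the whole suite stays a few minutes.
REML uses a 1e−6 kinship ridge; SVD components below 1e−12 of the largest
singular value are dropped; rank checks guard every least-squares fit.

## Known limitations

* The line random effect is an intercept; genotype × environment random
  structure beyond the fixed allele surfaces is not modeled.
* The F-test's null distribution treats the REML variance components as
  known; at these sample sizes the calibration is empirically clean
  (KS p ≈ 0.99 in the bundled check), but very small populations may need
  a permutation reference.
* Shape classification thresholds and mesh configuration are conventions;
  conclusions about category membership should be read jointly with the
  `ambiguous` flag and the exposed settings.
* No epistasis scan and no composite-interval mapping; the scan is
  single-marker by design.
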