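# Methods

This note records the statistical model, the numerical conventions, and
the design choices behind `isoniche`, in enough detail that every number
the package produces can be traced to a definition.

## Model and assumptions

Each group's isotope triples (δ¹³C, δ¹⁵N, δ³⁴S) are modelled as i.i.d.
draws from a trivariate normal N(μ, Σ).  Everything downstream — the
standard ellipsoid, coverage rescaling, the Bayesian volume posterior,
overlap — is a functional of (μ, Σ) under that assumption.  Mardia's
test is provided to check it; the package only reports verdicts and
never auto-excludes a non-normal group, because apparent non-normality
in niche data is often a few genuinely different individuals rather
than a modelling failure, and whether to keep them is an ecological
judgement.

## Ellipsoid geometry

* The *standard* (1-σ) ellipsoid is the shell of squared Mahalanobis
  radius 1 around μ.  Its shape matrix is the unbiased (n−1 denominator)
  sample covariance; because the unbiased estimator is used, the
  degrees-of-freedom correction (n−1)/(n−3) applied by `sev_c` must not
  be applied a second time.
* Coverage rescaling multiplies Σ by q_p/q_current, with q_p the
  χ²₃ quantile at p.  This is the unique rescaling consistent with the
  normality assumption, since the squared Mahalanobis radius of a
  trivariate normal is χ²₃.  The `Ellipsoid` type carries its coverage
  explicitly so volumes and overlaps are always compared at like scale;
  mixing scales raises an error rather than silently comparing.
* Eigenvalues below 10⁻¹² of the largest trigger a "degenerate
  covariance" error instead of silent regularization: collinear isotope
  data mean the three-dimensional niche is not identified and the user
  should know.
* Equal-eigenvalue ties are harmless for every quantity the package
  reports (volumes and containment are basis-free); `semi_axes` simply
  returns the sorted eigenvalue roots.

## Mesh overlap

The intersection of two ellipsoids is convex, so the convex hull of any
point set contained in both is an inner approximation of the true
intersection.  The point set combines (i) vertices of each ellipsoid's
surface mesh contained in the other ellipsoid (with a 10⁻⁹ slack so
surface points count as inside, which is what makes self-overlap exactly
100%), and (ii) the points where each mesh edge crosses the other
surface, found as roots of a quadratic along the edge in the whitened
frame.  Including the edge crossings sharpens the hull substantially at
low subdivision; the under-approximation property is preserved because
every added point still lies in both ellipsoids.

Mesh convention: level 0 is a 16×16 latitude–longitude quadrilateral
grid on the unit sphere (pole bands are degenerate quadrilaterals of
zero area); each subdivision level splits every quadrilateral into four
through edge midpoints and the face centroid, all reprojected onto the
sphere, and the sphere mesh is carried onto the ellipsoid by x = c + Lu
with L the lower Cholesky factor of the shape matrix.  The default
working level is 4 (65,536 faces), where the hull of a unit-sphere mesh
recovers 99.99% of the sphere volume and overlap volumes sit within
~0.5% of closed-form test cases.

Directed percentages divide the intersection-hull volume by each mesh's
*own* hull volume at the same subdivision level, not by the analytic
ellipsoid volume.  Both numerator and denominator are then inscribed
approximations with the same bias direction, so the ratio converges
faster than either volume, identical ellipsoids report exactly 100%,
and a small ellipsoid nested in a large one reports exactly 100% of
itself.  The intersection volume is clamped to the smaller mesh volume,
since edge-crossing points lie on the true surface and can poke
marginally past an inscribed hull.  Degenerate intersections (fewer
than four non-coplanar points) return volume 0: tangent ellipsoids have
negligible true overlap.

Properties maintained (and tested): the absolute volume is symmetric in
its arguments, non-decreasing in subdivision level, an
under-approximation of the truth, and equivariant under invertible
affine maps (volumes scale by |det|, percentages are invariant).  An
independent rejection-sampling oracle (`mc_overlap_oracle`) provides
the cross-check; it shares no code with the mesh path.

## Bayesian estimation

Prior: conjugate Normal–Inverse-Wishart, μ|Σ ~ N(m₀, Σ/κ₀),
Σ ~ IW(ν₀, Λ₀), defaults m₀ = 0, κ₀ = 10⁻³, Λ₀ = 10⁻³·I, ν₀ = 0.
The ν₀ = 0 default is deliberate and matters.  An Inverse-Wishart
prior with positive degrees of freedom adds ν₀ pseudo-observations of
the near-zero scale matrix, and the volume statistic √det Σ is
sensitive to exactly that shrinkage: with ν₀ = 4 (the smallest value
giving a finite prior mean) the posterior-median 1-σ volume is biased
about −23% at n = 30 and −7% at n = 100.  With ν₀ = 0 — the
independence-Jeffreys-style limit p(Σ) ∝ |Σ|^−(p+1)/2 as Λ₀ → 0 — the
bias is confined to small samples (≈ −50% at n = 5, −20% at n = 8,
−2% at n = 100), matching the intended behaviour of the method:
material underestimation only at n ≤ 8.  The prior is then improper,
but every Gibbs conditional and the joint posterior are proper for the
n ≥ 4 the package requires.  Users with real prior information can pass
any `NIWPrior`; sensitivity to ν₀ is the first thing to examine.

Sampling: conjugacy gives exact full conditionals
(μ|Σ,X normal; Σ|μ,X Inverse-Wishart with ν₀+n+1 degrees of freedom),
so the Gibbs sampler needs no tuning and mixes essentially immediately.
Default settings are 15,000 iterations, burn-in 10,000, thinning 25
(200 retained draws) for volume posteriors, and 7,500/5,000 for the
overlap run; the thinning factor of the overlap run is a package
convention (thin = 1) since every retained pair costs a full mesh
intersection, and `max_overlap_draws` can subsample pairs when 2,500
mesh intersections per species pair is more than a use case needs.
One seeded generator drives each group's fit; overlap pairs draws by
retained index so that joint uncertainty propagates.

Summaries: volumes are reported as median and 25–75% interquartile
range; overlap as median and equal-tailed 2.5–97.5% credible interval
(the equal-tailed convention is a package choice; HPD intervals would
differ slightly for skewed overlap posteriors).  Quantiles use linear
interpolation.  Directed overlap at or above 60% is flagged
significant, an interpretive convention from the reef-predator
literature, not a hypothesis test.

## Preprocessing

* Lipid correction: δ¹³C_protein = [(δ¹³C_sample·C:N) + 7·(C:N − 3.7)]
  / C:N, applied only when C:N > 3.7 (3.7 being the assumed protein
  C:N).  The correction is not idempotent, so the table-level API
  carries a `lipid_corrected` flag and refuses to re-correct.
* Layman ranges CR/NR/SR are max − min per axis after lipid correction;
  undefined for singleton groups.
* Mardia's test uses the maximum-likelihood (n denominator) covariance
  in the doubly centred Mahalanobis products, skewness statistic
  n·b₁/6 against χ²₁₀, kurtosis z = (b₂ − 15)/√(120/n) two-sided
  against N(0,1); the small-sample skewness correction factor
  (p+1)(n+1)(n+3)/[n((n+1)(p+1) − 6)] is applied automatically when
  n < 20 (switchable).  Verdict "normal" requires both p-values > α
  (default 0.05).

## Synthetic data

`simulate_groups` draws each group from its trivariate normal;
`default_community()` ships a SYNTHETIC two-area, seven-species reef
predator community with group sizes 1–13, per-mil-scale means and
diagonal covariances (dispersions backed out from plausible standard
errors as SE·√n), a singleton group to exercise the minimum-sample
exclusion path, and C:N ratios uniform on (2.9, 4.5) so both lipid
branches occur.  What it does *not* emulate: inter-isotope correlation
(covariances are diagonal; real niches are usually tilted), non-normal
individuals, measurement error structure, and any size- or
area-dependence of isotope values.  Passing tests on these fixtures
therefore validate the estimators under the model's own assumptions;
they do not certify behaviour on real data that violates them.

## Problem sizes used in the test suite

Replicated-simulation tests use deliberately economical settings chosen
once: short Gibbs chains (600–1,500 iterations — adequate because the
conjugate sampler has no warm-up pathology), 100 replicates for
bias/coverage sweeps, mesh subdivision 0–1 inside posterior-overlap
loops, and subdivision 4 wherever a single overlap is being checked
against an oracle.  Monte Carlo calibration checks use 10⁵ containment
samples (±0.3% standard error on a coverage fraction) and 10⁶ points
for volume oracles.

## Known limitations

* Strictly three-dimensional; no n-dimensional generalization.
* Overlap is mesh-based and biased low at coarse subdivision; use
  level ≥ 3 for reported numbers and level 4 for publication-grade ones.
* No convergence diagnostics beyond determinism and the SPD invariant —
  defensible only because the sampler is conjugate; swapping in a
  non-conjugate sampler would require real diagnostics.
* No plotting; the mesh vertices/faces are exposed for users who want
  to render ellipsoids themselves.
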