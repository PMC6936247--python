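# isoniche

Tri-isotope niche ellipsoids for trophic ecology: volumes, Bayesian
uncertainty, and mesh-based overlap in (δ¹³C, δ¹⁵N, δ³⁴S) space.

## The problem

Stable isotope ratios of carbon, nitrogen and sulfur in consumer tissue
summarize what an animal has been assimilating: δ¹³C and δ³⁴S trace the
production sources fuelling its food web, δ¹⁵N its trophic level.  The
region of isotope space a population occupies — its *isotopic niche* —
is widely used as a proxy for its trophic niche, and in two dimensions
(δ¹³C, δ¹⁵N) the standard ellipse of a bivariate normal is the standard
tool.  `isoniche` extends that machinery to three isotopes, for
ecologists who want δ³⁴S in the niche rather than projected away:

* **Standard ellipsoid volume.**  For a trivariate-normal sample with
  covariance Σ, the 1-σ ellipsoid has semi-axes a ≥ b ≥ c equal to the
  square roots of the eigenvalues of Σ, and volume
  **SEV = (4/3)πabc = (4/3)π√det Σ**.  The small-sample correction
  **SEV_C = SEV·(n−1)/(n−3)** removes the downward bias of the sample
  covariance determinant.  The 1-σ ellipsoid captures ≈20% of the
  population (P(χ²₃ ≤ 1) ≈ 0.199); multiplying Σ by the χ²₃ quantile q_p
  rescales it to capture any proportion p (q₀.₇₅ ≈ 4.108).
* **Bayesian volumes (SEV_B, EV_B).**  A conjugate
  Normal–Inverse-Wishart Gibbs sampler draws the posterior of (μ, Σ);
  each covariance draw yields a volume, giving a posterior distribution
  whose median and interquartile range summarize niche size with
  uncertainty.  EV_B denotes the volume rescaled to 75% coverage.
* **Pairwise overlap.**  Each ellipsoid is meshed by quadrilateral
  faces (a 16×16 latitude–longitude sphere grid pushed through the
  Cholesky factor of Σ, refined by face quadrisection); the convex hull
  of the mesh intersection estimates the overlap volume, reported as a
  directed percentage of each ellipsoid's own mesh volume.  Computed per
  paired posterior draw, this gives a median overlap with a 95% credible
  interval; directed overlap ≥60% is flagged as significant.
* **Preprocessing.**  Lipid correction of δ¹³C when tissue C:N > 3.7,
  Layman-style isotope ranges (CR/NR/SR), and Mardia's multivariate
  normality test with its small-sample skewness correction.

## Worked example

```python
import numpy as np
from isoniche import GroupSpec, IsotopeNicheModel, simulate_groups

spec = GroupSpec(
    species="Cephalopholis argus", area="inner", n=40,
    mean=np.array([-15.5, 12.8, 19.3]),
    covariance=np.diag([0.6, 0.1, 0.7]),
)
table = simulate_groups([spec], seed=3)

model = IsotopeNicheModel.from_dataframe(table, label="C. argus (inner)")
print(model.fit().summary())
print()
print(model.fit_bayes(seed=11).summary(coverage=0.75))
```

```
Trivariate Isotope Niche (analytic)
====================================================
Group:          C. argus (inner)
Observations:   40
Center (permil): d13C  -15.547   d15N  12.817   d34S  19.225
Semi-axes:      a 0.937  b 0.831  c 0.327
SEV:            1.0673 permil^3
SEV_C (n=40):   1.1250 permil^3
Ranges:         CR 4.765  NR 1.615  SR 3.526
Mardia:         skew p=0.672  kurt p=0.865  [normal]
```

```
Trivariate Isotope Niche (Bayesian)
====================================================
Group:          C. argus (inner)
Observations:   40
Sampler:        conjugate NIW Gibbs — 15000 iterations, burn-in 10000, thin 25 (200 draws)
EV_B (75%):     median 9.3180 permil^3   IQR [8.1533, 10.6179]
```

Reading this: the group's 1-σ ellipsoid occupies 1.07‰³ of isotope
space (1.13‰³ after small-sample correction); its data are consistent
with trivariate normality; the Bayesian 75% ellipsoid volume is 9.32‰³
with an interquartile range of [8.15, 10.62] — the ≈8× jump from SEV
reflects the 75% rescaling (q^{3/2} ≈ 8.3), not a different niche.

Overlap between two fitted groups:

```python
ba = IsotopeNicheModel.from_dataframe(table_b).fit_bayes(seed=1)
bb = IsotopeNicheModel.from_dataframe(table_c).fit_bayes(seed=2)
post = ba.overlap(bb, coverage=0.75, subdivision=4)
post.median_ab, post.ci_ab, post.significant_ab
```

## Command line

```bash
isoniche simulate --out survey.csv --seed 3
isoniche run --input survey.csv --out-dir results \
    --iterations 15000 --burn-in 10000 --thin 25 --subdivision 4 --seed 1
```

`run` writes per-group metrics (`metrics.csv`: n, CR/NR/SR, Mardia
p-values, SEV, SEV_C), posterior volume summaries (`volumes.csv`),
a tidy overlap table plus per-area overlap matrices formatted as
"median (2.5–97.5)", an exclusion report, the resolved configuration
and a run log.  Groups below `--min-n` (default 4) are reported and
skipped; overlap is only computed between groups in the same area.

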