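# Methods

## Mean–variance construction and fitting

An OTU table is a non-negative matrix of abundances, OTUs × samples.
Values may be raw counts or normalized relative abundances; which was used
is recorded in the output provenance, since the choice shifts the intercept
but, by the scale-covariance of the law (multiplying abundances by c maps
(M, V) to (cM, c²V)), changes the slope only through which pairs survive
the log transform.

* **Type-I**: for each sample, M is the mean and V the variance of that
  sample's abundances across *all* OTUs, zeros included — an OTU absent
  from a sample is an observation of abundance 0, not missing data.
* **Type-III**: for each OTU, M and V are taken across samples, zeros
  included for the same reason.

Variance uses the unbiased n−1 denominator by default; the population
(n) denominator is selectable (`ddof=0` / `--variance population`) so the
sensitivity of a fit to this convention can be checked directly.  Pairs
with M = 0 (unit entirely absent) or V = 0 (constant values) have no
logarithm and are dropped *as whole pairs* before fitting; the count of
dropped pairs is kept and logged, because silent filtering is the main way
such analyses become unauditable.

The law ln V = ln a + b ln M (natural log) is fitted by ordinary least
squares. Reduced-major-axis fitting is a known alternative when both axes
carry sampling error, but OLS is the conventional treatment of the
log-linear form and is what the reported slope b means here.  The 95%
confidence interval for b uses the t distribution with n−2 degrees of
freedom; at least 3 retained pairs are required (the CI is undefined
below that).  No rare-OTU filtering is applied by default; a
`min_prevalence` option exposes the choice for Type-III fits.

Heterogeneity classification: on the point estimate, b < 1 is *uniform*,
b = 1 (to 1e-12) *random*, b > 1 *aggregated*.  On the CI basis, a fit is
*aggregated* only when the whole interval lies above 1 and *uniform* only
when it lies below 1; anything straddling 1 is reported as *random* (b = 1
not excluded).  The CI basis is the default everywhere because slope point
estimates from noisy variance estimates are above or below 1 almost surely.

## Skin-area geometry

The host body is idealized as a cone (head: base diameter = head width b,
height = head length a) on a cylinder (trunk: diameter b, height h − a,
with h the body length).  The 3D area is the lateral cone surface
(π·b/2·√(a² + b²/4), the standard slant-height form) plus the lateral
cylinder surface (π·b·(h − a)) plus a single base disc (π·b²/4) at the
posterior end; no disc is placed at the cone/cylinder junction, which is
interior surface.  The single-disc reading is an explicit modelling
assumption.  The 2D counterpart is the silhouette: triangle (a·b/2) plus
rectangle (b·(h − a)).  Limbs are deliberately omitted.  Traits are
validated as a ≥ 0, b ≥ 0, h ≥ a; units are millimetres by convention but
the formulas are unit-agnostic.  A species' area is the arithmetic mean of
its individuals' areas.

## Diversity statistics

Shannon diversity uses the natural log (nats); the log base affects the
values, not any rank-based comparison built on them.  Kruskal–Wallis is the
tie-corrected rank test with a chi-squared reference distribution; the
all-values-identical degenerate case is defined as H = 0, p = 1.
Bray–Curtis is Σ|x−y| / Σ(x+y) on raw counts by default (a relative-
abundance flag exists); a pair of all-zero samples, whose quotient is 0/0,
is defined as distance 0 with a warning.

ANOSIM is implemented in-package rather than delegated, for three reasons:
the permutation stream must be seedable for byte-reproducible runs, the
p-value uses the add-one estimator p = (1 + #{R_perm ≥ R_obs}) / (1 +
n_permutations) so it can never be 0 and never falls below
1/(n_permutations+1), and small problems can be solved *exactly* by
enumerating all distinct label arrangements (`exact=True`), which the test
suite exploits against a brute-force oracle.  Distance ranks use midranks
for ties, which is required for R to stay in [−1, 1].  The statistic agrees
with scikit-bio's implementation to machine precision (tested).  The
default permutation count is 999, with the seed mandatory in the CLI.

## Scale invariance

Per-species fitted slopes are regressed (OLS) on the species' mean skin
area, for both levels and both area models (the 2D/3D cross-validation).
The area axis is untransformed by default with a `--log-area` option.  The
trend's slope, p and r² are reported; "invariance" is left to the user's
judgement rather than a formal equivalence test.  A constant-b input is
returned as slope 0, r² = 0 rather than a 0/0.  Phylum dominance for the
dominant-phyla fits is ranked by summed abundance across all samples (not
prevalence), with alphabetical tie-break.

## Synthetic data

The generator targets the law directly.  Each unit (OTU for Type-III,
sample for Type-I) draws a mean M log-uniformly from [m_lo, m_hi] (default
[1, 100]: two decades, spreading ln M so the regression design is
well-conditioned, and matching the rate range used for the Poisson-null
benchmarks); its variance is pinned to V = exp(ln_a)·M^b; its observations
are then drawn i.i.d. from a distribution realizing that moment pair:
gamma (shape M²/V, scale V/M — any positive moment pair, continuous
abundances, optional rounding), Poisson (V = M, the randomness null), or
negative binomial (integer counts, requires V > M).  Draws are independent
across units and observations: the fitted law concerns marginal moments
only, and spatial or taxon–taxon correlation is out of scope.

The study-level generator concatenates per-species communities: each host
species owns a block of OTUs with its own mean profile (so compositions
shift between hosts and ANOSIM can separate them), optionally plus a
shared core block with a common profile (hosts share their dominant
microbes).  Traits are drawn from truncated-at-zero normals with h ≥ a
enforced by resampling (bounded at 1000 attempts, after which the trait
spec is reported as infeasible).  Every OTU gets a phylum drawn from a
configurable proportion table whose default is dominated by Proteobacteria
and Bacteroidetes, as amphibian skin communities typically are.  The
default study emulates a field survey of 10 host species and 358 samples
over 10 sites, species mean body lengths from 35 to 110 mm (head length
0.32×, head width 0.30× body length, SDs 8% of the mean), 300 OTUs per
species plus a 200-OTU core, and an aggregated Type-III law with b = 1.8.

What passing tests on these data do **not** show about real data:
sequencing depth variation, compositionality constraints, taxon
co-occurrence structure, site effects and phylogenetic signal are all
absent, so the tests validate the *estimators*, not the field inference.

## Known limitations and numerical notes

* **Log-variance bias at low gamma shape.**  The sample variance of n
  draws from a gamma with shape k has relative sampling variance
  ≈ (2 + 6/k)/n, and E[ln s²] < ln σ² by roughly half that.  When the
  target law makes k = M^(2−b)/a small for large M (e.g. b = 2.5, a = 1,
  M up to 100 gives k down to 0.1), this bias varies with M and pulls the
  fitted slope slightly toward 2 (about −0.03 at b = 2.5 with 100
  observations per unit).  The median recovered slope stays within ±0.05
  of targets in [1.2, 2.5] at 500 units × 100 observations, but the OLS
  confidence interval — which knows nothing of this bias and is narrow at
  500 points — can then undercover the target (severely so at b = 2.5).
  This is a property of regressing log sample variances, not of the
  generator; it is visible in the test suite and deliberately not papered
  over.
* Poisson-null slope recovery is essentially unbiased (the shape analogue
  k = M is large over [1, 100]), which is why the null benchmarks sit
  within ±0.01 of 1.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; identical seeds give bit-identical tables, permutation
  streams and output files.
* Problem sizes in the test suite (up to 500 units × 100 observations, 50
  replicates per target; one full 358-sample study) were chosen as the
  smallest at which the statistical claims are stable across seeds.
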