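# Methods

This note documents the statistical machinery in `sfcoupling`: what each
stage computes, the modelling assumptions, the defaults and why they were
chosen, and what the synthetic cohort does and does not emulate.

## Connectome construction

A scan contributes two 360x360 (configurable) matrices over a fixed cortical
parcellation:

* **Functional connectivity (FC)** — Pearson correlation between each pair of
  regional time courses (`fc_from_timeseries`), diagonal zeroed. Zero-variance
  regions get zero rows with a warning rather than NaNs, so downstream
  selection logic stays finite.
* **Structural connectivity (SC)** — streamline counts scaled by the inverse
  volumes of the two endpoint regions:
  `w_ij = counts_ij * (1/v_i + 1/v_j) / 2`. Tools that apply inverse-node-
  volume scaling do not document a single canonical formula; the mean of the
  two inverse volumes is used here and recorded as this package's convention.
  Matrices are symmetrized exactly (after an asymmetry check at 1e-8) and the
  diagonal forced to zero.

Scan-level QC excludes scans whose functional mean frame-wise displacement
exceeds 0.5 mm (strictly greater; the boundary scan is kept). Diffusion
motion (`fd_dwi`) is not an exclusion criterion — it enters the trajectory
models as a covariate, alongside functional motion, scanner upgrade, sex and
medication.

## Consistency-based thresholding

For every edge, the coefficient of variation (sample SD / mean, zeros
included as weights) of its weight across *all* included scans is computed;
edges whose mean weight is zero are never candidates. The retained set is the
candidates with CV at or below the 75th percentile (linear-interpolation
"type 7" quantile; ties at the threshold are kept), i.e. the 75% most
consistent edges. One pooled mask is computed across groups and waves — a
single mask keeps the coupling statistic comparable across groups; per-group
masks would confound group differences with mask differences. Nodes with no
surviving edges are excluded from coupling for every scan.

## Regional structure-function coupling

Region i's coupling in a scan is Spearman's rank correlation between
`SC[i, S]` and `FC[i, S]` where `S = {j != i : masked SC[i, j] > 0}` — the
region's connectivity *profile* restricted to its non-zero structural
entries. Selection is on SC only: an FC value of zero is a legitimate
correlation. Regions with fewer than `min_edges = 3` profile entries (the
minimum for a defined rank correlation) are recorded as missing. Ranks use
average-tie assignment; a constant profile yields a missing value rather than
a spurious number.

## Developmental trajectory models

Per region, coupling is modelled as a Gaussian additive mixed model with a
subject random intercept for the repeated scans:

* **M0** — intercept + fd_dwi + fd_fmri + scanner + sex + medication.
* **M1** — M0 + s(age): penalized cubic B-spline, basis dimension k = 4,
  second-order difference penalty, knots at age quantiles, sum-to-zero
  constraint over the observed ages.
* **M2** — M1 + group indicator.
* **M3** — M2 + a group-specific smooth deviation: the same constrained age
  basis multiplied by the group indicator, with its own smoothing parameter,
  so M2 is nested in M3 exactly.

Covariate columns with zero variance in the analysed subset (e.g. medication
in a controls-only analysis, where nobody is medicated) are dropped with a
log entry; a genuinely singular design is a hard error.

### Fitting

Each smooth is reparametrized by eigendecomposition of its (constrained)
penalty: the penalty null space (the linear trend, once the constant is
absorbed by the constraint) joins the fixed effects; the penalized directions
become iid Gaussian random-effect columns whose variance ratio is the inverse
smoothing parameter. All variance parameters — subject-intercept ratio and
one ratio per smooth — are estimated by maximizing the exact marginal
log-likelihood (ML, not REML), with the fixed effects and residual variance
profiled out. The subject block of the marginal covariance is inverted in
closed form (it is block diagonal), and the few smooth columns enter through
a small Woodbury correction, so one likelihood evaluation costs microseconds
and a full 360-region four-model ladder runs in a few minutes on one core.
Optimization is bounded quasi-Newton over log variance ratios from five
deterministic starts (the two most promising starts are polished to
convergence, then refined by a derivative-free simplex); there is no
randomness in fitting. The reported log-likelihood reproduces by direct dense
evaluation of the marginal Gaussian density to better than 1e-6, and on
balanced random-intercept data the variance estimates match the closed-form
one-way ANOVA ML expressions.

### Model comparison

Nested models are compared by likelihood-ratio tests. The degrees of freedom
count every identifiable basis column of an added smooth (k - 1 = 3 after
the constraint), a deliberate upper bound for a penalized term that makes the
test conservative (null stage-1 rejection runs below the nominal 5%).
`AIC = -2 loglik + 2 (n_fixed + n_varpar)` with the same column counting plus
one per free variance parameter — an internally consistent definition, not a
reproduction of any other package's AIC.

The ladder is walked forward (M0 -> M1 -> M2 -> M3); the walk advances only
if the stage LRT has p < 0.05 *and* the more complex model improves AIC by at
least 2 units ("improve by >= 2" is this package's reading of an ambiguous
"AIC units < 2" convention; the margin is configurable and recorded in the
output metadata). `selected` is the last accepted model. Because a strict
sequential walk can never reach the group stage for a region with a pure
group offset and no age effect, the stage LRTs are *also* computed
unconditionally along the ladder and each region receives a `label`: the
deepest stage that passes its own LRT + AIC criterion (interaction > group >
age > null). The label is the region's winning-contrast classification and is
what recovery analyses score; both columns are reported.

Benjamini-Hochberg FDR at q <= 0.05 is applied separately per contrast
family across regions (age p-values; group p-values; interaction p-values);
missing p-values pass through without counting toward the number of tests.

Two analyses mirror the study design: `run_typical_development` (controls
only, M0 vs M1) and `run_group_ladder` (both groups, full ladder). Regions
with fewer than 10 usable rows, or missing a group entirely, are skipped and
logged. Network roll-ups (`summarize_by_network`) are purely descriptive.

## Synthetic cohort

The generator emulates the reference sample's statistical structure: 91 ADHD
and 84 control subjects; up to three waves at 1.4 +/- 0.15-year intervals;
first-wave age Normal(10.4, 0.5) years; per-wave attendance Bernoulli(0.44)
conditioned on attending at least one wave, which puts the expected cohort at
~280 scans (~278 after motion QC); ~69%/56% male (ADHD/control); lognormal
head motion with group-specific means (diffusion ~0.40/0.35 mm, functional
~0.16/0.13 mm) so a realistic ~1-2% of scans fail the 0.5 mm QC rule;
medication only in the ADHD group at per-wave rates 21%/19%/7%; scanner
upgrade at wave 3.

The group-level SC topology is a stochastic block pattern (8 communities,
within-community edges ~3x denser and 2x heavier) with log-normal weights,
redrawn until connected. Default edge density is 0.55 — streamline-filtered
whole-cortex connectomes are dense, and this leaves a 360-node region with
roughly 150 profile entries after 75th-percentile masking, so the Spearman
sampling noise of a single coupling estimate is ~0.06-0.07, the regime the
real statistic lives in. Per-scan SC multiplies each edge by an iid
log-normal factor (sigma = 0.4 on the log scale) and drops a random 5% of
edges, which is what gives the consistency-thresholding stage its across-scan
variability.

### Planting coupling

Each region follows a scenario: `null` (constant base 0.25), `increasing`
(+0.04/yr), `increase_then_plateau` (flat after age 12), `group_offset`
(ADHD -0.10), or `group_by_age` (ADHD +0.05/yr, controls flat). The default
map assigns 20/10/10/10 effect regions (seeded spread over the parcellation)
and leaves the rest null. Per-scan targets add a per-subject offset
(SD 0.02) and residual noise (SD 0.05), clipped to [-0.95, 0.95].

FC is generated through a Gaussian copula: region i's latent profile over
its structural neighbours is `r_i * z(rank(SC_i)) + sqrt(1 - r_i^2) * eps`,
the (i, j) and (j, i) constructions are averaged on the latent scale, and the
result is squashed monotonically into (-1, 1) (`tanh(0.25 + 0.4 sqrt(2) w)`;
structurally unconnected pairs get weak noise correlations, SD ~0.12). The
Spearman target converts to a latent Pearson correlation by the exact
bivariate-Gaussian relation `r = 2 sin(pi rho_s / 6)`. Naively setting
`r_i` from the target alone would attenuate realized coupling by ~1/sqrt(2),
because the averaged edge carries the neighbour row's construction too; the
per-row correlations are therefore solved by fixed point from

    rho_i = (r_i + c rbar_i) / sqrt(2 (1 + c r_i rbar_i)),

where `c` is the rank coherence between the two endpoint rows' scores of a
shared edge, estimated from the SC matrix itself, and `rbar_i` is the mean
`r` over region i's neighbours. With this calibration the measured coupling
tracks planted targets essentially 1:1 (regression slope ~0.99, rank
correlation ~0.99 for targets spanning 0.1-0.6), so planted slopes are
realized at the stated magnitudes rather than shrunk.

### What the generator does not emulate

No neural dynamics or simulated BOLD series (FC statistics beyond the planted
profile couplings are not matched to real data); no spatial embedding or
distance-dependent connectivity; no hub/rich-club structure beyond
communities; no longitudinal autocorrelation in SC beyond the shared group
topology; no site/sequence effects other than the binary scanner flag.
Passing recovery tests therefore demonstrates that the pipeline detects the
planted class of trajectory under realistic noise and missingness — not that
it would have identical power on real MRI.

## Numerical choices and degenerate inputs

* Matrix reads accept comma or whitespace delimiters; writes are
  comma-delimited with 17 significant digits (lossless round-trip). Asymmetry
  beyond 1e-8 is an error naming the offending indices; smaller asymmetry is
  averaged away exactly.
* Quantiles are linear-interpolation (type 7) everywhere; threshold ties are
  kept.
* Spearman denominators of zero (constant profile) yield missing values.
* LRT deviances are clipped at zero (optimizer noise can leave the complex
  fit marginally lower); df <= 0 is a nesting error.
* Variance ratios are optimized on log10 scale in [-8, 6]; ratios pinned at
  the lower bound correspond to an effectively infinite smoothing parameter.
* An unconverged fit is flagged and truncates the selection ladder at the
  last converged model.

## Problem sizes used in the test suite

Unit tests run on reduced cohorts (e.g. 28 subjects, 48 nodes) chosen so the
whole suite exercises every stage, including the file-based pipeline and CLI,
in a few minutes. The recovery and calibration checks run at the study's
scale where it matters: the planted-effect recovery test uses the full
default cohort (175 subjects, 360 nodes, ~278 scans), and null calibration
uses 500 regions. The end-to-end byte-identity check runs the `full` CLI at
48 nodes / 40 subjects, since determinism does not depend on size.
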