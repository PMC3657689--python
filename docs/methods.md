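# Methods

## The question

Two-group longitudinal rehabilitation studies — the motivating case is
post-stroke spatial neglect, where severity is tracked with a scale such
as the Catherine Bergego Scale (lower = less severe) over repeated
assessment sessions — are usually analysed with a mixed between-within
(split-plot) repeated-measures ANOVA. Neglect data violate that
analysis's assumptions in characteristic ways: large between-subject
differences in baseline severity, large differences in recovery rate,
and a strong negative correlation between the two (patients who start
better improve faster under prism-adaptation treatment). This package
implements both analyses from scratch and a Monte Carlo harness that
measures, under a growth-curve generating process with exactly those
features, the power and Type-I error of four inference procedures for
the group-by-session interaction — the term that says the treatment
changed the recovery trajectory.

## Generating model

Each subject j in group g follows

    Y_ij = (b0 + b0j) + (b1_g + b1j) * s_i + e_ij

with sessions coded s_i = 0, 1, ..., t-1 (so the intercept is baseline
severity), (b0j, b1j) bivariate normal with SDs (sigma_0, sigma_1) and
correlation rho, and e_ij iid N(0, sigma_e^2). Panels are balanced and
complete; improvement means a negative slope.

Default parameters (all configurable through `GeneratingModel`):

| parameter              | default | origin                                         |
|------------------------|---------|------------------------------------------------|
| fixed intercept b0     | 20      | arbitrary location; no test depends on it      |
| sigma_0 (intercept SD) | 8.42    | published mixed-model re-analysis estimate      |
| sigma_1 (slope SD)     | 0.927   | same re-analysis estimate                       |
| rho (int-slope corr)   | -0.93   | same re-analysis estimate                       |
| sigma_e (residual SD)  | 2.56    | same re-analysis estimate                       |
| slope-SD used for d    | 2.00    | standardization convention for effect sizes    |

The effect size d is the difference between the group slopes in units of
a conventional slope SD of 2.00, so d = 0.20, 0.50, 0.80, 1.00 map to
treatment slopes -0.40, -1.00, -1.60, -2.00 with the control slope fixed
at 0. Note the deliberate separation: 2.00 is a *scaling convention* for
d, while the generating random-slope SD is anchored, like every other
variance component, to the published re-analysis estimates. Treating
2.00 as the generating slope SD instead makes the simulated sphericity
violation far stronger and produces small-sample test behaviour
inconsistent with the published rejection rates this package reproduces;
both readings remain one constructor argument away.

Equal group allocation (N/2 per group) is used throughout — the
power-maximizing convention when total N is fixed.

What the generator deliberately does not emulate: missing assessments
and dropout, unequal group sizes, non-linear (plateauing) recovery,
autoregressive residuals, floor effects of bounded clinical scales, and
more than two groups. Passing tests therefore speak to the balanced
complete-panel case; with real data the mixed model's tolerance of
missingness is an additional advantage the simulations do not quantify.

## The two engines

**Split-plot rANOVA** (`ranova`). Session is treated as a discrete
factor. Group is tested against subjects-within-groups on (1, N-2) df;
session and session-by-group against the subject-by-session residual on
(t-1, (N-2)(t-1)) df. Sphericity diagnostics operate on M = C S C' with
C an orthonormal contrast basis and S the *pooled within-group*
covariance of the t repeated measures (group means removed first, so a
genuine group effect cannot masquerade as non-sphericity; divisor
N - 2). Greenhouse-Geisser epsilon is tr(M)^2 / ((t-1) tr(M^2)),
clipped to [1/(t-1), 1]; the corrected p refers the same F to
F(eps*df1, eps*df2). Mauchly's W uses the standard chi-square
approximation with Box's second-order tail term, in the exact algebraic
form used by R's `mauchly.test`, so the diagnostics agree with that
reference to 1e-6. The GG-corrected p is not uniformly larger than the
uncorrected p — the two F tail areas cross near F ~ 1.2-1.5 — but in the
rejection region the correction only weakens evidence, which is the
property the power comparisons rely on.

**Linear mixed model** (`lmm`). Fixed part: intercept, group (treatment
indicator), session (continuous), group-by-session. Random part: per
subject intercept and slope with unstructured 2x2 covariance G, plus iid
residuals. Estimation is full maximum likelihood (not REML): writing
V_j = Z_j G Z_j' + sigma^2 I, beta is profiled out by GLS and sigma^2 in
closed form, leaving a criterion over D = G/sigma^2 parameterized by its
log-Cholesky factor — G is positive semidefinite by construction and
variance components may go to the boundary (the anchored defaults place
rho near -1, so boundary solutions are routine and flagged rather than
fatal). The profiled criterion is minimized by L-BFGS-B with an analytic
gradient (envelope theorem: only the W-terms differentiate) from three
deterministic starts — a moment start from per-subject OLS lines, a
near-zero-variance start, and an inflated start — keeping the best
log-likelihood. Optimizer failure is reported as `converged=False`,
never an exception. When all subjects share one session vector (every
simulated panel) the t-by-t weight matrix is assembled once per
criterion evaluation, which keeps a fit under ~20 ms; unbalanced panels
fall back to a per-subject loop.

Fixed effects are tested two ways. Wald z refers estimate/SE to a
standard normal (the infinite-df convention some packages default to).
The F alternative refers the squared statistic to F(1, df_bw) with
*between-within* denominator df: terms that vary within subject
(session, group-by-session) get n_obs - n_subjects - 2; terms constant
within subject (intercept, group) get n_subjects - 2, the containment
convention (a complete 21-subject, 6-wave panel gives the familiar
F(1, 19) for the group term). The intraclass correlation is computed
from the random-intercept-only submodel as Var(intercept) / total.

## Monte Carlo harness

Each grid cell (N, waves, d) generates `n_reps` panels; every panel is
analysed by all requested methods, so method comparisons are paired
replicate-by-replicate. d = 0 cells estimate Type-I error, d > 0 cells
power, both as the proportion of interaction p-values below alpha = 0.05
with Monte Carlo SE sqrt(r(1-r)/n). Replicates with a failed mixed-model
fit are dropped from that method's denominator only; a cell under 50%
convergence is flagged. Seeding uses `numpy.random.SeedSequence` with
the cell coordinates as spawn keys and the replicate index below that,
so any single replicate is reproducible in isolation and results do not
depend on execution order.

The default replicate count is 2000 per cell (MC SE at most 0.011);
the shipped acceptance script and the heavier tests use that size, and
the test suite drops to a few hundred replicates only for bookkeeping
checks where the rejection rate itself is not under test.

## Numerical choices and edge cases

- Log-Cholesky bounds of +-12 on the log-diagonal (variance ratios
  between ~e^-24 and e^24); hitting them is reported as a boundary flag.
- Optimizer `ftol` 1e-10 on -2 log-likelihood; invariance tests confirm
  location shifts move only the intercept and rescaling y scales
  estimates exactly, leaving p-values unchanged to 1e-8.
- t = 2 waves: epsilon is exactly 1 and Mauchly's test is vacuous
  (W = 1, p = 1, df = 0) — a single difference score has no sphericity
  to violate.
- Incomplete panels are a hard, named error for the ANOVA path
  (`IncompleteDataError` lists the offending subjects) and are accepted
  by the mixed model; the CLI `fit` command demonstrates the contrast by
  still writing the mixed-model report while replacing the ANOVA report
  with an explanatory notice.
- A constant outcome, a single distinct session, or fewer than 2
  subjects per group raise descriptive errors before any optimization.

## Known limitations

- Only two groups and linear trajectories; no REML, no Satterthwaite or
  Kenward-Roger df, no AR(1) or heteroscedastic residual structures.
- The between-within df convention is generous for slope contrasts when
  random-slope variance dominates; the simulations quantify the
  resulting (small) liberality rather than correct it, since the
  convention itself is the object of study.
- Under the anchored defaults the 6-wave sphericity violation is mild,
  so the uncorrected rANOVA's large-sample Type-I inflation, while
  present, is smaller than what stronger random-slope settings produce;
  `GeneratingModel(sd_slope=...)` exposes that axis directly.
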