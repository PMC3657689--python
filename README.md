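# rehabpower

Power and Type-I-error analysis of the two standard ways to test a
treatment effect in two-group longitudinal rehabilitation studies:
mixed between-within repeated-measures ANOVA (rANOVA, with and without
the Greenhouse–Geisser correction) versus a linear mixed model (MLM)
with random intercepts and slopes, tested by Wald *z* or by *F* with
between-within denominator degrees of freedom.

The motivating setting is post-stroke spatial-neglect rehabilitation,
where severity scores (lower = better) are tracked over repeated
assessment sessions and patients differ widely both in baseline
severity and in recovery rate — with the two strongly negatively
correlated. The package is aimed at rehabilitation researchers planning
such studies (how many patients, how many waves, which test?) and at
methodologists who want the two analysis engines and the Monte Carlo
harness as importable, tested building blocks.

## Model

Each subject *j* in group *g* follows a linear recovery trajectory over
sessions *s* = 0, 1, …, *t*−1:

    Y_ij = (b0 + b0j) + (b1_g + b1j) · s_i + e_ij

with (b0j, b1j) ~ N(0, G) bivariate normal (unstructured G, correlation
ρ), e_ij ~ N(0, σ²) iid. The effect size *d* is the difference between
group slopes in units of a conventional slope SD of 2.00 (d = 0.20 →
treatment slope −0.40, …, d = 1.00 → −2.00). Default variance
components (intercept SD 8.42, slope SD 0.927, ρ = −0.93, residual SD
2.56) are anchored to published mixed-model estimates from a
prism-adaptation neglect panel; see `docs/methods.md`.

Both analysis engines are implemented from first principles and are
verified in the test suite against statsmodels `MixedLM`, pingouin's
mixed ANOVA, and R's `car`/`mauchly.test`. The MLM is fitted by full
maximum likelihood with β and σ² profiled out and the random-effects
covariance optimized on a log-Cholesky scale with an analytic gradient.

## Worked example

```python
from rehabpower import run_cell

for cell in run_cell(N=20, waves=3, d=0.5, n_reps=500, master_seed=123):
    print(f"{cell.method:<10} rejection rate {cell.rejection_rate:.3f}"
          f" +- {2 * cell.mc_se:.3f}")
```

prints

```
rANOVA     rejection rate 0.184 +- 0.035
GG-rANOVA  rejection rate 0.172 +- 0.034
MLM-z      rejection rate 0.250 +- 0.039
MLM-F      rejection rate 0.236 +- 0.038
```

— the power of each interaction test at α = 0.05 for a 3-wave study
with 10 subjects per group and a moderate effect (d = 0.5): the mixed
model buys roughly six percentage points of power over the ANOVA here,
and the GG correction costs the ANOVA a little more. With `d=0` the
same call estimates Type-I error instead (all four rates should sit
near 0.05, Wald *z* the most liberal).

The `examples/` directory holds short narrative scripts: one panel
fitted both ways (`01`), a single power cell (`02`), a reduced power
grid with plots (`03`), and the missing-data contrast — the ANOVA
refuses an incomplete panel while the MLM still fits it (`04`).

A thin CLI wraps the same functions:

```
rehabpower simulate --n-per-group 10 --waves 3 --effect 0.5 --seed 1 --out panel.csv
rehabpower fit --data panel.csv --out reports/
rehabpower power-grid --config grid.yaml --out results.csv --plots figures/
```

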