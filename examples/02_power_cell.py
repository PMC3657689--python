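"""Estimate power and Type-I error for one design cell.

Runs 500 Monte Carlo replicates of a 3-wave study with 10 subjects per
group, once under a moderate effect (d = 0.5) and once under the null,
comparing all four interaction tests on the same replicates.
"""

from rehabpower import run_cell

for d, label in [(0.5, "power (d = 0.5)"), (0.0, "Type-I error (d = 0)")]:
    print(f"\n{label}, N = 20 total, 3 waves, 500 replicates:")
    for cell in run_cell(N=20, waves=3, d=d, n_reps=500, master_seed=123):
        print(
            f"  {cell.method:<10} rejection rate {cell.rejection_rate:.3f}"
            f" +- {2 * cell.mc_se:.3f} ({cell.n_converged} converged)"
        )
# Under the effect, the mixed-model tests reject more often than the
# (GG-corrected) ANOVA; under the null all rates should sit near 0.05,
# with Wald z the most liberal and the GG correction the most conservative.
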