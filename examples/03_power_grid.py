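"""Sweep a small power grid and plot the resulting curves.

A reduced version of the full factorial study (two sample sizes, one
wave count, three effect sizes, 300 replicates) that finishes in about a
minute; the full grid is the GridSpec defaults.
"""

from rehabpower import GridSpec, run_grid
from rehabpower.simulation import plot_power_curves

spec = GridSpec(
    sample_sizes=(6, 20),
    waves=(3,),
    effects=(0.0, 0.5, 1.0),
    n_reps=300,
    master_seed=42,
)
results = run_grid(spec)
print(results.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
written = plot_power_curves(results, "scratch/power_curves")
print(f"\nwrote {len(written)} figures under scratch/power_curves/")
# Each d > 0 row is power, each d = 0 row Type-I error; mc_se is the
# binomial Monte Carlo standard error of the rejection rate.
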