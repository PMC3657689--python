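"""Why the mixed model suits patient panels: tolerance of missing cells.

Deletes two assessments from a complete panel; the ANOVA path refuses
(it needs complete data), while the mixed model still fits and tests the
interaction.
"""

from rehabpower import (
    EffectSpec,
    StudyDesign,
    fit_lmm,
    make_generating_model,
    simulate_dataset,
    to_wide,
    wald_f,
)
from rehabpower.ranova import IncompleteDataError

data = simulate_dataset(
    StudyDesign(n_per_group=8, n_waves=4), make_generating_model(EffectSpec(0.8)),
    seed=5,
)
gappy = data.drop(data.index[[5, 18]])  # two missed assessments

try:
    to_wide(gappy)
except IncompleteDataError as err:
    print(f"rANOVA refuses the panel: {err}")

fit = fit_lmm(gappy)
test = wald_f(fit, "group:session")
print(
    f"mixed model still fits ({fit.n_obs} obs, {fit.n_subjects} subjects): "
    f"interaction b = {test.estimate:.3f}, F(1, {int(test.df_den)}) = "
    f"{test.statistic:.2f}, p = {test.p:.4f}"
)
# The two subjects with missing cells contribute their remaining
# observations instead of being dropped wholesale.
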