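"""Detect module-specific plasticity with mixed-effects contrasts.

Simulates a crossover cohort (two training cohorts completing the same
three modules in different orders, plus untrained retest controls) with
an eccentricity increase of 0.2 planted in 20 of 100 parcels for the
attention-based module (Presence) only. The per-parcel mixed model
delta ~ 1 + age + sex + interval_index + TM + (1 | subject) then
contrasts Presence against the socio-cognitive module (Perspective), and
BH-FDR controls discoveries across parcels.
"""

import numpy as np

from gradplast import change_maps, fit_contrast
from gradplast.synthetic import EffectSpec, make_cohort

n_parcels = 100
effect = np.zeros(n_parcels)
effect[:20] = 0.2  # planted Presence-specific eccentricity increase

spec = EffectSpec(
    effect_maps={"Presence": effect, "Affect": np.zeros(n_parcels),
                 "Perspective": np.zeros(n_parcels)},
    subject_sd=0.1, residual_sd=0.3,
)
design, maps = make_cohort(80, 80, 80, spec, n_parcels=n_parcels, seed=3)
changes = change_maps(maps, design)
result = fit_contrast(changes, ("Presence", "Perspective"))

discovered = result.q < 0.05
print(f"contrast {result.description}: df = {result.df}")
print(f"FDR q<0.05 discoveries: {discovered.sum()} "
      f"({discovered[:20].sum()} of 20 planted, "
      f"{discovered[20:].sum()} false)")
print(f"mean estimated effect in planted parcels: {result.estimate[:20].mean():.3f} "
      f"(planted 0.2)")
print(f"largest effect size d = {result.d.max():.3f} at parcel {int(result.d.argmax())}")
# The contrast recovers the planted parcels while false discoveries stay
# controlled at the 5% FDR level.
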