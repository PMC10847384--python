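"""Coupled-ODE mixed models with a moderator, on a cohort with known truth.

Simulates a latent cohort in which behavior density drives physiology change
(coupling c = -0.0015 /s per density unit) and physiology drives behavior
change (f = 0.03), with a level-2 moderator weakening c by -0.001 per SD.
Fits the two mixed models of the pair, then probes the interaction at the
moderator mean and +/-1 SD.
"""

import warnings

warnings.filterwarnings("ignore")

from hrvdyn import PAIRS, TrueParams, fit_pair, probe_interaction, simulate_cohort
from hrvdyn.mlm import build_design, records_from_cohort, standardize

params = TrueParams(n_subjects=60, mod_effects={"c": -0.001})
cohort = simulate_cohort(params, seed=3)

design = build_design(records_from_cohort(cohort), PAIRS[0])
mods = cohort.moderator_frame()
mods["z_z"] = standardize(mods["z"])
design = design.merge(mods[["subject", "z_z"]], on="subject")

fit = fit_pair(design, PAIRS[0], moderator="z_z", include_task_total=False)
print(f"pair {fit.pair.label}: {fit.n_obs} rows, {fit.n_subjects} subjects")
print("\nphysiology equation (dIBI/dt):")
print(fit.phys_eq.params.round(5))
print(f"\ngenerating values: c = {params.c0}, interaction = -0.001")

print("\nsimple slopes of the behavior->physiology coupling:")
for s in probe_interaction(fit, "c"):
    print(f"  moderator at {s.level:+.0f} SD: slope {s.slope:+.5f} "
          f"(SE {s.se:.5f}, p = {s.p:.3f})")
print("the negative interaction strengthens the coupling at higher moderator")
print("levels: behavior raises cardiac arousal mainly for high-moderator")
print("subjects, and the +1 SD slope is the most negative.")
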