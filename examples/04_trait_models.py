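"""Link blood isotopes to breeding traits with within-individual centering.

Traits (body mass, clutch initiation date, total clutch mass) and
red-blood-cell isotopes are z-standardized within year, the isotope
covariate is split into within- and among-individual parts, and null vs
within+between mixed models are compared.  A significant between effect
would mean individually specialized foraging (consistently different
isotope values) predicts a bird's typical trait value.
"""

import dataclasses

from isoniche import SyntheticConfig, build_trait_model_set, generate_dataset

# among-individual link only: birds with higher average d15N are heavier
link = dataclasses.replace(SyntheticConfig().trait_link, beta_between=0.8)
cfg = SyntheticConfig(seed=4, trait_link=link, trait_sigma2_individual=0.1)
ds, _ = generate_dataset(cfg)

table, gate, lost = build_trait_model_set(ds, "body_mass", "d15N")
print(table.table.round(3).to_string(index=False))
print(f"\nwithin-individual effect p = {gate.within_p:.3g} "
      f"(slopes evaluated: {gate.slopes_evaluated})")
print(
    "\nThe within+between model beating the null here reflects the simulated"
    "\namong-individual link (beta_between = 0.8) between typical d15N and"
    "\nbody mass; the within (year-to-year plasticity) effect stays null."
)
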