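"""Among-year repeatability of isotope values within individual birds.

Repeatability (intraclass correlation) R = sigma2_ind / (sigma2_ind +
sigma2_res) is estimated by REML from the intercept-only mixed model with
bird identity as the sole random factor.  The standard error comes from a
parametric bootstrap and the p-value from a boundary-corrected
likelihood-ratio test of sigma2_ind = 0.
"""

from isoniche import SyntheticConfig, generate_dataset, repeatability

ds, _ = generate_dataset(SyntheticConfig(seed=2))

for tissue in ("red_blood_cell", "feather"):
    for isotope in ("d15N", "d13C"):
        obs = ds.tissue_samples(tissue)
        res = repeatability(obs, response=isotope, grouping="individual_id",
                            n_boot=300, seed=7)
        print(f"{tissue:15s} {isotope}:  R = {res.r:.3f} +/- {res.se:.3f}  "
              f"p = {res.p_value:.4g}")

print(
    "\nWith sigma2_individual = 0.5 against 0.6 of year+residual variance,"
    "\nthe true repeatability is near 0.45; significant p-values reflect"
    "\nconsistent among-individual differences across years."
)
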