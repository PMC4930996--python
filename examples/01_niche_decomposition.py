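"""Decompose the isotopic niche of a simulated penguin population.

Generates one synthetic multi-year dataset at the default study design
(30 females, 7 sampled years) and splits the total niche width (TNW) of
each tissue x isotope into its within-individual (WIC) and among-individual
(AIC) components.  WIC/TNW near 1 means a population of generalist
individuals; values well below 1 mean individually specialized birds.
"""

from isoniche import SyntheticConfig, decompose, generate_dataset, niche_table

cfg = SyntheticConfig(seed=1, sigma2_individual=0.5, sigma2_year=0.3, sigma2_residual=0.3)
ds, _ = generate_dataset(cfg)

decomps = [
    decompose(ds, tissue, isotope)
    for tissue in ("red_blood_cell", "feather")
    for isotope in ("d15N", "d13C")
]
print(niche_table(decomps))
print(
    "\nEach column is one tissue x isotope (variances in permil^2)."
    "\nWith sigma2_individual comparable to the within-individual variance,"
    "\nthe WIC/TNW ratio sits well below the generalist limit of 1."
)
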