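"""Stage-1 trial models: variance components, heritability and BLUPs.

Fits the within- and across-environment random-effects models by REML on
two simulated traits, prints the heritability tables, and the trait
correlation/PCA summaries computed from the genotype BLUPs.
"""

import pandas as pd

from megblup import (
    PhenotypeTable,
    fit_across_env,
    fit_within_env,
    get_preset,
    heritability_across,
    heritability_within,
    simulate_trial,
    trait_correlations,
    trait_pca,
)

# two traits measured on the same genotyped panel, each with its own
# (independent) genetic architecture
from megblup import simulate_genotypes, simulate_phenotypes  # noqa: E402

cfg_dthd = get_preset("wheat-dthd", seed=3, n_markers=1500, n_qtl=150)
cfg_daysmt = get_preset("wheat-daysmt", seed=5, n_markers=1500, n_qtl=150)
genotypes = simulate_genotypes(cfg_dthd)
tables = [
    simulate_phenotypes(genotypes, cfg_dthd)[0].data,
    simulate_phenotypes(genotypes, cfg_daysmt)[0].data,
]
table = PhenotypeTable(pd.concat(tables, ignore_index=True))

print("within-environment heritability:")
for trait in table.traits:
    for env in table.environments:
        fit = fit_within_env(table, env, trait)
        v = fit.components
        print(f"  {trait} {env}: H2={heritability_within(v):.2f} "
              f"(sigma2_g={v.sigma2_g:.2f}, sigma2_e={v.sigma2_e:.2f})")

fits = {}
print("across-environment heritability:")
for trait in table.traits:
    fit = fit_across_env(table, trait)
    fits[trait] = fit
    v = fit.components
    print(f"  {trait}: H2={heritability_across(v):.2f} "
          f"(sigma2_g={v.sigma2_g:.2f}, sigma2_ge={v.sigma2_ge:.2f}, "
          f"sigma2_e={v.sigma2_e:.2f})")

corr = trait_correlations(fits, table)
print("genetic (BLUP-BLUP) correlations (independent architectures -> ~0):")
print(corr.genetic.round(2).to_string())

pca = trait_pca(pd.DataFrame({t: f.blups for t, f in fits.items()}))
print("PCA of the BLUP matrix, explained variance (%):")
print(pca.explained_pct.round(1).to_string())
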