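"""Simulate a multi-environment wheat trial with known variance components.

Builds a small truth-known trial (100 lines, 1,000 SNPs, 4 environments,
2 replicates), prints its realized heritabilities, and writes the plain
text inputs a downstream analysis would read.
"""

from pathlib import Path

from megblup import get_preset, simulate_trial
from megblup.pipeline import cmd_simulate

config = get_preset("small-test", seed=1)
genotypes, phenotypes, truth = simulate_trial(config)

print(f"trial: {genotypes.n_lines} lines x {genotypes.n_markers} markers, "
      f"{config.n_environments} environments x {config.n_reps} reps")
print(f"true components: var_g={config.var_g}, var_ge={config.var_ge}, "
      f"var_e={config.var_e}")
print("realized within-environment H2 (from the drawn effects):")
print(truth.realized_h2_within.round(3).to_string())
print(f"realized across-environment H2: {truth.realized_h2_across:.3f}")

# H2 within one environment mixes main-genetic and G-by-E variance:
# (var_g + var_ge) / (var_g + var_ge + var_e / nReps); across environments
# the interaction and residual are averaged away over 4 envs x 2 reps.

out = Path("scratch/example_trial")
paths = cmd_simulate(config, out)
print(f"inputs written to {out}/ ({', '.join(p.name for p in paths.values())})")
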