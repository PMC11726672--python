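"""Aqueous conformer abundances from a quantum-chemistry energy table.

Generates a synthetic conformer table (with planted duplicates and a
planted basis-set-limit model), then runs the full analysis funnel:
uniqueness screening -> CBS extrapolation -> RRHO corrections at
310.15 K with 0.971 frequency scaling -> Boltzmann populations.
"""

import numpy as np

from confensemble import (
    boltzmann_populations,
    dedup,
    ensemble_free_energies,
    gen_conformer_ensemble,
)

table, truth = gen_conformer_ensemble(
    seed=42, n_unique=5, n_dup_per_group=3,
    dg_spectrum=[0.0, 0.4, 1.1, 1.8, 2.6],
)
print(f"raw ensemble: {len(table)} conformer records")

unique, dup_map = dedup(table)  # constants within 1% AND energy within 0.1 kcal/mol
print(f"after uniqueness screen: {len(unique)} unique ({len(dup_map)} duplicates removed)")

g = ensemble_free_energies(unique, temperature=310.15, scale=0.971)
pops = boltzmann_populations(
    dict(zip(g["conformer_id"], g["g_total_kcal"])), temperature=310.15
)
print("\nconformer   dG (kcal/mol)   population")
for _, row in pops.table.iterrows():
    print(f"{row['conformer_id']:<12s} {row['delta_g_kcal']:>8.3f}      "
          f"{100 * row['population']:6.2f}%")
print("\nplanted populations:",
      " ".join(f"{100 * p:.2f}%" for p in truth["populations"]))
# dG is each conformer's Gibbs free energy above the global minimum; the
# population is its expected equilibrium abundance in aqueous solution
# at physiological temperature (Boltzmann-weighted).
np.testing.assert_allclose(
    pops.populations, truth["populations"], atol=1e-6
)
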