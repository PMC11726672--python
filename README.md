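# confensemble

Post-processing toolkit for ligand conformer ensembles and receptor
structure ensembles, built for computational chemists studying how
flexible drug-like ligands (opioids such as fentanyl, naltrexone, and
BU72 are the motivating case) behave in aqueous solution and how their
receptor — the μ-opioid receptor, a class A GPCR — moves between
inactive and active states.

Electronic-structure programs produce the raw numbers (electronic
energies at several basis-set levels, harmonic frequencies, rotational
constants); experimental structures come from the PDB. `confensemble`
turns those inputs into the quantities people actually argue about:

* **Conformer uniqueness screening** — two conformers are duplicates
  when all three rotational constants agree within 1 % *and* their
  energies agree within 0.1 kcal·mol⁻¹; screening is greedy in
  ascending energy so each group keeps its lowest-energy member.
* **RRHO thermochemistry** — ideal-gas rigid-rotor/harmonic-oscillator
  corrections H_corr, S_corr, G_corr at a chosen temperature (default
  310.15 K) with a uniform frequency scale factor (default 0.971).
* **CBS extrapolation** — the two-term inverse-polynomial form
  E(n) = E_CBS + A·n⁻⁴ + B·n⁻⁵ solved exactly through the
  double/triple/quadruple-ζ cardinal numbers n = 2, 3, 4.
* **Boltzmann populations** — p_i = exp(−ΔG°_i/RT) / Σ_j exp(−ΔG°_j/RT),
  with R = 1.9872041×10⁻³ kcal·mol⁻¹·K⁻¹.
* **Thermodynamic-cycle pKa** — ΔG_aq = ΔG_gas + ΔΔG_sol over the
  proton cycle HA⁺ → A + H⁺, then pKa = ΔG_aq/(RT ln 10); the proton
  uses experimental references ΔG_sol(H⁺) = −265.6 kcal·mol⁻¹ and
  G_gas(H⁺) = −6.28 kcal·mol⁻¹ (the latter reproducible from
  H = 5/2·RT with Sackur–Tetrode entropy).
* **Superposition & RMSD** — Kabsch least-squares alignment,
  RMSD = √(1/N Σ_i |x_i − x′_i|²), per-transmembrane-helix reports
  after a single conserved-core fit (TM ranges in hMOR numbering ship
  as a JSON config; mouse structures are renumbered by +2), and
  permutation-optimal heavy-atom RMSD for ligand conformers
  (Hungarian assignment per element alternated with refits).
* **Ensemble PCA** — sequence-aligned, gap-free Cα coordinate tensors,
  iterative invariant-core detection, complete-linkage clustering on
  pairwise RMSD, and eigen-decomposition of the 3P×3P Cartesian
  covariance: eigenvalue fractions are the variance proportions, and
  eigenvectors are collective displacement modes exportable as
  trajectories.
* **Synthetic data** — every stage has a generator that plants the
  truth (duplicate groups, CBS limits, ΔG° spectra, displacement
  modes, group offsets, target pKa), so the whole pipeline is testable
  offline.

## Worked example

```bash
python examples/conformer_populations.py
```

```
raw ensemble: 15 conformer records
after uniqueness screen: 5 unique (10 duplicates removed)

conformer   dG (kcal/mol)   population
conf001         0.000       56.85%
conf002         0.400       29.71%
conf003         1.100        9.54%
conf004         1.800        3.06%
conf005         2.600        0.84%

planted populations: 56.85% 29.71% 9.54% 3.06% 0.84%
```

Fifteen synthetic conformer records (five unique, each with two
planted near-duplicates) are screened down to five; CBS extrapolation
plus RRHO corrections at 310.15 K give each survivor a Gibbs free
energy, and the Boltzmann weights say the lowest conformer accounts
for ~57 % of the aqueous population — matching the planted spectrum to
six decimals. The other scripts in `examples/` walk through the pKa
cycle, per-helix RMSD of an activation-like TM6 displacement,
permutation-optimal ligand RMSD, and the ensemble clustering/PCA
workflow.

The command-line interface wires the same stages together for shell
use (`confensemble --help`; subcommands `dedup`, `thermo`, `cbs`,
`boltz`, `pka`, `rmsd`, `helices`, `pca`, `simulate`). Users with
network access can materialize the experimental receptor ensemble with
`python scripts/fetch_structures.py --out-dir structures/` and feed
the resulting manifest to `confensemble pca`; the library itself never
downloads anything.

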