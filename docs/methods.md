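# Methods

This note records the models implemented in `confensemble`, the
defaults and why they were chosen, the numerical conventions, and what
the synthetic-data tests do and do not demonstrate.

## Units and constants

Coordinates are Å; electronic energies hartree; thermal corrections
and free energies kcal·mol⁻¹; entropies cal·mol⁻¹·K⁻¹; frequencies
cm⁻¹; rotational constants GHz; masses u. All thermochemistry flows
through constants pinned in `confensemble.constants` (SI defining
constants plus CODATA 2018 for the atomic mass unit), with
1 hartree = 627.5095 kcal·mol⁻¹ and
R = 1.9872041×10⁻³ kcal·mol⁻¹·K⁻¹, so results are identical across
environments regardless of the numerics stack's CODATA revision.

## Conformer uniqueness screening

Two conformers are considered the same structure when their three
size-sorted rotational constants agree within a relative tolerance
(default 1 %) **and** their comparison energies agree within an
absolute tolerance (default 0.1 kcal·mol⁻¹). The conjunction matters:
an OR rule would merge genuinely different conformers that happen to
be isoenergetic. Because pairwise similarity is not transitive, the
screen is greedy: records are processed in ascending energy and each
is compared against the already-kept representatives, so every
duplicate group is represented by its lowest-energy member. The
comparison energy defaults to the best level present per record
(DFT > QZ > TZ > DZ) and can be pinned to a column, since screening is
meaningful both after semiempirical sampling and after DFT refinement.

## RRHO thermochemistry

`rrho_corrections` implements the standard ideal-gas
rigid-rotor/harmonic-oscillator partition-function expressions:
translational enthalpy 5/2·RT with Sackur–Tetrode entropy; rotational
RT (linear) or 3/2·RT (nonlinear) with the classical rotational
partition function built from the rotational constants, symmetry
number fixed at 1; and a harmonic-oscillator sum over modes giving the
zero-point energy, thermal vibrational energy, and vibrational
entropy. H_corr includes the pV term (+RT); G_corr = H_corr − T·S.
Defaults: T = 310.15 K (physiological), p = 1 atm, frequency scale
factor 0.971 applied to **every** vibrational wavenumber before both
the zero-point and thermal terms (scaling only the ZPE is a defensible
alternative; a single uniform treatment was chosen and is controlled
by one parameter). Imaginary (negative-tagged) frequencies abort by
default — a transition state is not a conformer — with an explicit
opt-in to drop them with a logged warning. No quasi-harmonic damping
of low-frequency modes is applied; low-frequency torsions therefore
carry the usual harmonic-entropy exaggeration, which largely cancels
in relative ΔG between conformers of the same molecule.

Rotational constants, when absent from input tables, are computed from
the geometry via the center-of-mass inertia tensor, B = h/(8π²I). A
moment below 10⁻⁶ u·Å² is treated as zero and its constant reported as
infinite (linear molecule); single atoms have no rotational constants.

## CBS extrapolation

The basis-set series at cardinal numbers n = 2, 3, 4 is fitted with
E(n) = E_CBS + A·n⁻⁴ + B·n⁻⁵ — an exactly determined 3×3 linear solve,
so the planted-model recovery and the ≤10⁻¹⁰ hartree residual checked
in the tests are algebraic identities, not fit quality. The exponent
pair (4, 5) and an optional cardinal offset are keyword-configurable
because inverse-polynomial schemes appear in the literature both with
plain and half-integer-shifted cardinal numbers; the plain form is the
default. Total Gibbs energies are assembled as
G = 627.5095·E_CBS + G_corr, mixing the coupled-cluster electronic
energy with the DFT-level thermal correction.

## Boltzmann populations

p_i = exp(−ΔG°_i/RT)/Σ_j exp(−ΔG°_j/RT) with ΔG° relative to the
ensemble minimum — so the weights are invariant to any uniform shift
of the free energies, populations sum to one by construction, and
population order is the reverse of ΔG° order (ties allowed for
degenerate conformers).

## Thermodynamic-cycle pKa

The cycle decomposes HA⁺ → A + H⁺ into a gas-phase leg and three
solvation legs and assumes the caller's component free energies were
computed on solution-phase geometries (the cycle's "method 2"; the
package adds no geometry bookkeeping of its own). The proton
references default to ΔG_sol(H⁺) = −265.6 kcal·mol⁻¹ and
G_gas(H⁺) = −6.28 kcal·mol⁻¹; both are configuration, not constants —
the gas-phase value in particular circulates with either sign
convention, so the magnitude is what the package asserts and the sign
is overridable. `proton_gas_free_energy` reproduces the tabulated
magnitude analytically (H = 5/2·RT, Sackur–Tetrode S) **at the 1 bar
thermodynamic standard state**: at 298.15 K it gives −6.282 (|G| →
6.28 at two decimals), whereas a 1 atm state gives −6.274; the 1 bar
default matches the tabulated reference value, and the pressure is an
explicit argument. The Sackur–Tetrode implementation is validated
against the textbook argon entropy (154.85 J·mol⁻¹·K⁻¹ at 298.15 K,
1 bar). No 1 atm → 1 M standard-state correction is added to ΔG_aq
unless explicitly enabled (`standard_state_correction=True`, adding
RT·ln(R′T) ≈ 1.89 kcal·mol⁻¹ at 298 K for the net mole of gas created)
— component conventions differ between solvation datasets, so the
correction is the caller's decision. Default temperature 310.15 K.

## Superposition and RMSD

Kabsch superposition is solved by SVD of the covariance of the
centered paired coordinates with a determinant correction enforcing a
proper rotation; it requires at least three non-collinear pairs
(collinearity detected by a rank check at tolerance 10⁻⁸). The tests
cross-check it against an independent closed-form quaternion
(Horn-type) solution.

Receptor comparisons pair atoms on (residue number, atom name) after
any renumbering (`renumber_offset`; the mouse receptor needs +2 to
match human numbering). Backbone means {N, CA, C, O}. Unmatched
residues or atoms (unresolved loops are routine in experimental GPCR
structures) are silently dropped from the pairing and logged with
counts. Per-helix reports use fit-then-measure semantics by default:
one rigid fit on the conserved region (66–349), then per-region RMSD
in that common frame, so a helix that swings relative to the core
shows a large residual; `per_region_fit=True` refits inside each
region instead. The TM range map (hMOR numbering) ships as both a code
default and a JSON config users can override.

Ligand heavy-atom RMSD minimizes over like-element atom relabellings:
Hungarian assignment per element with squared-distance cost alternated
with a Kabsch refit until the assignment stabilizes (≤50 rounds),
started from the input order and from principal-axes pre-alignments
under the four proper axis flips, keeping the best converged minimum.
Multi-start matters because the alternation from a single pose can
stall in a local minimum; the tests verify agreement with exhaustive
per-element permutation enumeration on 6-heavy-atom molecules. The
alternation is a heuristic: global optimality is not guaranteed for
large, highly symmetric molecules, only strongly encouraged by the
flip starts.

## Ensemble alignment, invariant core, clustering, PCA

Chains are mapped to common positions by progressive pairwise global
sequence alignment against the first chain (match +1, mismatch 0,
gap −1) — adequate at the ≥94 % identities of a single-receptor
ensemble and deliberately not a general multiple-alignment; columns
gapped in any chain are removed, so the coordinate tensor is gap-free
by construction.

The invariant core is found iteratively: superimpose all structures on
the current core (first structure as the initial reference, ensemble
mean thereafter), compute each position's scatter-ellipsoid volume
(4/3·π·√(λ₁λ₂λ₃) of the per-position 3×3 covariance eigenvalues), drop
the worst position, and stop when the largest core volume is below the
cutoff or a floor is reached. Defaults — volume cutoff 0.5 Å³,
minimum core 30 positions — are this package's documented choices;
ties drop the lowest index, making the procedure fully deterministic.

Pairwise Cα RMSD is measured in the common superposed frame (no
per-pair refit by default, so the distance matrix is consistent with
the PCA frame); agglomerative clustering uses complete linkage by
default (configurable — the linkage is a genuine free choice) and the
tree is cut at the requested group count, with labels renumbered by
first appearance and exportable as Newick.

PCA eigen-decomposes the (3P×3P) covariance of the flattened Cα
coordinate vector across structures. All 3P eigenvalues are reported
(an ensemble of S structures has at most S−1 nonzero ones); variance
proportions are eigenvalue fractions; a zero-variance ensemble is
flagged degenerate with zero proportions rather than NaNs; mode signs
are fixed by making each mode's largest-magnitude loading positive.
The PCA atom set is Cα only — a P-position ensemble yields exactly 3P
eigenvalues, which for the 12-chain receptor set (276 gap-free
positions) is the expected 828. Mode trajectories interpolate
mean ± amplitude along a chosen eigenvector for visualization.

## Synthetic generators and what the tests show

The generators are pure functions of their arguments (same seed ⇒
byte-identical output) and write planted-truth JSON sidecars.

* **Conformer ensembles**: group-head rotational constants sit on a
  multiplicative grid ≥3 % apart so distinct conformers can never
  merge; duplicates jitter constants by ≤0.5 % and energies by
  +0.01…+0.045 kcal·mol⁻¹ (strictly positive, so the head stays the
  group minimum) — inside the screening tolerances by construction.
  DZ/TZ/QZ energies follow the planted inverse-polynomial model
  exactly, with the limit chosen so total Gibbs energies realize a
  requested ΔG° spectrum; default 24 modes in 80–3400 cm⁻¹ and mass
  336.47 u emulate a drug-like ligand.
* **Structure ensembles**: template is an ideal α-helix-like Cα trace;
  planted modes are random orthonormal centered displacement
  directions with variances default 4:1 Å²; optional per-group rigid
  sub-domain shifts (last quarter of positions) emulate an
  activation-like split; isotropic Gaussian noise (default 0.05 Å) and
  random rigid motions exercise the superposition. With noise σ the
  population eigen-spectrum is (mode variance + σ²) on each planted
  mode plus a σ² floor on the remaining ~3P−6 non-rigid degrees of
  freedom, so the truth sidecar carries both the mode-only fractions
  and the full-model expected PCA fractions; recovery is checked
  against the latter (and against the mode-only fractions in a
  low-noise setting where the floor is negligible).
* **pKa cycles**: component energies are sampled at chemically
  plausible magnitudes, then one solvation term is adjusted so
  ΔG_aq = target·RT·ln10 exactly.

Passing these tests demonstrates that the estimators are correct on
data satisfying their own assumptions — exact arithmetic, planted
low-rank structure, isotropic noise. It does **not** demonstrate
accuracy on real chemistry: real conformer energies carry method error
far larger than the screening tolerances, real receptor ensembles have
anisotropic, position-dependent uncertainty, unresolved loops, and
alternate conformations, and real pKa accuracy is dominated by the
quality of the quantum-chemical component energies (1.36 kcal·mol⁻¹ of
free-energy error is a full pKa unit at 298 K).

## Problem sizes

Default test and example sizes — ensembles of 5–8 unique conformers
with 2–4 duplicates each, structure ensembles of 12–50 chains at 25–60
Cα positions, 6–8 heavy atoms for exhaustive permutation checks — were
chosen so every planted effect is overwhelmingly resolved (group
separations of 25σ, mode variances 400× the noise floor) while the
full suite runs in seconds.

## Known limitations

* PDB input is the classic format only (first model, blank/'A'
  altlocs, insertion codes rejected); no mmCIF.
* Pairing across structures is by residue number / sequence alignment,
  not structural alignment: it assumes a consistent numbering
  convention after the documented offsets.
* The RRHO model has no anharmonic or hindered-rotor treatment and a
  fixed symmetry number of 1.
* The permutation-optimal RMSD is heuristic beyond exhaustively
  checkable sizes (see above).
* The invariant-core and clustering defaults are sensible for
  single-receptor ensembles but are not tuned to reproduce any
  specific published core selection; variance proportions on real
  ensembles depend measurably on the core chosen.
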