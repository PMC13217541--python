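# Methods

## Scope and protocol

abfekit implements a desk-scale, single-trajectory MM/GBSA pipeline: a
structure-quality triage stage, molecular-mechanics interaction energies,
generalized-Born + SASA implicit solvation, snapshot-scheduled trajectory
averaging with replica SEM, trajectory stability checks, and the
correlation statistics used to validate parameter choices.  The MD engine
itself is out of scope: trajectories are consumed (multi-model PDB) or
emulated by the fixture generators.  Configurational entropy estimators,
Poisson–Boltzmann solvers, 3D-RISM and variable-dielectric GB models are
deliberately not implemented; the toolkit targets the single fixed
parameterization that such large-scale campaigns need.

## Energy model

Per snapshot, ΔG_bind = ΔE_internal + ΔE_elec + ΔE_vdW + ΔG_p + ΔG_np with
Δ the complex-minus-species difference.  All energies are kcal/mol
internally; reports carry a ×4.184 conversion to kJ/mol.  Coordinates are
Å throughout.

**Nonbonded terms.** Coulomb k_e q_i q_j/(ε_in r_ij) with
k_e = 332.0636 kcal·Å·mol⁻¹·e⁻², and 12-6 Lennard-Jones with
Lorentz–Berthelot combination.  No cutoff and no periodicity: the terms
act on isolated solute snapshots, which is standard end-point practice.
Bonded exclusions are the caller's responsibility via the explicit pair
set; the binding ΔG only ever evaluates receptor×ligand cross pairs, for
which no exclusions arise.  The 1/ε_in scaling of the vacuum Coulomb term
is a deliberate pairing with the GB prefactor below; a solute dielectric
of 1 recovers the unscaled sum.

**Polar solvation.** Generalized Born in the OBC-II parameterization:
pairwise HCT descreening integrals I_i over neighbor spheres with scaled
reduced radii, Ψ = I_i ρ̃_i, ρ̃_i = ρ_i − 0.09 Å, and

    a_i⁻¹ = ρ̃_i⁻¹ − ρ_i⁻¹ · tanh(αΨ − βΨ² + γΨ³),  (α, β, γ) = (1.0, 0.8, 4.85)

    G_p = −(k_e/2)(1/ε_in − 1/ε_w) Σ_{i,j} q_i q_j / f_GB,
    f_GB = sqrt(r² + a_i a_j e^{−r²/(4 a_i a_j)}),  f_GB(i,i) = a_i.

The prefactor is generalized from the textbook −½(1 − 1/ε_w) to
(1/ε_in − 1/ε_w) so that solute dielectric constants above one are
meaningful; at ε_in = 1 it reduces exactly to the textbook form.  This
prefactor placement (together with the 1/ε_in Coulomb scaling) is the one
genuine theory-gap decision in the package and is surfaced in the
configuration rather than hidden.  The HCT pair term is the closed-form
integral of 1/x⁴ over the scaled neighbor sphere restricted outside the
self sphere, including the engulfed-atom correction; the test suite checks
it against adaptive quadrature of the same integral to 1e−10.

**Nonpolar solvation.** ΔG_np = γ·SASA + b with defaults
γ = 0.0072 kcal/mol/Å², b = 0 — the common GB/SA surface-tension default,
configurable because published campaigns rarely print their (γ, b).  SASA
is Shrake–Rupley on spheres expanded by a 1.4 Å probe, sampled with a
deterministic Fibonacci (golden-angle) lattice of 960 points per atom —
no RNG, so results are bit-reproducible; an isolated sphere is exact at
any point count, and 960 vs 3840 points differ by <0.5% on the fixtures.

**Defaults and radii.** ε_in = 3 and ε_w = 80, the combination that
validated best for this protocol family; intrinsic radii default to a
small element table (H 1.2, C 1.7, N 1.55, O 1.5, S 1.8 Å; fallback
1.5 Å) with per-element descreening scales (H 0.85, C 0.72, N 0.79,
O 0.85, S 0.96; fallback 0.80) when the parameter file omits them.  All
of these are configuration fields, not constants.

## Protocol assembly

Under the single-trajectory protocol the receptor and ligand species are
coordinate slices of the complex frame, so bonded (internal) terms cancel
identically and ΔE_internal is reported as exactly 0.  Born radii and SASA
are recomputed per species in isolation — atoms outside a selection
neither descreen nor bury it.  No Boltzmann reweighting is applied between
the simulation and post-processing Hamiltonians.

Snapshot schedules are index-based and include frame 0: equally spaced
selection with a stride that must divide the frame spacing evenly
(250 ns every 200 ps → 1251 snapshots, the production binding-affinity
schedule), or final-frame-only (the pose-rescoring schedule).  Replica
means are combined into mean ± SEM (sample standard deviation, n−1
denominator); a single replica reports SEM as unavailable rather than 0.
The negativity filter is one-sided: mean + t_{0.99, n−1}·SEM < 0.  The
underlying test is a protocol choice, so a normal-quantile variant is
available by flag; with 4 replicas t is noticeably more conservative
(t₀.₉₉,₃ ≈ 4.54 vs z₀.₉₉ ≈ 2.33).

## Quality control

Triage assigns exactly one category per complex in a fixed priority
order: membrane protein (consumed as a metadata flag or CLI option —
implementing a transmembrane predictor is out of scope) → nonstandard
amino acid → unsupported metal (default supported set NA, K, MG, CA, CL,
ZN; any other charged monatomic hetero species rejects) → unsupported
cosolvent → parameter-assignment failure → missing heavy atoms within
3 Å of the ligand site → peptide-ligand completeness → sequence checks →
gap detection → disulfide comparison.  "Within 3 Å" means any ligand atom
to any residue atom; residues without a heavy-atom template are skipped
with a note.  Sequence consistency uses a global alignment (match +1,
mismatch −1, gap −2) of the resolved one-letter structure sequence against
the reference record; an 'X' aligned to a resolved residue means the
reference itself is unknown.  Chain gaps fire on a C(i)–N(i+1) distance
above 2.5 Å (≈2× the peptide bond) or a numbering jump; because gap
*repair* (homology modelling) is out of scope, a detected gap is a
non-fatal note while a *crash* of gap detection is a technical failure.
Disulfides are geometric SG–SG pairs within 2.1 Å (the conventional S–S
upper bound; the cutoff is configurable), matched greedily nearest-first;
a changed pair count versus the declared SSBOND records is a note on a
still-converted complex.  Summary percentages round half-away-from-zero
to one decimal, with reason percentages relative to their outcome group.

## Stability checks

Backbone (N, CA, C) RMSD per frame after least-squares Kabsch
superposition onto frame 0, warning above 4 Å (flexibility, not automatic
rejection); ligand dissociation when the protein–ligand centre-of-mass
distance grows by more than 15 Å over frame 0; ion dissociation when any
coordinated ion moves more than 10 Å in the protein-fitted frame.  All
thresholds are strict inequalities — boundary equality does not fire.
Centres of mass are geometric (unit-mass) by default since the parameter
file need not carry masses; mass weighting is available when masses are
supplied.  Pose RMSD is computed without refitting (poses share the
pocket frame), heavy-atom and symmetry-naive; graph-automorphism
correction is a declared non-goal.

## Validation statistics

Pearson and Spearman (average ranks on ties) via their definition
formulas, Fisher-z confidence intervals z = atanh r,
half-width z*/√(n−3), and OLS trendlines.  Reported bounds round
half-away-from-zero to 3 decimals (2 on large-sample summaries).  The
convergence table reports one correlation row per trajectory length.

## Synthetic data

The fixture generators define the study conditions for every test.  The
toy complex is a ring of eight standard residues (ALA with one CYS pair
carrying a declared disulfide) whose side chains line a pocket holding a
neutral hexagonal carbon ligand — chemically labelled but geometrically
non-physical; it exists so that residue templates, gap detection,
disulfide detection and the energy modules all apply unchanged.  Defect
injection (membrane flag, nonstandard residue, unsupported metal, missing
site atom, numbering-jump chain gap, lost disulfide, gap-detection crash)
produces a corpus with known triage labels.  Trajectories jitter atoms
with σ = 0.15 Å Gaussian noise around frame 0 (the input structure) and,
per mode, drift the ligand to +20 Å or an ion to 12 Å by the final frame.
Pose sets are rigid translations, so target RMSDs are exact by
construction.  Validation pair tables draw experimental ΔG uniformly on
[−12, −2] kcal/mol and set computed = 3.54·experimental − 35.93 + ε with
Gaussian ε sized so the population correlation is 0.517 — the
calibration-scale scatter of this protocol family.  All randomness flows
through numpy's seeded PCG64 generator; fixed seeds give byte-identical
files.

What passing tests show — and do not show.  The fixtures exercise the
code paths and invariants (cancellations, limits, label recovery,
determinism, statistical calibration), not force-field realism: toy
geometry has no rotamer structure, no hydrogens, no counterion atmosphere
and no conformational ensembles, so agreement on fixtures says nothing
about prediction accuracy on real complexes.

## Numerical choices and degenerate inputs

Atom pairs closer than 1e−6 Å raise an overlapping-atoms error; Kabsch
requires ≥3 non-collinear atoms and enforces a proper rotation
(det = +1); correlation is refused for constant vectors and Fisher
intervals for n ≤ 3 or |r| = 1; schedules refuse non-divisible spacings;
an empty ion selection yields an empty stability report with no flag; a
single-replica SEM is reported as unavailable and the significance filter
refuses to run on it.  Greedy disulfide matching breaks ties by distance
then index order, making reports byte-reproducible.

## Problem sizes

Default fixture sizes (8 residues / 42 receptor atoms + 6 ligand atoms,
4–10 frames, 960 SASA points, 100-seed calibration loops) were chosen so
the full suite exercises every pipeline stage in seconds on one core
while keeping all closed-form comparisons in their asymptotic regimes.

## Known limitations

Single fixed solute dielectric (no variable-dielectric treatment); no
salt dependence in GB; no entropy term; symmetry-naive pose RMSD; no
homology repair of detected gaps; the published (γ, b) of the nonpolar
term and the exact intrinsic-radius set of production campaigns are not
printed in the sources this package models, so its defaults are its own
and are surfaced in the configuration.
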