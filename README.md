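# abfekit

Desk-scale toolkit for end-point absolute binding free energy (ABFE)
estimation of protein–ligand complexes with MM/GBSA, together with the
structure quality control, trajectory stability checks and correlation
statistics needed to run and validate such a protocol at scale.

It is aimed at computational chemists and structural bioinformaticians who
post-process MD snapshot ensembles into binding-affinity estimates — for
ranking ligands against a target (binding-affinity prediction) or for
rescoring alternative docking poses of one ligand (pose selection) — and who
need every stage of that pipeline to be scriptable, deterministic and
testable without cluster-scale inputs.

## The model

The binding free energy of a complex RL is decomposed per snapshot as

    ΔG_bind = ΔE_internal + ΔE_elec + ΔE_vdW + ΔG_p + ΔG_np

where Δ denotes the complex-minus-species difference X(RL) − X(R) − X(L),
the molecular-mechanics terms are a cutoff-free Coulomb sum
Σ k_e q_i q_j / (ε_in r_ij) and a 12-6 Lennard-Jones sum with
Lorentz–Berthelot combination, and solvation is split into a polar and a
nonpolar part.  Configurational entropy (−TΔS) is deliberately excluded:
the toolkit targets ranking, not absolute reproduction of experiment.

The polar term is the generalized Born model in its OBC-II flavour
(the `igb = 5` variant of common MM/GBSA codes):

    G_p = −(k_e/2) (1/ε_in − 1/ε_w) Σ_{i,j} q_i q_j / f_GB(r_ij, a_i, a_j)
    f_GB = sqrt(r_ij² + a_i a_j exp(−r_ij² / (4 a_i a_j)))

with effective Born radii a_i from pairwise HCT descreening integrals
rescaled through the OBC tanh correction (α, β, γ = 1.0, 0.8, 4.85; offset
0.09 Å).  The nonpolar term is ΔG_np = γ·SASA + b with the solvent
accessible surface area computed by a deterministic Shrake–Rupley scheme
(Fibonacci-spiral sphere lattice, probe 1.4 Å).  Default dielectric
constants are ε_in = 3, ε_w = 80.

Under the single-trajectory protocol (STP) the receptor and ligand terms
are coordinate slices of the complex trajectory, so ΔE_internal cancels
exactly.  Two snapshot schedules mirror the two production workflows:
equally spaced snapshots over long trajectories (250 ns sampled every
200 ps → 1251 snapshots per replica) for binding-affinity prediction, and
the final frame of each short replica for pose rescoring.  Replica means
are combined into mean ± SEM, and a one-sided Student-t test at the 99%
level flags estimates that are significantly negative.

Around the energetics, the toolkit provides:

- **Structure triage** (`abfekit.qc`): each complex is converted, rejected
  for a scientific reason (membrane protein, nonstandard amino acid,
  unsupported metal/cosolvent, missing heavy atoms within 3 Å of the
  binding site, sequence-structure mismatch, unknown sequence, ligand
  parameterization failure) or failed technically, with exactly one
  category per complex and deterministic priority order.
- **Stability checks** (`abfekit.stability`): backbone RMSD after Kabsch
  superposition (warning above 4 Å), ligand COM separation increase
  (dissociation above +15 Å), ion displacement in the protein-fitted frame
  (above 10 Å), and unfitted pose RMSD labelling (wrong above 3 Å).
- **Validation statistics** (`abfekit.valstats`): Pearson/Spearman
  coefficients, Fisher-z confidence intervals, OLS trendlines and
  correlation-vs-trajectory-length tables.
- **Synthetic fixtures** (`abfekit.fixtures`): seed-deterministic toy
  complexes, defect-injected QC corpora, stable/dissociating/ion-drift
  trajectories, pose sets with exactly known RMSDs, and linear-model
  affinity pair tables.

## Worked example

```python
import numpy as np
from abfekit import abfe, fixtures
from abfekit.gbsa import GBConfig

spec = fixtures.FixtureSpec(seed=42, n_frames=10)
system, params = fixtures.make_toy_complex(spec)
cfg = GBConfig()  # eps_in=3, eps_w=80, OBC-II, 1.4 A probe
per_replica = []
for rep in range(4):
    traj = fixtures.make_trajectory(system, spec, replica_id=rep)
    sched = abfe.snapshot_schedule(traj.n_frames, traj.spacing_ps,
                                   "equally-spaced", traj.spacing_ps)
    mean_dg, comp = abfe.trajectory_estimate(system, params, traj, sched, cfg)
    per_replica.append(mean_dg)
est = abfe.replica_aggregate(per_replica, comp)
est.significant_negative_99 = abfe.significance_filter(est)
print("per-replica means:", [round(x, 3) for x in est.per_replica_means])
print(f"dG = {est.mean:.3f} +/- {est.sem:.3f} kcal/mol "
      f"({est.mean*4.184:.3f} kJ/mol), negative@99%: {est.significant_negative_99}")
```

prints

```
per-replica means: [34.843, 28.212, 33.081, 35.822]
dG = 32.990 +/- 1.691 kcal/mol (138.029 kJ/mol), negative@99%: False
```

Four replica trajectories of the toy pocket are averaged over their
equally spaced snapshot schedules; the per-replica ΔG means are combined
into mean ± SEM.  The toy ligand sits snugly (positive van der Waals
contact) in a non-physical test pocket, so the estimate is positive and
the 99% negativity filter correctly refuses it — on real complexes this
same filter removes non-binders before any downstream use of the dataset.

The same run is available from the shell:

```sh
abfekit fixtures --kind trajectory --seed 42 --out fx/
abfekit abfe --mode bap --pdb fx/complex.pdb --params fx/complex.prm \
             --traj fx/trajectory.pdb --out run/
```

which writes `run/triage.json`, `run/stability.json` and `run/abfe.json`
(all embedding the resolved configuration), and exits non-zero when QC
rejects the complex or inputs fail to parse.

## Input formats

PDB (ATOM/HETATM/MODEL/ENDMDL/TER/CONECT/SSBOND, column-strict; multi-model
files double as trajectories), TRIPOS MOL2 (MOLECULE/ATOM/BOND; the charge
column loads a provisional parameter set), FASTA, CSV pair tables with a
header row, and a flat per-atom parameter file:

```
# serial charge sigma epsilon gb_radius gb_scale
1  -0.30  3.25  0.17  1.55  0.79
2   0.10  3.40  0.09  1.70  0.72
BOND 0 1 300.0 1.5
ANGLE 0 1 2 0.1 109.5
DIHEDRAL 0 1 2 3 2.5 3 0.0
```

(charges in e, lengths in Å, energies in kcal/mol, angles in degrees;
BOND/ANGLE/DIHEDRAL blocks are optional and indices are 0-based).

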