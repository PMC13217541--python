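"""Trajectory stability checks and docking-pose RMSD labelling.

Three per-replica checks qualify a simulation for end-point analysis:
backbone RMSD after optimal superposition (warning above 4 Å — flexibility,
not automatic rejection), protein–ligand centre-of-mass separation increase
(dissociation above +15 Å) and displacement of coordinated ions in the
protein-fitted frame (dissociation above 10 Å).  All thresholds are strict
inequalities: boundary equality does not fire.  Docking poses are labelled
wrong when their unfitted heavy-atom RMSD to the reference pose exceeds 3 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import MolecularSystem, Trajectory

__all__ = [
    "StabilityThresholds",
    "StabilityReport",
    "kabsch_superpose",
    "backbone_rmsd_check",
    "ligand_dissociation_check",
    "ion_dissociation_check",
    "pose_rmsd",
    "label_pose",
    "stability_report",
]

BACKBONE_NAMES = ("N", "CA", "C")


@dataclass
class StabilityThresholds:
    protein_rmsd_A: float = 4.0
    ligand_com_shift_A: float = 15.0
    ion_rmsd_A: float = 10.0
    wrong_pose_rmsd_A: float = 3.0

    def __post_init__(self):
        if min(self.protein_rmsd_A, self.ligand_com_shift_A,
               self.ion_rmsd_A, self.wrong_pose_rmsd_A) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class StabilityReport:
    backbone_rmsd_A: np.ndarray
    ligand_com_shift_A: np.ndarray
    ion_displacement_A: dict[int, np.ndarray] = field(default_factory=dict)
    protein_warning: bool = False
    ligand_dissociated: bool = False
    ion_dissociated: bool = False

    @property
    def flags(self) -> dict[str, bool]:
        return {
            "protein-warning": self.protein_warning,
            "ligand-dissociated": self.ligand_dissociated,
            "ion-dissociated": self.ion_dissociated,
        }

    def as_dict(self) -> dict:
        return {
            "backbone_rmsd_A": [float(x) for x in self.backbone_rmsd_A],
            "ligand_com_shift_A": [float(x) for x in self.ligand_com_shift_A],
            "ion_displacement_A": {
                str(k): [float(x) for x in v]
                for k, v in self.ion_displacement_A.items()},
            "flags": self.flags,
        }


class DegenerateSelectionError(ValueError):
    """Too few or collinear atoms for a rigid superposition."""


def kabsch_superpose(ref_coords: np.ndarray, mobile_coords: np.ndarray,
                     selection: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of mobile onto reference (Kabsch).

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation ≈ ref`` on the selection, with a
    proper rotation (det = +1) enforced.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mob = np.asarray(mobile_coords, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        ref, mob = ref[sel], mob[sel]
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise DegenerateSelectionError("superposition needs at least 3 atoms")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    # collinearity: rank of the centred reference must be >= 2
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise DegenerateSelectionError("selection is collinear")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref.mean(axis=0) - rot @ mob.mean(axis=0)
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def backbone_selection(system: MolecularSystem) -> np.ndarray:
    sel = [i for i in system.receptor_selection
           if system.atoms[i].name in BACKBONE_NAMES
           and system.atoms[i].record_kind == "standard-residue"]
    if not sel:
        raise ValueError("no backbone atoms (N, CA, C) in receptor selection")
    return np.asarray(sel, dtype=int)


def backbone_rmsd_check(trajectory: Trajectory, system: MolecularSystem,
                        thresholds: StabilityThresholds | None = None
                        ) -> tuple[np.ndarray, bool]:
    """Per-frame backbone RMSD to frame 0 after superposition; warn if any
    frame strictly exceeds the protein threshold."""
    thresholds = thresholds or StabilityThresholds()
    trajectory.check_compatible(system)
    bb = backbone_selection(system)
    ref = trajectory.frames[0]
    series = np.empty(trajectory.n_frames)
    for t in range(trajectory.n_frames):
        _, _, rmsd = kabsch_superpose(ref, trajectory.frames[t], bb)
        series[t] = rmsd
    return series, bool(np.any(series > thresholds.protein_rmsd_A))


def _com(coords: np.ndarray, masses: np.ndarray | None) -> np.ndarray:
    if masses is None:
        return coords.mean(axis=0)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def ligand_dissociation_check(trajectory: Trajectory, system: MolecularSystem,
                              thresholds: StabilityThresholds | None = None,
                              masses: np.ndarray | None = None
                              ) -> tuple[np.ndarray, bool]:
    """Increase of the protein–ligand COM distance over frame 0.

    Geometric (unit-mass) centres by default; pass per-atom masses for
    mass-weighted centres.  The dissociation flag fires on a strict +15 Å
    exceedance in any frame.
    """
    thresholds = thresholds or StabilityThresholds()
    trajectory.check_compatible(system)
    rsel, lsel = system.receptor_selection, system.ligand_selection
    if rsel.size == 0 or lsel.size == 0:
        raise ValueError("both selections must be non-empty")
    m_r = masses[rsel] if masses is not None else None
    m_l = masses[lsel] if masses is not None else None
    dist = np.array([
        np.linalg.norm(_com(fr[rsel], m_r) - _com(fr[lsel], m_l))
        for fr in trajectory.frames])
    shift = dist - dist[0]
    return shift, bool(np.any(shift > thresholds.ligand_com_shift_A))


def ion_dissociation_check(trajectory: Trajectory, system: MolecularSystem,
                           ion_selection: np.ndarray,
                           thresholds: StabilityThresholds | None = None
                           ) -> tuple[dict[int, np.ndarray], bool]:
    """Displacement of each ion after fitting the protein backbone to frame 0.

    Empty ion selection returns an empty report with no flag.
    """
    thresholds = thresholds or StabilityThresholds()
    ion_selection = np.asarray(ion_selection, dtype=int)
    if ion_selection.size == 0:
        return {}, False
    trajectory.check_compatible(system)
    bb = backbone_selection(system)
    ref = trajectory.frames[0]
    series = {int(i): np.empty(trajectory.n_frames) for i in ion_selection}
    for t in range(trajectory.n_frames):
        rot, trans, _ = kabsch_superpose(ref, trajectory.frames[t], bb)
        fitted = trajectory.frames[t] @ rot.T + trans
        for i in ion_selection:
            series[int(i)][t] = np.linalg.norm(fitted[i] - ref[i])
    flagged = any(np.any(s > thresholds.ion_rmsd_A) for s in series.values())
    return series, bool(flagged)


def pose_rmsd(pose_a: np.ndarray, pose_b: np.ndarray,
              atom_map: np.ndarray | None = None) -> float:
    """Plain coordinate RMSD between two poses sharing the pocket frame.

    No refitting is performed; ``atom_map`` maps pose_a indices onto pose_b.
    Symmetry-naive: topological automorphisms are not considered.
    """
    a = np.asarray(pose_a, dtype=float)
    b = np.asarray(pose_b, dtype=float)
    if atom_map is not None:
        b = b[np.asarray(atom_map, dtype=int)]
    if a.shape != b.shape:
        raise ValueError("poses must have the same mapped atom count")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def label_pose(rmsd: float, thresholds: StabilityThresholds | None = None) -> str:
    """'wrong' iff the pose RMSD strictly exceeds the 3 Å threshold."""
    thresholds = thresholds or StabilityThresholds()
    return "wrong" if rmsd > thresholds.wrong_pose_rmsd_A else "acceptable"


def stability_report(trajectory: Trajectory, system: MolecularSystem,
                     ion_selection: np.ndarray | None = None,
                     thresholds: StabilityThresholds | None = None
                     ) -> StabilityReport:
    """Run all three checks on one replica and collect the flags."""
    thresholds = thresholds or StabilityThresholds()
    bb_series, protein_warning = backbone_rmsd_check(trajectory, system, thresholds)
    lig_series, lig_flag = ligand_dissociation_check(trajectory, system, thresholds)
    ion_sel = (np.asarray(ion_selection, dtype=int)
               if ion_selection is not None else np.array([], dtype=int))
    ion_series, ion_flag = ion_dissociation_check(
        trajectory, system, ion_sel, thresholds)
    return StabilityReport(
        backbone_rmsd_A=bb_series,
        ligand_com_shift_A=lig_series,
        ion_displacement_A=ion_series,
        protein_warning=protein_warning,
        ligand_dissociated=lig_flag,
        ion_dissociated=ion_flag,
    )
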