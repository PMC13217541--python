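"""Molecular-mechanics energy terms: Coulomb, Lennard-Jones, bonded.

All energies are kcal/mol and act on isolated solute snapshots: no nonbonded
cutoff and no periodicity, matching end-point post-processing practice.
Bonded exclusions (1-2/1-3/1-4) are the caller's responsibility via the
explicit pair set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import BondedTerms, MolecularSystem, ParameterSet

#: Coulomb constant, kcal·Å·mol⁻¹·e⁻².
K_COULOMB = 332.0636

_MIN_SEPARATION = 1e-6  # Å


class OverlappingAtomsError(ValueError):
    """Two atoms in a pair are (numerically) coincident."""


@dataclass
class EnergyBreakdown:
    """Per-snapshot ΔG_bind components (kcal/mol).

    total = e_internal + e_elec + e_vdw + g_polar + g_nonpolar; under the
    single-trajectory protocol e_internal is exactly zero because the
    receptor, ligand and complex terms are slices of the same frame.
    """

    e_internal: float
    e_elec: float
    e_vdw: float
    g_polar: float
    g_nonpolar: float

    @property
    def total(self) -> float:
        return (self.e_internal + self.e_elec + self.e_vdw
                + self.g_polar + self.g_nonpolar)

    def as_dict(self) -> dict[str, float]:
        return {
            "e_internal": self.e_internal,
            "e_elec": self.e_elec,
            "e_vdw": self.e_vdw,
            "g_polar": self.g_polar,
            "g_nonpolar": self.g_nonpolar,
            "total": self.total,
        }


def _pair_distances(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        return np.zeros(0)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) index array")
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    r = np.sqrt(np.sum(d * d, axis=1))
    if np.any(r < _MIN_SEPARATION):
        bad = pairs[np.argmin(r)]
        raise OverlappingAtomsError(f"atoms {bad[0]} and {bad[1]} overlap")
    return r


def coulomb_energy(coords: np.ndarray, charges: np.ndarray, pairs: np.ndarray,
                   eps_in: float = 1.0) -> float:
    """Σ k_e q_i q_j / (eps_in · r_ij) over the explicit pair set."""
    if eps_in < 1:
        raise ValueError("eps_in must be ≥ 1")
    r = _pair_distances(coords, pairs)
    if r.size == 0:
        return 0.0
    charges = np.asarray(charges, dtype=float)
    pairs = np.asarray(pairs, dtype=int)
    qq = charges[pairs[:, 0]] * charges[pairs[:, 1]]
    return float(np.sum(K_COULOMB * qq / (eps_in * r)))


def lj_energy(coords: np.ndarray, sigma: np.ndarray, epsilon: np.ndarray,
              pairs: np.ndarray) -> float:
    """12-6 Lennard-Jones with Lorentz–Berthelot combination rules."""
    r = _pair_distances(coords, pairs)
    if r.size == 0:
        return 0.0
    sigma = np.asarray(sigma, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    pairs = np.asarray(pairs, dtype=int)
    sig_ij = 0.5 * (sigma[pairs[:, 0]] + sigma[pairs[:, 1]])
    eps_ij = np.sqrt(epsilon[pairs[:, 0]] * epsilon[pairs[:, 1]])
    sr6 = (sig_ij / r) ** 6
    return float(np.sum(4.0 * eps_ij * (sr6 * sr6 - sr6)))


def _angle(coords, i, j, k) -> float:
    """Angle i-j-k in degrees."""
    a = coords[i] - coords[j]
    b = coords[k] - coords[j]
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _dihedral(coords, i, j, k, l) -> float:
    """Signed dihedral i-j-k-l in degrees."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def bonded_energy(coords: np.ndarray, bonded: BondedTerms | None) -> float:
    """Harmonic bonds k_b(r−r0)², harmonic angles k_θ(θ−θ0)² (degrees),
    periodic dihedrals k_φ(1+cos(nφ−φ0))."""
    if bonded is None:
        return 0.0
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    e = 0.0
    for i, j, kb, r0 in bonded.bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"bond index ({i},{j}) out of range")
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e += kb * (r - r0) ** 2
    for i, j, k, kt, t0 in bonded.angles:
        if not all(0 <= x < n for x in (i, j, k)):
            raise IndexError(f"angle index ({i},{j},{k}) out of range")
        e += kt * (_angle(coords, i, j, k) - t0) ** 2
    for i, j, k, l, kp, per, p0 in bonded.dihedrals:
        if not all(0 <= x < n for x in (i, j, k, l)):
            raise IndexError(f"dihedral index ({i},{j},{k},{l}) out of range")
        phi = _dihedral(coords, i, j, k, l)
        e += kp * (1.0 + np.cos(np.radians(per * phi - p0)))
    return float(e)


def cross_pairs(system: MolecularSystem) -> np.ndarray:
    """All receptor×ligand index pairs."""
    if system.receptor_selection.size == 0 or system.ligand_selection.size == 0:
        raise ValueError("receptor and ligand selections must be non-empty")
    r, l = np.meshgrid(system.receptor_selection, system.ligand_selection,
                       indexing="ij")
    return np.column_stack([r.ravel(), l.ravel()])


def interaction_energy(system: MolecularSystem, params: ParameterSet,
                       frame: np.ndarray, eps_in: float = 1.0
                       ) -> tuple[float, float]:
    """Receptor–ligand cross electrostatic and van der Waals energy.

    Equals E(RL) − E(R) − E(L) when the species share coordinates (the
    single-trajectory identity), because intra-group pairs cancel.
    """
    params.check_compatible(system)
    pairs = cross_pairs(system)
    e_elec = coulomb_energy(frame, params.charge, pairs, eps_in)
    e_vdw = lj_energy(frame, params.lj_sigma, params.lj_epsilon, pairs)
    return e_elec, e_vdw
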