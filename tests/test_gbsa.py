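"""Generalized-Born and SASA terms against closed forms and quadrature
oracles: Born-ion energy, HCT descreening integral, spherical-cap areas and
the screened-Coulomb large-separation limit."""

import numpy as np
import pytest
from scipy import integrate

from abfekit.gbsa import (BornRadii, GBConfig, born_radii, gb_polar_energy,
                          nonpolar_energy, sasa, solvation_free_energy)
from abfekit.mmenergy import K_COULOMB
from abfekit.structio import Atom, MolecularSystem, ParameterSet


def hct_integral_numeric(r, s, rho_i):
    """Quadrature oracle for the pairwise descreening integral.

    (1/4π) ∫ dV/x⁴ over the scaled neighbor sphere (radius s at distance r),
    restricted to x ≥ ρ̃_i, evaluated in spherical shells around atom i.
    """
    def shell(x):
        mu_lo = (x * x + r * r - s * s) / (2 * x * r)
        mu_lo = max(-1.0, mu_lo)
        if mu_lo >= 1.0:
            return 0.0
        return 2 * np.pi / x ** 2 * (1.0 - mu_lo)
    lo = max(rho_i, r - s) if r > s else rho_i
    kink = s - r  # below this radius the whole shell is inside the sphere
    points = [kink] if lo < kink < r + s else None
    val, _ = integrate.quad(shell, lo, r + s, limit=400, points=points,
                            epsabs=1e-13, epsrel=1e-13)
    return val / (4 * np.pi)


class TestBornRadii:
    def test_isolated_atom_zero_descreening(self):
        cfg = GBConfig()
        born = born_radii(np.zeros((1, 3)), np.array([1.5]), np.array([0.8]), cfg)
        assert born.radii[0] == pytest.approx(1.5 - 0.09, abs=1e-12)

    def test_neighbor_strictly_increases_radius(self):
        cfg = GBConfig()
        alone = born_radii(np.zeros((1, 3)), np.array([1.5]),
                           np.array([0.8]), cfg).radii[0]
        pair = born_radii(np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                          np.array([1.5, 1.7]), np.array([0.8, 0.72]),
                          cfg).radii[0]
        assert pair > alone

    @pytest.mark.parametrize("r, rho, rho_j, scale", [
        (3.0, 1.59, 1.59, 0.8),    # separated spheres
        (1.2, 1.59, 1.59, 0.8),    # overlapping spheres
        (0.8, 0.59, 2.09, 0.9),    # atom i inside the scaled neighbor
    ])
    def test_hct_pair_term_matches_quadrature(self, r, rho, rho_j, scale):
        cfg = GBConfig()
        from abfekit.gbsa import _hct_descreen_sum
        coords = np.array([[0.0, 0, 0], [0.0, 0, r]])
        rho_red = np.array([rho, rho_j]) - cfg.offset_A
        scaled = scale * rho_red
        psi = _hct_descreen_sum(coords, rho_red, scaled)
        analytic = psi[0] / rho_red[0]
        numeric = hct_integral_numeric(r, scaled[1], rho_red[0])
        assert analytic == pytest.approx(numeric, abs=1e-10)

    def test_invariant_lower_bound(self, rng):
        cfg = GBConfig()
        coords = rng.normal(size=(6, 3)) * 3
        rho = rng.uniform(1.3, 1.9, 6)
        born = born_radii(coords, rho, np.full(6, 0.8), cfg)
        assert np.all(born.radii >= rho - cfg.offset_A - 1e-12)
        assert np.all(np.isfinite(born.radii))


class TestPolarEnergy:
    def test_born_ion_closed_form(self):
        # q = 1e, a = 2 Å, eps_in = 1, eps_w = 80
        cfg = GBConfig(eps_in=1.0)
        e = gb_polar_energy(np.zeros((1, 3)), np.array([1.0]),
                            BornRadii(np.array([2.0])), cfg)
        expected = -0.5 * K_COULOMB * (1.0 - 1.0 / 80.0) / 2.0
        assert e == pytest.approx(expected, abs=1e-9)
        assert e == pytest.approx(-81.97820125, abs=1e-6)

    def test_zero_charges(self):
        cfg = GBConfig()
        e = gb_polar_energy(np.zeros((2, 3)) + [[0, 0, 0], [3, 0, 0]],
                            np.zeros(2), BornRadii(np.array([1.5, 1.5])), cfg)
        assert e == 0.0

    def test_cross_term_reaches_screened_coulomb(self, vacuum_gb):
        # at 10⁴ Å the GB cross term must equal the screened Coulomb pair
        coords = np.array([[0.0, 0, 0], [0.0, 0, 1e4]])
        born = born_radii(coords, np.array([1.59, 1.59]),
                          np.array([0.8, 0.8]), vacuum_gb)
        total = gb_polar_energy(coords, np.array([1.0, 1.0]), born, vacuum_gb)
        self_terms = sum(
            gb_polar_energy(np.zeros((1, 3)), np.array([1.0]),
                            BornRadii(born.radii[i:i + 1]), vacuum_gb)
            for i in range(2))
        cross = total - self_terms
        expected = -K_COULOMB * (1.0 - 1.0 / 80.0) / 1e4
        assert cross == pytest.approx(expected, rel=1e-3)

    def test_nonpositive_for_single_signed_charges(self, rng):
        cfg = GBConfig()
        coords = rng.normal(size=(5, 3)) * 3
        q = rng.uniform(0.1, 0.8, 5)  # all positive
        born = born_radii(coords, np.full(5, 1.6), np.full(5, 0.8), cfg)
        assert gb_polar_energy(coords, q, born, cfg) < 0

    def test_generalized_prefactor_reduces_to_printed_formula(self):
        # eps_in = 1 ⇒ the prefactor is exactly −½(1 − 1/ε_w)
        born = BornRadii(np.array([2.0]))
        q = np.array([0.7])
        e1 = gb_polar_energy(np.zeros((1, 3)), q, born, GBConfig(eps_in=1.0))
        printed = -0.5 * K_COULOMB * (1 - 1 / 80.0) * q[0] ** 2 / 2.0
        assert e1 == pytest.approx(printed, abs=1e-12)


class TestSasa:
    def test_isolated_sphere_exact(self):
        cfg = GBConfig()
        _, total = sasa(np.zeros((1, 3)), np.array([1.7]), cfg)
        assert total == pytest.approx(4 * np.pi * 3.1 ** 2, abs=1e-9)

    def test_fully_enclosed_atom_is_zero(self):
        # 12 large spheres on an icosahedral shell swallow the central atom
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array([(0, 1, phi), (0, -1, phi), (0, 1, -phi), (0, -1, -phi),
                          (1, phi, 0), (-1, phi, 0), (1, -phi, 0), (-1, -phi, 0),
                          (phi, 0, 1), (-phi, 0, 1), (phi, 0, -1), (-phi, 0, -1)])
        verts = verts / np.linalg.norm(verts[0]) * 2.0
        coords = np.vstack([[0.0, 0, 0], verts])
        radii = np.array([1.0] + [3.0] * 12)
        areas, _ = sasa(coords, radii, GBConfig())
        assert areas[0] == 0.0

    def test_two_sphere_cap_formula(self):
        cfg = GBConfig(sphere_points=960)
        d, r = 2.0, 1.7
        R = r + cfg.probe_A
        _, total = sasa(np.array([[0.0, 0, 0], [0.0, 0, d]]),
                        np.array([r, r]), cfg)
        exact = 2 * (4 * np.pi * R * R - 2 * np.pi * R * (R - d / 2))
        assert total == pytest.approx(exact, rel=0.01)

    def test_lattice_convergence(self, toy_complex):
        system, params = toy_complex
        coarse = GBConfig(sphere_points=960)
        fine = GBConfig(sphere_points=3840)
        _, t1 = sasa(system.coords, params.gb_radius, coarse)
        _, t2 = sasa(system.coords, params.gb_radius, fine)
        assert abs(t1 - t2) / t2 < 0.005


class TestNonpolar:
    def test_hand_product(self):
        assert nonpolar_energy(100.0, GBConfig()) == pytest.approx(0.72)

    def test_zero_area_gives_intercept(self):
        cfg = GBConfig(sasa_beta=1.25)
        assert nonpolar_energy(0.0, cfg) == 1.25

    def test_zero_slope_gives_intercept(self):
        cfg = GBConfig(sasa_gamma=0.0, sasa_beta=0.4)
        assert nonpolar_energy(12345.0, cfg) == 0.4


def _four_atom_system(rng):
    coords = rng.normal(size=(4, 3)) * 2.5
    atoms = [Atom(i + 1, "C", "C", "LIG", "L", 1, coords[i], "hetero")
             for i in range(4)]
    system = MolecularSystem(atoms, receptor_selection=np.array([0, 1]),
                             ligand_selection=np.array([2, 3]))
    # net-neutral species so the electrostatic tail decays as dipole-dipole
    params = ParameterSet([0.4, -0.4, 0.3, -0.3], np.full(4, 3.4),
                          np.full(4, 0.1), rng.uniform(1.4, 1.8, 4),
                          np.full(4, 0.8))
    return system, params


class TestSolvation:
    def test_neutral_single_atom(self):
        cfg = GBConfig()
        atoms = [Atom(1, "AR", "AR", "ARG", "A", 1, [0.0, 0, 0], "hetero")]
        system = MolecularSystem(atoms, receptor_selection=np.array([0]),
                                 ligand_selection=np.array([], dtype=int))
        params = ParameterSet([0.0], [3.4], [0.1], [1.7], [0.8])
        g_p, g_np = solvation_free_energy(system, params, system.coords,
                                          np.array([0]), cfg)
        assert g_p == 0.0
        expected = cfg.sasa_gamma * 4 * np.pi * (1.7 + cfg.probe_A) ** 2
        assert g_np == pytest.approx(expected, abs=1e-9)

    def test_separated_species_have_additive_solvation(self, rng):
        cfg = GBConfig()
        system, params = _four_atom_system(rng)
        frame = system.coords.copy()
        frame[2:] += np.array([2000.0, 0.0, 0.0])
        both = solvation_free_energy(system, params, frame,
                                     np.arange(4), cfg)
        rec = solvation_free_energy(system, params, frame, np.array([0, 1]), cfg)
        lig = solvation_free_energy(system, params, frame, np.array([2, 3]), cfg)
        assert both[0] == pytest.approx(rec[0] + lig[0], abs=1e-6)
        assert both[1] == pytest.approx(rec[1] + lig[1], abs=1e-6)

    def test_matches_monolithic_evaluation(self, rng):
        """Selection-based evaluation equals direct calls on the subset."""
        cfg = GBConfig()
        system, params = _four_atom_system(rng)
        sel = np.array([0, 1])
        g_p, g_np = solvation_free_energy(system, params, system.coords, sel, cfg)
        sub = params.subset(sel)
        born = born_radii(system.coords[sel], sub.gb_radius, sub.gb_scale, cfg)
        direct_gp = gb_polar_energy(system.coords[sel], sub.charge, born, cfg)
        _, area = sasa(system.coords[sel], sub.gb_radius, cfg)
        assert g_p == pytest.approx(direct_gp, abs=1e-9)
        assert g_np == pytest.approx(nonpolar_energy(area, cfg), abs=1e-9)

    def test_empty_selection_errors(self, rng):
        system, params = _four_atom_system(rng)
        with pytest.raises(ValueError):
            solvation_free_energy(system, params, system.coords,
                                  np.array([], dtype=int))


def test_rigid_transform_invariance(rng):
    """G_p and SASA are unchanged by a random rigid motion."""
    cfg = GBConfig()
    coords = rng.normal(size=(6, 3)) * 3
    rho = rng.uniform(1.4, 1.8, 6)
    scale = np.full(6, 0.8)
    q = rng.normal(size=6) * 0.3
    qmat, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(qmat) < 0:
        qmat[:, 0] *= -1
    moved = coords @ qmat.T + np.array([5.0, -3.0, 9.0])
    born_a = born_radii(coords, rho, scale, cfg)
    born_b = born_radii(moved, rho, scale, cfg)
    assert np.allclose(born_a.radii, born_b.radii, atol=1e-9)
    ga = gb_polar_energy(coords, q, born_a, cfg)
    gb = gb_polar_energy(moved, q, born_b, cfg)
    assert ga == pytest.approx(gb, abs=1e-8)
    # SASA uses a fixed lattice, so rotation changes the quadrature slightly
    _, ta = sasa(coords, rho, cfg)
    _, tb = sasa(moved, rho, cfg)
    assert ta == pytest.approx(tb, rel=0.01)


def test_sasa_burial_on_contact_fixture(toy_complex):
    system, params = toy_complex
    cfg = GBConfig()
    rl = np.concatenate([system.receptor_selection, system.ligand_selection])

    def total(sel):
        sub = params.subset(sel)
        return sasa(system.coords[sel], sub.gb_radius, cfg)[1]

    d_sasa = (total(rl) - total(system.receptor_selection)
              - total(system.ligand_selection))
    assert d_sasa <= 0.0
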