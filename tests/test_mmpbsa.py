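"""Vacuum terms against brute-force oracles; PB solver against analytic
limits (coarse grids here; the full refinement study runs in the acceptance
suite); binding decomposition identities."""

import numpy as np
import pytest
from scipy.special import eval_legendre

from s100b_abeta.mmpbsa import (
    ClashError,
    EnergyDecomposition,
    F_COULOMB,
    KJ_PER_KCAL,
    PBConfig,
    apolar_energy,
    coulomb_energy,
    frame_binding_decomposition,
    lj_energy,
    solve_pb,
)

from conftest import make_model


def charged_cluster(n, seed, box=1.5):
    rng = np.random.default_rng(seed)
    return make_model(
        rng.uniform(0, box, size=(n, 3)),
        radii=rng.uniform(0.12, 0.2, n),
        charges=rng.uniform(-1, 1, n),
        lj_sigmas=rng.uniform(0.25, 0.4, n),
        lj_epsilons=rng.uniform(0.1, 1.0, n),
    )


def born_ion(q=1.0, a=0.2):
    return make_model([[0.0, 0.0, 0.0]], radii=[a], charges=[q])


def kirkwood_energy(charges, positions, a, eps_in, eps_out, lmax=80):
    """Analytic reaction-field energy of charges inside a dielectric sphere."""
    g = 0.0
    for qi, ri in zip(charges, positions):
        for qj, rj in zip(charges, positions):
            si, sj = np.linalg.norm(ri), np.linalg.norm(rj)
            cosg = 1.0 if si == 0 or sj == 0 else float(np.dot(ri, rj) / (si * sj))
            for l in range(lmax + 1):
                c = (
                    (1.0 / eps_in)
                    * ((l + 1) * (eps_in - eps_out))
                    / (eps_in * l + eps_out * (l + 1))
                    / a ** (2 * l + 1)
                )
                g += 0.5 * F_COULOMB * qi * qj * c * si**l * sj**l * eval_legendre(l, cosg)
    return g


class TestCoulomb:
    def test_unit_charges_at_one_nm(self):
        m = make_model([[0, 0, 0], [1.0, 0, 0]], charges=[1.0, -1.0])
        e = coulomb_energy(m, np.array([0, 1]))
        assert e == pytest.approx(-F_COULOMB, rel=1e-12)
        assert e / KJ_PER_KCAL == pytest.approx(-33.207, abs=0.001)

    def test_zero_charges_zero_energy(self):
        m = charged_cluster(8, 0)
        m.charges = np.zeros(8)
        assert coulomb_energy(m, np.arange(8)) == 0.0

    def test_matches_double_loop_oracle(self):
        m = charged_cluster(10, 42)
        e = coulomb_energy(m, np.arange(10))
        brute = 0.0
        for i in range(10):
            for j in range(i + 1, 10):
                r = np.linalg.norm(m.positions[i] - m.positions[j])
                brute += F_COULOMB * m.charges[i] * m.charges[j] / r
        assert e == pytest.approx(brute, rel=1e-10)

    def test_clash_detected(self):
        m = make_model([[0, 0, 0], [0.005, 0, 0]], charges=[1.0, 1.0])
        with pytest.raises(ClashError):
            coulomb_energy(m, np.array([0, 1]))


class TestLennardJones:
    def test_minimum_at_sigma_times_sixth_root_of_two(self):
        sigma, eps = 0.34, 0.8
        r_min = 2 ** (1 / 6) * sigma
        m = make_model(
            [[0, 0, 0], [r_min, 0, 0]],
            lj_sigmas=[sigma, sigma], lj_epsilons=[eps, eps],
        )
        assert lj_energy(m, np.array([0, 1])) == pytest.approx(-eps, rel=1e-12)

    def test_vanishes_at_infinity(self):
        m = make_model(
            [[0, 0, 0], [500.0, 0, 0]],
            lj_sigmas=[0.3, 0.3], lj_epsilons=[0.5, 0.5],
        )
        assert lj_energy(m, np.array([0, 1])) == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_oracle(self):
        m = charged_cluster(12, 7)
        e = lj_energy(m, np.arange(12))
        brute = 0.0
        for i in range(12):
            for j in range(i + 1, 12):
                r = np.linalg.norm(m.positions[i] - m.positions[j])
                s = 0.5 * (m.lj_sigmas[i] + m.lj_sigmas[j])
                ep = np.sqrt(m.lj_epsilons[i] * m.lj_epsilons[j])
                brute += 4 * ep * ((s / r) ** 12 - (s / r) ** 6)
        assert e == pytest.approx(brute, rel=1e-10)


class TestPoissonBoltzmann:
    def test_born_ion_coarse_grid(self):
        m = born_ion()
        exact = -(F_COULOMB / (2 * 0.2)) * (1 - 1 / 78.4)
        cfg = PBConfig(
            solute_dielectric=1.0, ionic_strength=0.0, grid_spacing=0.05,
        )
        assert solve_pb(m, cfg) == pytest.approx(exact, rel=0.03)

    def test_zero_charges_exactly_zero(self):
        m = born_ion(q=0.0)
        m.charges = np.zeros(1)
        assert solve_pb(m, PBConfig()) == 0.0

    def test_kirkwood_two_charges_coarse_grid(self):
        pos = [[0.08, 0, 0], [-0.08, 0, 0], [0, 0, 0]]
        m = make_model(pos, radii=[0.01, 0.01, 0.2], charges=[1.0, -1.0, 0.0])
        exact = kirkwood_energy([1.0, -1.0], pos[:2], 0.2, 1.0, 78.4)
        cfg = PBConfig(solute_dielectric=1.0, ionic_strength=0.0, grid_spacing=0.05)
        assert solve_pb(m, cfg) == pytest.approx(exact, rel=0.05)

    def test_translation_invariance_within_grid_tolerance(self):
        m = born_ion()
        cfg = PBConfig(solute_dielectric=1.0, ionic_strength=0.0, grid_spacing=0.05)
        e0 = solve_pb(m, cfg)
        moved = m.copy()
        moved.positions = m.positions + np.array([0.013, -0.029, 0.007])
        e1 = solve_pb(moved, cfg)
        assert e1 == pytest.approx(e0, rel=0.01)

    def test_salt_screening_stabilizes(self):
        m = born_ion()
        base = dict(solute_dielectric=1.0, grid_spacing=0.05)
        no_salt = solve_pb(m, PBConfig(ionic_strength=0.0, **base))
        salt = solve_pb(m, PBConfig(ionic_strength=0.1, **base))
        assert salt < no_salt < 0  # Debye screening adds favourable energy


class TestApolar:
    def test_zero_gamma(self):
        m = charged_cluster(5, 3)
        assert apolar_energy(m, gamma=0.0) == 0.0

    def test_single_atom_closed_form(self):
        m = born_ion()
        area = 4 * np.pi * (0.2 + 0.14) ** 2
        assert apolar_energy(m, gamma=2.27) == pytest.approx(2.27 * area, rel=1e-9)

    def test_interface_burial_is_favourable(self, study_complex):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        pb = np.flatnonzero(study_complex.chain_ids == "L")
        union = np.concatenate([pa, pb])
        kw = dict(gamma=2.27, n_sphere_points=480)
        delta = (
            apolar_energy(study_complex, union, **kw)
            - apolar_energy(study_complex, pa, **kw)
            - apolar_energy(study_complex, pb, **kw)
        )
        assert delta < 0.0


class TestBindingDecomposition:
    def test_coulomb_delta_equals_cross_pairs(self, study_complex):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        pb = np.flatnonzero(study_complex.chain_ids == "L")
        union = np.concatenate([pa, pb])
        delta = (
            coulomb_energy(study_complex, union)
            - coulomb_energy(study_complex, pa)
            - coulomb_energy(study_complex, pb)
        )
        cross = coulomb_energy(study_complex, pa, pb)
        assert delta == pytest.approx(cross, rel=1e-10)

    def test_charge_flip_antisymmetry(self, study_complex):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        pb = np.flatnonzero(study_complex.chain_ids == "L")
        flipped = study_complex.copy()
        flipped.charges = study_complex.charges.copy()
        flipped.charges[pb] *= -1.0
        assert coulomb_energy(flipped, pa, pb) == pytest.approx(
            -coulomb_energy(study_complex, pa, pb), rel=1e-12
        )

    def test_total_is_exact_sum_of_terms(self):
        dec = EnergyDecomposition(e_coul=-1.25, e_vdw=0.5, solv_polar=2.0, solv_apolar=-0.125)
        assert dec.total == -1.25 + 0.5 + 2.0 + -0.125

    def test_distant_partners_all_terms_vanish(self):
        # two neutral dipoles 10 nm apart, 0.1 M salt: every binding term
        # should be negligible
        positions = [[0, 0, 0], [0.3, 0, 0], [10.0, 0, 0], [10.3, 0, 0]]
        m = make_model(
            positions,
            radii=[0.15] * 4, charges=[0.5, -0.5, 0.5, -0.5],
            lj_sigmas=[0.3] * 4, lj_epsilons=[0.5] * 4,
            chain_ids=["A", "A", "B", "B"], residue_seqs=[1, 1, 2, 2],
        )
        cfg = PBConfig(solute_dielectric=2.0, ionic_strength=0.1, grid_spacing=0.2)
        dec = frame_binding_decomposition(
            m, np.array([0, 1]), np.array([2, 3]), cfg, n_sphere_points=960
        )
        for term_kcal in (dec.e_coul, dec.e_vdw, dec.solv_polar, dec.solv_apolar):
            assert abs(term_kcal) * KJ_PER_KCAL < 0.1  # kJ/mol

    def test_overlapping_parts_rejected(self, study_complex):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        with pytest.raises(ValueError):
            frame_binding_decomposition(study_complex, pa, pa, PBConfig())
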