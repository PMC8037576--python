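"""Interfacial area, SAS^hydro index, windowing and replicate statistics."""

import numpy as np
import pytest

from s100b_abeta.interface import (
    HydrophobicityScale,
    apply_burn_in,
    floating_window,
    interfacial_area,
    per_residue_interfacial_sas,
    replicate_stats,
    sas_hydro,
)
from s100b_abeta.synthetic import build_ideal_helix, build_two_body_complex

from conftest import make_model, mc_sasa_oracle


def two_atom_pair(separation=0.25):
    return make_model(
        [[0, 0, 0], [separation, 0, 0]],
        radii=[0.15, 0.15],
        chain_ids=["A", "B"],
        residue_seqs=[1, 2],
    )


class TestInterfacialArea:
    def test_symmetry_in_partners(self, study_complex):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        pb = np.flatnonzero(study_complex.chain_ids == "L")
        ab = interfacial_area(study_complex, pa, pb, n_sphere_points=240)
        ba = interfacial_area(study_complex, pb, pa, n_sphere_points=240)
        assert ab == ba

    def test_distant_partners_zero(self):
        m = two_atom_pair(5.0)
        assert interfacial_area(m, np.array([0]), np.array([1])) == 0.0

    def test_symmetric_pair_mappings_equal(self):
        m = two_atom_pair(0.25)
        a0 = per_residue_interfacial_sas(m, np.array([0]), np.array([1]),
                                         n_sphere_points=30720)
        # identical atoms: the two mapped areas agree (to lattice quadrature;
        # the buried caps are sampled from different lattice directions)
        assert a0[("A", 1)] == pytest.approx(a0[("B", 2)], rel=0.01)
        avg = interfacial_area(m, np.array([0]), np.array([1]), n_sphere_points=30720)
        assert avg == pytest.approx(0.5 * (a0[("A", 1)] + a0[("B", 2)]), rel=1e-12)

    def test_overlapping_parts_rejected(self, study_complex):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        with pytest.raises(ValueError, match="overlap"):
            interfacial_area(study_complex, pa, pa)

    def test_matches_monte_carlo_oracle(self):
        rec = build_ideal_helix("AAAAAA")
        lig = build_ideal_helix("GGGGGG")
        m = build_two_body_complex(rec, lig, 0.35)
        pa = np.flatnonzero(m.chain_ids == "R")
        pb = np.flatnonzero(m.chain_ids == "L")
        area = interfacial_area(m, pa, pb, n_sphere_points=7680)

        union = np.concatenate([pa, pb])
        sub_complex = m
        mc_complex = mc_sasa_oracle(sub_complex, 0.14, 100_000, seed=1)

        def mc_part(part):
            part_model = make_model(
                m.positions[part], radii=m.radii[part],
                residue_seqs=np.arange(1, len(part) + 1),
            )
            return mc_sasa_oracle(part_model, 0.14, 100_000, seed=2)

        lost_a = mc_part(pa).sum() - mc_complex[pa].sum()
        lost_b = mc_part(pb).sum() - mc_complex[pb].sum()
        assert area == pytest.approx(0.5 * (lost_a + lost_b), rel=0.02)


class TestPerResidueDecomposition:
    def test_sums_to_twice_average_area(self, study_complex):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        pb = np.flatnonzero(study_complex.chain_ids == "L")
        per_res = per_residue_interfacial_sas(study_complex, pa, pb, n_sphere_points=480)
        avg = interfacial_area(study_complex, pa, pb, n_sphere_points=480)
        assert sum(per_res.values()) == pytest.approx(2 * avg, rel=1e-9)

    def test_all_values_non_negative(self, study_complex):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        pb = np.flatnonzero(study_complex.chain_ids == "L")
        per_res = per_residue_interfacial_sas(study_complex, pa, pb, n_sphere_points=480)
        assert all(v >= 0 for v in per_res.values())

    def test_far_side_residue_zero(self, study_complex):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        pb = np.flatnonzero(study_complex.chain_ids == "L")
        per_res = per_residue_interfacial_sas(study_complex, pa, pb, n_sphere_points=480)
        # client C-terminal residue 42 points away from the receptor helix
        touching = {k for k, v in per_res.items() if v > 0}
        assert len(touching) < len(per_res)


class TestSASHydro:
    def test_sign_structure(self, study_complex, ww_scale):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        pb = np.flatnonzero(study_complex.chain_ids == "L")
        keys = [("L", r) for r in range(25, 36)]
        res = sas_hydro(study_complex, pa, pb, keys, ww_scale, n_sphere_points=480)
        assert res.per_residue[("L", 28)] > 0  # Lys28: hydrophilic
        hydrophobic = [res.per_residue[("L", r)] for r in (31, 32, 35)]
        assert all(v <= 0 for v in hydrophobic)
        assert min(hydrophobic) < 0

    def test_split_sums_reconstruct_total(self, study_complex, ww_scale):
        pa = np.flatnonzero(study_complex.chain_ids == "R")
        pb = np.flatnonzero(study_complex.chain_ids == "L")
        keys = [("L", r) for r in range(25, 36)]
        res = sas_hydro(study_complex, pa, pb, keys, ww_scale, n_sphere_points=480)
        assert res.hydrophilic_sum >= 0 >= res.hydrophobic_sum
        assert res.hydrophilic_sum + res.hydrophobic_sum == pytest.approx(
            sum(res.per_residue.values()), abs=1e-12
        )

    def test_zero_interfacial_sas_zero_index(self, ww_scale):
        m = two_atom_pair(5.0)
        m.residue_names = np.array(["LYS", "ILE"], dtype=object)
        res = sas_hydro(m, np.array([0]), np.array([1]), [("A", 1), ("B", 2)], ww_scale)
        assert res.per_residue[("A", 1)] == 0.0
        assert res.per_residue[("B", 2)] == 0.0

    def test_gly_interface_weaker_than_lys(self, ww_scale):
        rec = build_ideal_helix("AAAAAAAA")
        for seq, name in (("GGGGGGGG", "gly"), ("KKKKKKKK", "lys")):
            lig = build_ideal_helix(seq)
            m = build_two_body_complex(rec, lig, 0.35)
            pa = np.flatnonzero(m.chain_ids == "R")
            pb = np.flatnonzero(m.chain_ids == "L")
            keys = sorted(
                {("L", int(r)) for r in m.residue_seqs[pb]}, key=lambda k: k[1]
            )
            res = sas_hydro(m, pa, pb, keys, ww_scale, n_sphere_points=480)
            if name == "gly":
                gly_net = abs(res.net)
            else:
                lys_net = abs(res.net)
        assert gly_net < 0.1 * lys_net

    def test_scale_covers_standard_residues(self, ww_scale):
        assert ww_scale["LYS"] > 0
        assert ww_scale["ILE"] < 0 and ww_scale["MET"] < 0
        with pytest.raises(KeyError):
            ww_scale["XYZ"]


class TestFloatingWindow:
    def test_constant_series_unchanged(self):
        t = np.arange(10.0)
        v = np.full(10, 3.3)
        np.testing.assert_allclose(floating_window(t, v, 4.0), v, rtol=1e-14)

    def test_window_below_sampling_is_identity(self):
        t = np.arange(0.0, 10.0)
        v = np.sin(t)
        np.testing.assert_array_equal(floating_window(t, v, 0.5), v)

    def test_two_sample_running_mean_by_hand(self):
        t = np.arange(6.0)
        v = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        out = floating_window(t, v, 1.5)
        np.testing.assert_allclose(out, [1.0, 0.0, 0.0, 0.0, 0.0, 0.0])

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            floating_window(np.arange(3.0), np.ones(3), 0.0)


class TestReplicateStats:
    def test_closed_form(self):
        mean, sem = replicate_stats([np.array([1.0]), np.array([2.0]), np.array([3.0])])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1.0 / np.sqrt(3.0))

    def test_identical_replicates_zero_sem(self):
        mean, sem = replicate_stats([np.ones(5), np.ones(7)])
        assert mean == 1.0
        assert sem == 0.0

    def test_single_replicate_flagged(self):
        mean, sem = replicate_stats([np.array([4.0, 6.0])])
        assert mean == 5.0
        assert np.isnan(sem)

    def test_burn_in_sample_count(self):
        kept = apply_burn_in(1000, 0.55)
        assert len(kept) == 450
        assert kept[0] == 550
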