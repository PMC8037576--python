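"""PDB round trips, parameter assignment and segment selection."""

import numpy as np
import pytest

from s100b_abeta.structure import (
    ParameterSet,
    PDBFormatError,
    PDBParseError,
    ParameterizationError,
    SegmentSpec,
    SelectionError,
    StructureError,
    Trajectory,
    assign_parameters,
    read_pdb_models,
    select_segment,
    write_pdb_models,
)
from s100b_abeta.synthetic import build_ideal_helix, default_parameter_set

from conftest import make_model


SINGLE_ATOM_PDB = """\
ATOM      1  CA  ALA A   1       2.900   0.000   1.000  1.00  0.00           C
END
"""


class TestReadPDB:
    def test_angstrom_to_nm_conversion(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(SINGLE_ATOM_PDB)
        traj = read_pdb_models(p)
        assert traj.n_frames == 1
        assert traj.frames[0].n_atoms == 1
        np.testing.assert_allclose(traj.frames[0].positions[0], [0.290, 0.0, 0.100])

    def test_multi_model_counts(self, tmp_path):
        helix = build_ideal_helix("ALAKEGYVAM", parameterize=False)
        traj = Trajectory(frames=[helix.copy() for _ in range(3)], times=np.arange(3.0))
        p = tmp_path / "multi.pdb"
        write_pdb_models(traj, p)
        back = read_pdb_models(p)
        assert back.n_frames == 3
        assert all(f.n_atoms == helix.n_atoms for f in back.frames)

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  ALA A   1       x.900   0.000\n")
        with pytest.raises(PDBParseError, match="line 1"):
            read_pdb_models(p)

    def test_inconsistent_model_sizes_rejected(self, tmp_path):
        lines = ["MODEL     1"]
        lines += ["ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C"]
        lines += ["ENDMDL", "MODEL     2"]
        lines += ["ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C"]
        lines += ["ATOM      2  CB  ALA A   1       2.000   0.000   0.000  1.00  0.00           C"]
        lines += ["ENDMDL"]
        p = tmp_path / "ragged.pdb"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(StructureError):
            read_pdb_models(p)


class TestWritePDB:
    def test_round_trip_preserves_coordinates(self, tmp_path):
        helix = build_ideal_helix("KLVFFAEDVG", parameterize=False)
        p = tmp_path / "rt.pdb"
        write_pdb_models(helix, p)
        back = read_pdb_models(p).frames[0]
        assert back.same_topology(helix)
        # PDB precision is 0.001 A = 1e-4 nm
        assert np.abs(back.positions - helix.positions).max() <= 1e-4 + 1e-12

    def test_empty_trajectory_rejected(self, tmp_path):
        with pytest.raises((PDBFormatError, StructureError)):
            write_pdb_models(Trajectory(frames=[], times=np.array([])), tmp_path / "x.pdb")

    def test_two_frames_two_model_blocks(self, tmp_path):
        helix = build_ideal_helix("GSNKGAIIGL", parameterize=False)
        traj = Trajectory(frames=[helix.copy(), helix.copy()], times=np.array([0.0, 1.0]))
        p = tmp_path / "two.pdb"
        write_pdb_models(traj, p)
        text = p.read_text()
        assert text.count("MODEL ") == 2
        assert text.count("ENDMDL") == 2

    def test_long_atom_name_rejected(self, tmp_path):
        m = make_model([[0, 0, 0]], names=["TOOLONG"])
        with pytest.raises(PDBFormatError):
            write_pdb_models(m, tmp_path / "x.pdb")


class TestReadGRO:
    def test_single_frame_gro_positions_in_nm(self, tmp_path):
        from s100b_abeta.structure import read_gro

        gro = tmp_path / "tiny.gro"
        gro.write_text(
            "tiny peptide\n"
            "    3\n"
            "    1ALA      N    1   0.100   0.200   0.300\n"
            "    1ALA     CA    2   0.246   0.200   0.300\n"
            "    1ALA      C    3   0.300   0.340   0.300\n"
            "   2.00000   2.00000   2.00000\n"
        )
        model = read_gro(gro)
        assert model.n_atoms == 3
        assert list(model.names) == ["N", "CA", "C"]
        np.testing.assert_allclose(model.positions[0], [0.1, 0.2, 0.3], atol=1e-6)
        np.testing.assert_allclose(model.box, [2.0, 2.0, 2.0], atol=1e-6)


class TestParameters:
    def test_full_table_assigns_all(self):
        helix = build_ideal_helix("KAMVA", parameterize=False)
        out = assign_parameters(helix, default_parameter_set())
        assert np.all(out.radii > 0)
        assert np.all(np.isfinite(out.charges))

    def test_unresolved_atom_named_in_error(self):
        m = make_model([[0, 0, 0]], names=["XX1"], residue_names=["UNK"], elements=["Xx"])
        pset = ParameterSet(by_residue_atom={("ALA", "CA"): (0.2, 0.0, 0.3, 0.4)})
        with pytest.raises(ParameterizationError, match="XX1"):
            assign_parameters(m, pset)

    def test_element_fallback_precedence(self):
        m = make_model([[0, 0, 0]], names=["CX"], residue_names=["UNK"], elements=["C"])
        pset = ParameterSet(
            by_residue_atom={("ALA", "CA"): (0.2, 0.1, 0.3, 0.4)},
            by_element={"C": 0.185},
        )
        out = assign_parameters(m, pset)
        assert out.radii[0] == pytest.approx(0.185)
        assert out.charges[0] == 0.0


class TestSegments:
    @pytest.mark.parametrize(
        "first,last,expected",
        [(25, 35, 11), (1, 24, 24), (30, 30, 1)],
    )
    def test_inclusive_residue_counts(self, study_complex, first, last, expected):
        idx = select_segment(study_complex, SegmentSpec("seg", "L", (first, last)))
        residues = {int(r) for r in study_complex.residue_seqs[idx]}
        assert len(residues) == expected

    def test_segments_partition_client_chain(self, study_complex):
        nter = select_segment(study_complex, SegmentSpec("nter", "L", (1, 24)))
        core = select_segment(study_complex, SegmentSpec("core", "L", (25, 35)))
        assert np.intersect1d(nter, core).size == 0
        covered = {int(r) for r in study_complex.residue_seqs[np.concatenate([nter, core])]}
        assert covered == set(range(1, 36))

    def test_empty_selection_raises(self, study_complex):
        with pytest.raises(SelectionError):
            select_segment(study_complex, SegmentSpec("none", "Z", (1, 5)))
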