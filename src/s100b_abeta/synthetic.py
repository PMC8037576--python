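"""Desk-scale synthetic inputs: ideal helices, two-body complexes,
pseudo-trajectories and noisy ThT aggregation traces.

These generators stand in for microsecond MD trajectories and plate-reader
data: they are reduced models (four backbone atoms plus one pseudo-sidechain
sphere per residue; rigid-body separation schedules; isotropic Gaussian
thermal noise) whose purpose is to exercise every downstream analysis with
known ground truth.  All generators are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .structure import MolecularModel, ParameterSet, Trajectory, assign_parameters

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Ideal backbone internal coordinates (nm / degrees), Engh-Huber-like.
_B_N_CA = 0.1458
_B_CA_C = 0.1525
_B_C_N = 0.1329
_B_C_O = 0.1231
_B_CA_SC = 0.1530
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_A_N_CA_SC = 110.5
_OMEGA = 180.0


def default_parameter_set() -> ParameterSet:
    """The packaged parameter table matching the reduced synthetic models."""
    with resources.as_file(
        resources.files("s100b_abeta.data").joinpath("synthetic_params.tsv")
    ) as p:
        return ParameterSet.from_tsv(p)


def _place_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from A-B-C with |CD|=bond, angle(BCD), torsion(ABCD)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(
    sequence: str,
    phi_deg: float = -57.0,
    psi_deg: float = -47.0,
    chain_id: str = "A",
    first_residue_seq: int = 1,
    parameterize: bool = True,
) -> MolecularModel:
    """Build a peptide with uniform backbone dihedrals at ideal geometry.

    Each residue carries N, CA, C, O and a single pseudo-sidechain sphere
    ``SC`` (a united sidechain placed at the C-beta position).  The default
    dihedrals (-57, -47) give a canonical alpha helix with ~0.38 nm
    consecutive CA-CA distances and ~0.15 nm rise per residue; (-120, 120)
    gives an extended strand.
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 4:
        raise ValueError("sequence must have at least 4 residues")
    for code in sequence:
        if code not in ONE_TO_THREE:
            raise ValueError(f"unknown residue code {code!r}")

    positions: list[np.ndarray] = []
    meta: list[tuple[str, str, int]] = []  # (atom name, residue_name, residue_seq)

    def add(name: str, resname: str, seq: int, pos: np.ndarray) -> None:
        positions.append(pos)
        meta.append((name, resname, seq))

    n_prev = ca_prev = c_prev = None
    for i, code in enumerate(sequence):
        resname = ONE_TO_THREE[code]
        seq = first_residue_seq + i
        if i == 0:
            n_pos = np.zeros(3)
            ca_pos = n_pos + np.array([_B_N_CA, 0.0, 0.0])
            ang = np.deg2rad(_A_N_CA_C)
            c_pos = ca_pos + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n_pos = _place_nerf(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi_deg)
            ca_pos = _place_nerf(ca_prev, c_prev, n_pos, _B_N_CA, _A_C_N_CA, _OMEGA)
            c_pos = _place_nerf(c_prev, n_pos, ca_pos, _B_CA_C, _A_N_CA_C, phi_deg)
        add("N", resname, seq, n_pos)
        add("CA", resname, seq, ca_pos)
        # pseudo-sidechain at the C-beta position (L-configuration branch)
        sc_pos = _place_nerf(c_pos, n_pos, ca_pos, _B_CA_SC, _A_N_CA_SC, 122.6)
        add("SC", resname, seq, sc_pos)
        add("C", resname, seq, c_pos)
        n_prev, ca_prev, c_prev = n_pos, ca_pos, c_pos

    # carbonyl oxygens need the next residue's N (trans carbonyl); append at end
    oxy: list[tuple[int, np.ndarray]] = []
    n_res = len(sequence)
    atoms_per_res = 4
    for i in range(n_res):
        base = i * atoms_per_res
        n_i, ca_i, c_i = positions[base], positions[base + 1], positions[base + 3]
        if i + 1 < n_res:
            n_next = positions[(i + 1) * atoms_per_res]
            # O opposite N(i+1) in the peptide plane
            o_pos = _place_nerf(n_next, ca_i, c_i, _B_C_O, _A_CA_C_O, 180.0)
        else:
            o_pos = _place_nerf(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, psi_deg + 180.0)
        oxy.append((base + 3, o_pos))

    # interleave: final atom order N, CA, SC, C, O per residue
    final_pos: list[np.ndarray] = []
    final_meta: list[tuple[str, str, int]] = []
    for i in range(n_res):
        base = i * atoms_per_res
        for off in range(atoms_per_res):
            final_pos.append(positions[base + off])
            final_meta.append(meta[base + off])
        final_pos.append(oxy[i][1])
        final_meta.append(("O", meta[base][1], meta[base][2]))

    n_atoms = len(final_pos)
    model = MolecularModel(
        serials=np.arange(1, n_atoms + 1),
        names=np.array([m[0] for m in final_meta], dtype=object),
        elements=np.array(
            [{"N": "N", "CA": "C", "C": "C", "O": "O", "SC": "C"}[m[0]] for m in final_meta],
            dtype=object,
        ),
        residue_names=np.array([m[1] for m in final_meta], dtype=object),
        residue_seqs=np.array([m[2] for m in final_meta]),
        chain_ids=np.array([chain_id] * n_atoms, dtype=object),
        positions=np.array(final_pos),
    )
    if parameterize:
        model = assign_parameters(model, default_parameter_set())
    return model


def min_interatomic_distance(model_a: MolecularModel, model_b: MolecularModel) -> float:
    from scipy.spatial.distance import cdist

    return float(cdist(model_a.positions, model_b.positions).min())


def build_two_body_complex(
    receptor: MolecularModel,
    ligand: MolecularModel,
    gap_nm: float,
    receptor_chain: str = "R",
    ligand_chain: str = "L",
) -> MolecularModel:
    """Rigidly place ``ligand`` along +x of the receptor so that the minimum
    receptor-ligand interatomic distance equals ``gap_nm`` (within 0.001 nm).

    Chains are relabelled to ``receptor_chain`` / ``ligand_chain``.
    """
    if gap_nm < 0:
        raise ValueError("gap_nm must be non-negative")
    if receptor.n_atoms == 0 or ligand.n_atoms == 0:
        raise ValueError("both partners must be non-empty")
    rec = receptor.copy()
    lig = ligand.copy()
    rec.chain_ids = np.array([receptor_chain] * rec.n_atoms, dtype=object)
    lig.chain_ids = np.array([ligand_chain] * lig.n_atoms, dtype=object)

    # centre both bodies, then bisect the +x offset of the ligand between
    # coincident centres (overlapping) and full separation
    rec.positions = rec.positions - rec.positions.mean(axis=0)
    lig.positions = lig.positions - lig.positions.mean(axis=0)

    def gap_at(offset: float) -> float:
        shifted = lig.positions + np.array([offset, 0.0, 0.0])
        from scipy.spatial.distance import cdist

        return float(cdist(rec.positions, shifted).min())

    lo = 0.0
    hi = (
        np.ptp(rec.positions, axis=0).max()
        + np.ptp(lig.positions, axis=0).max()
        + gap_nm
        + 1.0
    )
    if gap_at(lo) >= gap_nm:
        raise ValueError("bodies cannot be brought closer than the requested gap")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap_at(mid) < gap_nm:
            lo = mid
        else:
            hi = mid
    offset = hi
    achieved = gap_at(offset)
    if abs(achieved - gap_nm) > 1e-3:
        raise RuntimeError(f"gap placement failed: {achieved:.4f} vs {gap_nm:.4f} nm")
    lig.positions = lig.positions + np.array([offset, 0.0, 0.0])

    max_serial = int(rec.serials.max())
    return MolecularModel(
        serials=np.concatenate([rec.serials, lig.serials + max_serial]),
        names=np.concatenate([rec.names, lig.names]),
        elements=np.concatenate([rec.elements, lig.elements]),
        residue_names=np.concatenate([rec.residue_names, lig.residue_names]),
        residue_seqs=np.concatenate([rec.residue_seqs, lig.residue_seqs]),
        chain_ids=np.concatenate([rec.chain_ids, lig.chain_ids]),
        positions=np.vstack([rec.positions, lig.positions]),
        radii=None if rec.radii is None or lig.radii is None else np.concatenate([rec.radii, lig.radii]),
        charges=None if rec.charges is None or lig.charges is None else np.concatenate([rec.charges, lig.charges]),
        lj_sigmas=None if rec.lj_sigmas is None or lig.lj_sigmas is None else np.concatenate([rec.lj_sigmas, lig.lj_sigmas]),
        lj_epsilons=None if rec.lj_epsilons is None or lig.lj_epsilons is None else np.concatenate([rec.lj_epsilons, lig.lj_epsilons]),
    )


@dataclass
class TrajectoryRecipe:
    """Recipe for a pseudo-trajectory: thermal jitter on a base complex plus a
    rigid per-frame separation offset applied to the ligand chain (+x)."""

    base_model: MolecularModel
    n_frames: int
    thermal_noise_sd: float = 0.0  # nm, isotropic per atom per frame
    separation_schedule: np.ndarray | None = None  # nm, extra ligand offset
    ligand_chain: str = "L"
    frame_dt_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.thermal_noise_sd < 0:
            raise ValueError("thermal_noise_sd must be >= 0")
        if self.separation_schedule is not None:
            self.separation_schedule = np.asarray(self.separation_schedule, dtype=float)
            if len(self.separation_schedule) != self.n_frames:
                raise ValueError("separation_schedule length must equal n_frames")


def generate_pseudo_trajectory(recipe: TrajectoryRecipe) -> Trajectory:
    """n_frames copies of the base model with i.i.d. Gaussian coordinate noise
    and the per-frame rigid ligand offset; bit-reproducible under the seed."""
    rng = np.random.default_rng(recipe.seed)
    base = recipe.base_model
    lig_mask = base.chain_ids == recipe.ligand_chain
    frames: list[MolecularModel] = []
    times = np.arange(recipe.n_frames, dtype=float) * recipe.frame_dt_ns
    for k in range(recipe.n_frames):
        frame = base.copy()
        if recipe.separation_schedule is not None:
            frame.positions[lig_mask, 0] += recipe.separation_schedule[k]
        if recipe.thermal_noise_sd > 0:
            frame.positions = frame.positions + rng.normal(
                0.0, recipe.thermal_noise_sd, size=frame.positions.shape
            )
        frame.frame_time = float(times[k])
        frames.append(frame)
    return Trajectory(frames=frames, times=times)


@dataclass
class ThTRecipe:
    """Recipe for a synthetic ThT fluorescence trace.

    Either ``model_params`` (secondary-nucleation-dominated kinetics) or
    ``logistic`` (midpoint s, slope 1/s) defines the underlying normalized
    fibrillar-mass curve M(t) in [0, 1].  The sampled signal is
    ``baseline_value + plateau_scale * M(t) + N(0, baseline_noise_sd)``,
    acquired every ``sampling_interval`` seconds (the plate-reader cadence,
    default 400 s).
    """

    model_params: "object | None" = None  # kinetics.SecondaryNucleationParams
    logistic: tuple[float, float] | None = None  # (midpoint_s, slope_per_s)
    sampling_interval: float = 400.0
    t_end: float = 40000.0
    baseline_value: float = 100.0
    baseline_noise_sd: float = 0.0
    plateau_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if (self.model_params is None) == (self.logistic is None):
            raise ValueError("exactly one of model_params / logistic must be set")


def generate_tht_trace(recipe: ThTRecipe):
    """Sample a noisy sigmoidal ThT curve on the 400 s cadence."""
    from .kinetics import KineticTrace, model_mass_fraction

    n = int(np.floor(recipe.t_end / recipe.sampling_interval)) + 1
    times = np.arange(n, dtype=float) * recipe.sampling_interval
    if recipe.logistic is not None:
        midpoint, slope = recipe.logistic
        mass = 1.0 / (1.0 + np.exp(-slope * (times - midpoint)))
    else:
        mass = model_mass_fraction(recipe.model_params, times)
    rng = np.random.default_rng(recipe.seed)
    noise = rng.normal(0.0, recipe.baseline_noise_sd, size=n) if recipe.baseline_noise_sd > 0 else 0.0
    signal = recipe.baseline_value + recipe.plateau_scale * mass + noise
    return KineticTrace(times=times, signal=signal)


def align_principal_axis(model: MolecularModel, axis: int = 2) -> MolecularModel:
    """Rotate a copy of the model so its longest principal axis lies along
    the given coordinate axis (proper rotation, centred at the centroid)."""
    out = model.copy()
    centred = out.positions - out.positions.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    rot = vt  # rows: principal directions
    if np.linalg.det(rot) < 0:
        rot[-1] *= -1.0
    rotated = centred @ rot.T  # component 0 = longest principal axis
    cols = [0, 1, 2]
    cols[0], cols[axis] = cols[axis], cols[0]
    rotated = rotated[:, cols]
    if axis != 0:  # column swap is improper; restore handedness
        rotated[:, (set(range(3)) - {0, axis}).pop()] *= -1.0
    out.positions = rotated
    return out


def orient_residue_toward(
    model: MolecularModel,
    residue_seq: int,
    atom_name: str,
    azimuth_deg: float,
) -> MolecularModel:
    """Rotate a copy of the model about its centroid z axis so the named
    atom sits at the given azimuth in the xy plane (0 deg = +x).

    Used to point a chosen sidechain at the binding partner before the
    bodies are combined (partners are offset along x).
    """
    out = model.copy()
    centre = out.positions.mean(axis=0)
    pos = out.positions - centre
    idx = np.flatnonzero((out.residue_seqs == residue_seq) & (out.names == atom_name))
    if idx.size != 1:
        raise ValueError(f"atom {residue_seq}:{atom_name} matched {idx.size} atoms")
    x, y = pos[idx[0], 0], pos[idx[0], 1]
    rot = np.deg2rad(azimuth_deg) - np.arctan2(y, x)
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    out.positions = pos @ R.T + centre
    return out


AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"
# S100B-like helical receptor stretch, numbered 49-91 so that the binding-
# cleft triad positions (Met79, Thr82, Glu86) carry their canonical numbers.
RECEPTOR_SEQUENCE = "LEEIKEQEVVDKVMETLDNDGDGECDFQEFMAFTAMVETACHE"
RECEPTOR_FIRST_RESIDUE = 49


def default_complex(
    receptor_sequence: str = RECEPTOR_SEQUENCE,
    ligand_sequence: str = AB42_SEQUENCE,
    gap_nm: float = 0.45,
) -> MolecularModel:
    """A reduced chaperone-client complex: an S100B-like helical receptor
    chain (R, residues 49-91, with MET79/THR82/GLU86 at their canonical
    positions) side by side with the full 42-residue amyloid-beta peptide
    built helical (L, residues 1-42; Lys28 and the hydrophobic Ile31/Ile32/
    Met35 core lie in the 25-35 segment).

    Both helices are aligned on z; the receptor's Glu86 sidechain faces the
    client (+x) and the client's Lys28 sidechain faces the receptor (-x), a
    reduced mimic of the electrostatic-anchor geometry.  The default gap
    (0.45 nm minimum interatomic centre distance) corresponds to van der
    Waals contact of the pseudo-sidechain spheres."""
    receptor = align_principal_axis(
        build_ideal_helix(receptor_sequence, chain_id="R",
                          first_residue_seq=RECEPTOR_FIRST_RESIDUE)
    )
    receptor = orient_residue_toward(receptor, 86, "SC", azimuth_deg=0.0)
    ligand = align_principal_axis(
        build_ideal_helix(ligand_sequence, chain_id="L", first_residue_seq=1)
    )
    ligand = orient_residue_toward(ligand, 28, "SC", azimuth_deg=180.0)
    return build_two_body_complex(receptor, ligand, gap_nm)
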