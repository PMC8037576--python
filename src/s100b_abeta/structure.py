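"""Coordinate containers, PDB/GRO input, physical-parameter assignment and
segment selection.

Coordinates are stored internally in nanometres (MD convention: every distance
threshold in the analysis protocol is quoted in nm); PDB I/O converts to and
from angstroms.  Residue numbering is 1-based and residue ranges are inclusive
at both ends.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

NM_PER_ANGSTROM = 0.1


class PDBParseError(ValueError):
    """A PDB record could not be parsed (message names the line number)."""


class PDBFormatError(ValueError):
    """A model cannot be represented in fixed-column PDB format."""


class StructureError(ValueError):
    """Inconsistent multi-frame structure (e.g. varying atom counts)."""


class SelectionError(ValueError):
    """A segment specification resolved to an empty atom set."""


class ParameterizationError(ValueError):
    """One or more atoms could not be assigned physical parameters."""


@dataclass(frozen=True)
class Atom:
    """A single atom with coordinates (nm) and optional physical parameters.

    ``radius`` (nm), ``charge`` (e), ``lj_sigma`` (nm) and ``lj_epsilon``
    (kJ/mol) are NaN until :func:`assign_parameters` fills them in.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    radius: float = np.nan
    charge: float = np.nan
    lj_sigma: float = np.nan
    lj_epsilon: float = np.nan

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} has a non-finite or malformed position")
        if np.isfinite(self.radius) and self.radius < 0:
            raise ValueError(f"atom {self.serial} has negative radius")
        if np.isfinite(self.lj_epsilon) and self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial} has negative lj_epsilon")


@dataclass
class MolecularModel:
    """One frame: parallel arrays over atoms.

    The array representation keeps per-frame analyses (SASA, energies,
    distances) vectorised; :meth:`atom` materialises an :class:`Atom` view.
    """

    serials: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    residue_names: np.ndarray
    residue_seqs: np.ndarray
    chain_ids: np.ndarray
    positions: np.ndarray  # (n_atoms, 3), nm
    radii: np.ndarray | None = None
    charges: np.ndarray | None = None
    lj_sigmas: np.ndarray | None = None
    lj_epsilons: np.ndarray | None = None
    frame_time: float | None = None  # ns
    box: np.ndarray | None = None  # nm

    def __post_init__(self) -> None:
        n = len(self.serials)
        self.serials = np.asarray(self.serials, dtype=int)
        for attr in ("names", "elements", "residue_names", "chain_ids"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        self.residue_seqs = np.asarray(self.residue_seqs, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain_ids, self.residue_seqs, self.names))
        if len(set(keys)) != n:
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise StructureError(f"duplicate atom identity {k}")
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def atom(self, i: int) -> Atom:
        def _opt(arr: np.ndarray | None) -> float:
            return float(arr[i]) if arr is not None else np.nan

        return Atom(
            serial=int(self.serials[i]),
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_name=str(self.residue_names[i]),
            residue_seq=int(self.residue_seqs[i]),
            chain_id=str(self.chain_ids[i]),
            position=self.positions[i].copy(),
            radius=_opt(self.radii),
            charge=_opt(self.charges),
            lj_sigma=_opt(self.lj_sigmas),
            lj_epsilon=_opt(self.lj_epsilons),
        )

    def __iter__(self) -> Iterator[Atom]:
        return (self.atom(i) for i in range(self.n_atoms))

    def copy(self) -> "MolecularModel":
        kwargs = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            kwargs[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return MolecularModel(**kwargs)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain_id, residue_seq) pairs in atom order."""
        out: list[tuple[str, int]] = []
        seen: set = set()
        for c, r in zip(self.chain_ids, self.residue_seqs):
            k = (str(c), int(r))
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out

    def residue_atom_indices(self, chain_id: str, residue_seq: int) -> np.ndarray:
        mask = (self.chain_ids == chain_id) & (self.residue_seqs == residue_seq)
        return np.flatnonzero(mask)

    def same_topology(self, other: "MolecularModel") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.names, other.names)
            and np.array_equal(self.residue_seqs, other.residue_seqs)
            and np.array_equal(self.chain_ids, other.chain_ids)
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, with strictly increasing times (ns)."""

    frames: list[MolecularModel]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise StructureError("len(times) != len(frames)")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")
        if self.frames:
            first = self.frames[0]
            for i, fr in enumerate(self.frames[1:], start=1):
                if not fr.same_topology(first):
                    raise StructureError(f"frame {i} does not share the topology of frame 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[MolecularModel]:
        return iter(self.frames)


@dataclass(frozen=True)
class SegmentSpec:
    """A named residue-range selection, inclusive at both ends.

    The two S100B protomers are distinguished by chain ID rather than by a
    residue-number offset; peptide segments such as the amyloid-beta 25-35
    core and the 1-24 N-terminus are expressed as ranges on the peptide chain.
    """

    name: str
    chain_id: str
    residue_range: tuple[int, int]

    def __post_init__(self) -> None:
        first, last = self.residue_range
        if first > last:
            raise ValueError(f"segment {self.name!r}: first residue {first} > last {last}")


@dataclass
class ParameterSet:
    """Per-atom physical parameters keyed by (residue_name, atom_name).

    Lookup precedence: exact (residue, atom) key, then element fallback
    (radius only; charge and LJ default to zero), then failure.
    """

    by_residue_atom: dict[tuple[str, str], tuple[float, float, float, float]]
    by_element: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, (radius, *_rest) in self.by_residue_atom.items():
            if not radius > 0:
                raise ValueError(f"non-positive radius for {key}")
        for elem, radius in self.by_element.items():
            if not radius > 0:
                raise ValueError(f"non-positive fallback radius for element {elem!r}")

    def resolve(self, residue_name: str, atom_name: str, element: str) -> tuple[float, float, float, float]:
        key = (residue_name, atom_name)
        if key in self.by_residue_atom:
            return self.by_residue_atom[key]
        if element in self.by_element:
            return (self.by_element[element], 0.0, 0.0, 0.0)
        raise KeyError(key)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParameterSet":
        """Read a table with columns residue_name, atom_name, radius_nm,
        charge_e, sigma_nm, epsilon_kj.  Rows with residue_name ``*`` are
        element fallbacks whose atom_name column holds the element symbol."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"residue_name", "atom_name", "radius_nm", "charge_e", "sigma_nm", "epsilon_kj"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parameter table {path} missing columns {sorted(missing)}")
        by_ra: dict[tuple[str, str], tuple[float, float, float, float]] = {}
        by_el: dict[str, float] = {}
        for row in df.itertuples(index=False):
            values = (
                float(row.radius_nm),
                float(row.charge_e),
                float(row.sigma_nm),
                float(row.epsilon_kj),
            )
            if row.residue_name == "*":
                by_el[str(row.atom_name)] = values[0]
            else:
                by_ra[(str(row.residue_name), str(row.atom_name))] = values
        return cls(by_residue_atom=by_ra, by_element=by_el)


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column, multi-model)
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    two = stripped[:2].upper()
    if two in {"CL", "BR", "ZN", "CA", "NA", "MG", "FE", "MN"} and len(stripped) <= 2:
        return two.capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        return {
            "serial": int(line[6:11]),
            "name": line[12:16].strip(),
            "residue_name": line[17:20].strip(),
            "chain_id": line[21].strip() or " ",
            "residue_seq": int(line[22:26]),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "element": line[76:78].strip() if len(line) >= 78 else "",
        }
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc


def read_pdb_models(path: str | Path, frame_dt_ns: float = 1.0) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Each MODEL/ENDMDL block becomes one frame; a file without MODEL records
    yields a single frame.  Coordinates are converted angstrom -> nm.  Frame
    times are ``i * frame_dt_ns``.
    """
    path = Path(path)
    frames: list[MolecularModel] = []
    current: list[dict] | None = None
    saw_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                if current:
                    frames.append(_records_to_model(current))
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(_records_to_model(current))
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    current = []
                current.append(_parse_atom_line(line, lineno))
    if current:
        frames.append(_records_to_model(current))
    if not frames:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    n0 = frames[0].n_atoms
    for i, fr in enumerate(frames):
        if fr.n_atoms != n0:
            raise StructureError(
                f"{path}: model {i + 1} has {fr.n_atoms} atoms, expected {n0}"
            )
    times = np.arange(len(frames), dtype=float) * frame_dt_ns
    for t, fr in zip(times, frames):
        fr.frame_time = float(t)
    return Trajectory(frames=frames, times=times)


def _records_to_model(records: list[dict]) -> MolecularModel:
    return MolecularModel(
        serials=np.array([r["serial"] for r in records]),
        names=np.array([r["name"] for r in records], dtype=object),
        elements=np.array(
            [r["element"] or _guess_element(r["name"]) for r in records], dtype=object
        ),
        residue_names=np.array([r["residue_name"] for r in records], dtype=object),
        residue_seqs=np.array([r["residue_seq"] for r in records]),
        chain_ids=np.array([r["chain_id"] for r in records], dtype=object),
        positions=np.array([[r["x"], r["y"], r["z"]] for r in records]) * NM_PER_ANGSTROM,
    )


def write_pdb_models(trajectory: Trajectory | MolecularModel, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (coordinates in angstrom)."""
    if isinstance(trajectory, MolecularModel):
        trajectory = Trajectory(frames=[trajectory], times=np.array([0.0]))
    if trajectory.n_frames == 0:
        raise PDBFormatError("cannot write an empty trajectory")
    path = Path(path)
    lines: list[str] = []
    for m, frame in enumerate(trajectory.frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i in range(frame.n_atoms):
            name = str(frame.names[i])
            if len(name) > 4:
                raise PDBFormatError(f"atom name {name!r} exceeds 4 characters")
            seq = int(frame.residue_seqs[i])
            if seq > 9999 or seq < -999:
                raise PDBFormatError(f"residue_seq {seq} out of PDB range")
            serial = int(frame.serials[i]) % 100000
            # element-style justification: names of <4 chars start in column 14
            namef = name if len(name) == 4 else f" {name:<3s}"
            x, y, z = frame.positions[i] / NM_PER_ANGSTROM
            lines.append(
                f"ATOM  {serial:5d} {namef}{'':1s}{str(frame.residue_names[i]):>3s} "
                f"{str(frame.chain_ids[i]):1s}{seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{str(frame.elements[i]):>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_gro(path: str | Path) -> MolecularModel:
    """Read a single-frame GROMACS GRO file (coordinates already in nm)."""
    import mdtraj

    traj = mdtraj.load(str(path))
    top = traj.topology
    n = top.n_atoms
    serials = np.arange(1, n + 1)
    names, elements, resnames, resseqs, chains = [], [], [], [], []
    for atom in top.atoms:
        names.append(atom.name)
        elements.append(atom.element.symbol if atom.element is not None else _guess_element(atom.name))
        resnames.append(atom.residue.name)
        resseqs.append(atom.residue.resSeq)
        chains.append(chr(ord("A") + (atom.residue.chain.index % 26)))
    box = None
    if traj.unitcell_lengths is not None:
        box = np.asarray(traj.unitcell_lengths[0], dtype=float)
    return MolecularModel(
        serials=serials,
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_seqs=np.array(resseqs),
        chain_ids=np.array(chains, dtype=object),
        positions=np.asarray(traj.xyz[0], dtype=float),
        box=box,
    )


# ---------------------------------------------------------------------------
# Parameter assignment and segment selection
# ---------------------------------------------------------------------------

def assign_parameters(model: MolecularModel, parameter_set: ParameterSet) -> MolecularModel:
    """Return a copy of ``model`` with radius/charge/LJ parameters attached.

    All unresolved atoms are collected and reported together before failing.
    """
    n = model.n_atoms
    radii = np.empty(n)
    charges = np.empty(n)
    sigmas = np.empty(n)
    epsilons = np.empty(n)
    unresolved: list[str] = []
    for i in range(n):
        try:
            radii[i], charges[i], sigmas[i], epsilons[i] = parameter_set.resolve(
                str(model.residue_names[i]), str(model.names[i]), str(model.elements[i])
            )
        except KeyError:
            unresolved.append(
                f"{model.chain_ids[i]}/{model.residue_names[i]}{model.residue_seqs[i]}/{model.names[i]}"
            )
    if unresolved:
        raise ParameterizationError(
            f"{len(unresolved)} atom(s) without parameters: {', '.join(unresolved)}"
        )
    out = model.copy()
    out.radii, out.charges, out.lj_sigmas, out.lj_epsilons = radii, charges, sigmas, epsilons
    return out


def select_segment(model: MolecularModel, spec: SegmentSpec) -> np.ndarray:
    """Atom indices of all residues in the (inclusive) range on the chain."""
    first, last = spec.residue_range
    mask = (
        (model.chain_ids == spec.chain_id)
        & (model.residue_seqs >= first)
        & (model.residue_seqs <= last)
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(
            f"segment {spec.name!r} (chain {spec.chain_id}, residues {first}-{last}) "
            "selects no atoms"
        )
    return idx


def select_chain(model: MolecularModel, chain_id: str) -> np.ndarray:
    idx = np.flatnonzero(model.chain_ids == chain_id)
    if idx.size == 0:
        raise SelectionError(f"chain {chain_id!r} selects no atoms")
    return idx
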