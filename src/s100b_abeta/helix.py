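"""Alpha-helix assignment from backbone geometry.

Uses the Kabsch-Sander electrostatic hydrogen-bond criterion: for a donor
amide (N-H) and an acceptor carbonyl (C=O),

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol, r in A,

a bond when E < -0.5 kcal/mol.  Amide hydrogens are built geometrically
(1.0 A from N, opposite the bisector of C(prev)-N and CA-N) when absent,
which is the norm for united-atom models.  A residue is helical when it lies
inside two consecutive i -> i+4 hydrogen-bonded turns (the minimal
alpha-helix rule); 3-10 and pi helices are not counted by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import MolecularModel, SegmentSpec, Trajectory

KS_Q = 0.084 * 332.0  # kcal/mol * A
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
CHAIN_BREAK_NM = 0.45  # consecutive CA-CA beyond this = break
_NM_TO_A = 10.0


@dataclass
class SecondaryStructureFrame:
    """Per-residue helix labels for one frame."""

    residue_keys: list[tuple[str, int]]
    is_helix: np.ndarray

    def helical_fraction(self, keys: list[tuple[str, int]] | None = None) -> float:
        if keys is None:
            return float(np.mean(self.is_helix)) if len(self.is_helix) else 0.0
        lookup = dict(zip(self.residue_keys, self.is_helix))
        flags = [bool(lookup.get(k, False)) for k in keys]
        return float(np.mean(flags)) if flags else 0.0


def _backbone_table(frame: MolecularModel) -> dict[tuple[str, int], dict[str, np.ndarray]]:
    table: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for i in range(frame.n_atoms):
        name = str(frame.names[i])
        if name in ("N", "CA", "C", "O", "H", "HN"):
            key = (str(frame.chain_ids[i]), int(frame.residue_seqs[i]))
            table.setdefault(key, {})["H" if name == "HN" else name] = frame.positions[i]
    return table


def _amide_hydrogen(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Geometric N-H: 1.0 A from N, opposite the bisector of C(prev)-N-CA."""
    u = n - c_prev
    u /= np.linalg.norm(u)
    v = n - ca
    v /= np.linalg.norm(v)
    d = u + v
    d /= np.linalg.norm(d)
    return n + 0.10 * d  # 1.0 A in nm


def backbone_hbond_energy(
    donor: dict[str, np.ndarray],
    acceptor: dict[str, np.ndarray],
    donor_prev_c: np.ndarray | None = None,
) -> float:
    """Kabsch-Sander energy (kcal/mol) of donor N-H ... O=C acceptor.

    ``donor`` needs N, CA (and H, otherwise built from ``donor_prev_c``);
    ``acceptor`` needs C and O.  Distances are evaluated in angstroms.
    """
    n = donor["N"]
    if "H" in donor:
        h = donor["H"]
    else:
        if donor_prev_c is None:
            raise ValueError("cannot build amide H without the previous residue's C")
        h = _amide_hydrogen(n, donor["CA"], donor_prev_c)
    c, o = acceptor["C"], acceptor["O"]

    def dist(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.linalg.norm(a - b)) * _NM_TO_A

    return KS_Q * (1.0 / dist(o, n) + 1.0 / dist(c, h) - 1.0 / dist(o, h) - 1.0 / dist(c, n))


def assign_helix(
    frame: MolecularModel,
    energy_cutoff: float = HBOND_ENERGY_CUTOFF,
) -> SecondaryStructureFrame:
    """Label each residue helix/other by the minimal-alpha-helix rule.

    Chains shorter than 5 residues cannot form an i -> i+4 bond and are
    labelled other.  Pairs across a chain break (consecutive CA-CA distance
    > 0.45 nm) are skipped.
    """
    table = _backbone_table(frame)
    keys = [k for k in frame.residue_keys() if k in table]
    is_helix = np.zeros(len(keys), dtype=bool)

    by_chain: dict[str, list[tuple[str, int]]] = {}
    for k in keys:
        by_chain.setdefault(k[0], []).append(k)

    key_pos = {k: i for i, k in enumerate(keys)}
    for chain_keys in by_chain.values():
        chain_keys.sort(key=lambda k: k[1])
        m = len(chain_keys)
        if m < 5:
            continue

        def broken(i: int, j: int) -> bool:
            # any consecutive CA-CA gap within [i, j] exceeding the break limit
            for t in range(i, j):
                a, b = table[chain_keys[t]], table[chain_keys[t + 1]]
                if "CA" not in a or "CA" not in b:
                    return True
                if chain_keys[t + 1][1] != chain_keys[t][1] + 1:
                    return True
                if np.linalg.norm(a["CA"] - b["CA"]) > CHAIN_BREAK_NM:
                    return True
            return False

        turn4 = np.zeros(m, dtype=bool)  # turn4[i]: CO(i) ... HN(i+4)
        for i in range(m - 4):
            acc = table[chain_keys[i]]
            don = table[chain_keys[i + 4]]
            if not {"C", "O"} <= set(acc) or "N" not in don or "CA" not in don:
                continue
            if broken(i, i + 4):
                continue
            prev_c = table[chain_keys[i + 3]].get("C")
            try:
                e = backbone_hbond_energy(don, acc, donor_prev_c=prev_c)
            except ValueError:
                continue
            turn4[i] = e < energy_cutoff
        for i in range(m - 5):
            if turn4[i] and turn4[i + 1]:
                for j in range(i + 1, i + 5):
                    is_helix[key_pos[chain_keys[j]]] = True
    return SecondaryStructureFrame(residue_keys=keys, is_helix=is_helix)


def helicity_series(
    trajectory: Trajectory,
    segments: dict[str, list[tuple[str, int]]],
) -> pd.DataFrame:
    """Helical fraction per frame for each named segment.

    ``segments`` maps a segment name to its (chain, residue_seq) keys; use
    :func:`segment_keys` to build them from a :class:`SegmentSpec`.
    """
    rows = {name: np.empty(trajectory.n_frames) for name in segments}
    for k, frame in enumerate(trajectory):
        ss = assign_helix(frame)
        for name, keys in segments.items():
            rows[name][k] = ss.helical_fraction(keys)
    df = pd.DataFrame(rows, index=trajectory.times)
    df.index.name = "time_ns"
    return df


def segment_keys(spec: SegmentSpec) -> list[tuple[str, int]]:
    first, last = spec.residue_range
    return [(spec.chain_id, r) for r in range(first, last + 1)]
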