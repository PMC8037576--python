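"""Solvent-accessible surface area by the Shrake-Rupley method.

A deterministic spherical Fibonacci lattice replaces the classic random test
points so that every result is exactly reproducible.  The probe radius
defaults to 0.14 nm (water).  Hydrogens are excluded from both scoring and
occlusion by default (heavy-atom SASA); a flag includes them.

Tie rule: a test point exactly on a neighbouring expanded sphere counts as
accessible (burial requires a strictly smaller distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure import MolecularModel

DEFAULT_PROBE_NM = 0.14
DEFAULT_N_POINTS = 960


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere lattice (n, 3); deterministic in n."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    # offset lattice: z strictly inside (-1, 1)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SASAResult:
    """Per-atom and per-residue accessible areas, nm^2.

    ``per_atom_area`` is full-length over the model's atoms; atoms outside the
    scored subset hold zero.  ``per_residue_area`` maps (chain_id,
    residue_seq) to the sum over its scored member atoms.
    """

    per_atom_area: np.ndarray
    per_residue_area: dict[tuple[str, int], float]
    total: float
    probe_radius: float
    n_sphere_points: int
    subset: np.ndarray

    def residue_area(self, chain_id: str, residue_seq: int) -> float:
        return self.per_residue_area.get((chain_id, residue_seq), 0.0)


def _resolve_subset(
    model: MolecularModel,
    atom_subset: np.ndarray | None,
    include_hydrogens: bool,
) -> np.ndarray:
    if atom_subset is None:
        subset = np.arange(model.n_atoms)
    else:
        subset = np.asarray(atom_subset, dtype=int)
        if subset.size == 0:
            raise ValueError("atom subset is empty")
    if not include_hydrogens:
        heavy = np.array([model.elements[i] != "H" for i in subset])
        subset = subset[heavy]
        if subset.size == 0:
            raise ValueError("atom subset contains only hydrogens")
    return subset


def compute_sasa(
    model: MolecularModel,
    atom_subset: np.ndarray | None = None,
    probe_radius: float = DEFAULT_PROBE_NM,
    n_sphere_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = False,
) -> SASAResult:
    """Shrake-Rupley SASA of ``atom_subset`` (default: all heavy atoms).

    The subset is both the scored set and the occluding set, so passing a
    partner's atom indices yields that partner's SASA "in isolation" at the
    complex coordinates.  Per-atom area is
    ``4*pi*(r_i + probe)^2 * accessible_fraction`` on the lattice.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_sphere_points < 60:
        raise ValueError("n_sphere_points must be >= 60")
    if model.radii is None:
        raise ValueError("model has no radii; run assign_parameters first")
    subset = _resolve_subset(model, atom_subset, include_hydrogens)

    pos = model.positions[subset]
    expanded = model.radii[subset] + probe_radius
    if np.any(~np.isfinite(expanded)) or np.any(model.radii[subset] < 0):
        raise ValueError("invalid radii in subset")
    lattice = fibonacci_sphere(n_sphere_points)

    r_max = expanded.max()
    tree = cKDTree(pos)
    neighbor_lists = tree.query_ball_point(pos, expanded + r_max)
    per_atom = np.zeros(model.n_atoms)
    for k, i in enumerate(subset):
        ri = expanded[k]
        neighbors = [j for j in neighbor_lists[k] if j != k]
        # prune to spheres that can actually intersect the expanded surface
        if neighbors:
            nb = np.asarray(neighbors)
            d_centre = np.linalg.norm(pos[nb] - pos[k], axis=1)
            nb = nb[d_centre < ri + expanded[nb]]
        else:
            nb = np.empty(0, dtype=int)
        if nb.size:
            pts = pos[k] + ri * lattice
            d2 = cdist(pts, pos[nb], "sqeuclidean")
            # strict inequality: boundary points stay accessible
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * ri * ri * frac

    per_res: dict[tuple[str, int], float] = {}
    for i in subset:
        key = (str(model.chain_ids[i]), int(model.residue_seqs[i]))
        per_res[key] = per_res.get(key, 0.0) + per_atom[i]
    return SASAResult(
        per_atom_area=per_atom,
        per_residue_area=per_res,
        total=float(per_atom.sum()),
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
        subset=subset,
    )


def sasa_in_isolation(
    model: MolecularModel,
    part_indices: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_NM,
    n_sphere_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = False,
) -> SASAResult:
    """SASA of a subset as if only its atoms existed (coordinates unchanged)."""
    part_indices = np.asarray(part_indices, dtype=int)
    if part_indices.size == 0:
        raise ValueError("part_indices is empty")
    return compute_sasa(
        model,
        atom_subset=part_indices,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
        include_hydrogens=include_hydrogens,
    )
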