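"""Shared fixtures: bare-model factories and small reference systems."""

from __future__ import annotations

import numpy as np
import pytest

from s100b_abeta.structure import MolecularModel


def make_model(
    positions,
    radii=None,
    charges=None,
    lj_sigmas=None,
    lj_epsilons=None,
    chain_ids=None,
    residue_seqs=None,
    residue_names=None,
    names=None,
    elements=None,
) -> MolecularModel:
    """Build a minimal parameterized model from raw arrays."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    model = MolecularModel(
        serials=np.arange(1, n + 1),
        names=np.array(names if names is not None else [f"X{i}" for i in range(n)], dtype=object),
        elements=np.array(elements if elements is not None else ["C"] * n, dtype=object),
        residue_names=np.array(residue_names if residue_names is not None else ["UNK"] * n, dtype=object),
        residue_seqs=np.array(residue_seqs if residue_seqs is not None else np.arange(1, n + 1)),
        chain_ids=np.array(chain_ids if chain_ids is not None else ["A"] * n, dtype=object),
        positions=positions,
    )
    model.radii = np.asarray(radii, dtype=float) if radii is not None else np.full(n, 0.15)
    model.charges = np.asarray(charges, dtype=float) if charges is not None else np.zeros(n)
    model.lj_sigmas = np.asarray(lj_sigmas, dtype=float) if lj_sigmas is not None else np.zeros(n)
    model.lj_epsilons = np.asarray(lj_epsilons, dtype=float) if lj_epsilons is not None else np.zeros(n)
    return model


def random_cluster(n_atoms: int, seed: int, box: float = 1.4) -> MolecularModel:
    """Seeded random atom cluster with radii in [0.1, 0.2] nm."""
    rng = np.random.default_rng(seed)
    return make_model(
        rng.uniform(0.0, box, size=(n_atoms, 3)),
        radii=rng.uniform(0.1, 0.2, size=n_atoms),
    )


def mc_sasa_oracle(model: MolecularModel, probe: float, n_samples: int, seed: int) -> np.ndarray:
    """Independent Monte-Carlo SASA: uniform random points on each expanded
    sphere, accessibility checked against every other sphere by brute force."""
    rng = np.random.default_rng(seed)
    pos = model.positions
    expanded = model.radii + probe
    out = np.zeros(len(pos))
    chunk = 100_000
    for i in range(len(pos)):
        others = [j for j in range(len(pos)) if j != i]
        # prune spheres that cannot reach the surface of sphere i
        others = [
            j for j in others
            if np.linalg.norm(pos[j] - pos[i]) < expanded[i] + expanded[j]
        ]
        n_acc = 0
        done = 0
        while done < n_samples:
            m = min(chunk, n_samples - done)
            v = rng.normal(size=(m, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            pts = pos[i] + expanded[i] * v
            acc = np.ones(m, dtype=bool)
            for j in others:
                d2 = np.einsum("ij,ij->i", pts - pos[j], pts - pos[j])
                acc &= d2 >= expanded[j] ** 2
            n_acc += int(acc.sum())
            done += m
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * n_acc / n_samples
    return out


@pytest.fixture(scope="session")
def study_complex():
    """The default reduced chaperone-client complex (built once per session)."""
    from s100b_abeta.synthetic import default_complex

    return default_complex()


@pytest.fixture(scope="session")
def ww_scale():
    from s100b_abeta.interface import HydrophobicityScale

    return HydrophobicityScale.wimley_white()
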