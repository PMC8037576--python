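"""Interfacial-area and hydrophobicity-index (SAS^hydro) profiling.

The interfacial area between two partners is the SASA each partner loses on
complex formation, averaged over the two mappings::

    area = 1/2 [ (SASA_A,alone - SASA_A,complex) + (SASA_B,alone - SASA_B,complex) ]

computed at identical coordinates (partner "alone" means occluders restricted
to that partner).  The per-residue interfacial SAS weighted by the
Wimley-White interface score gives the SAS^hydro index, whose sign separates
hydrophilic (positive) from hydrophobic (negative) contributions.

Equilibrium statistics follow the replicate convention: per-replicate means
over the equilibrated segment first, then mean and standard error of the mean
across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE_NM, compute_sasa
from .structure import MolecularModel, Trajectory


@dataclass
class HydrophobicityScale:
    """Residue (3-letter) -> score in kcal/mol; positive = hydrophilic."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        standard = {
            "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
            "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        }
        missing = standard - set(self.scores)
        if missing:
            raise ValueError(f"scale missing residues: {sorted(missing)}")
        if not (self.scores["LYS"] > 0 and self.scores["ILE"] < 0 and self.scores["MET"] < 0):
            raise ValueError("scale violates the expected hydrophilic/hydrophobic signs")

    def __getitem__(self, residue_name: str) -> float:
        try:
            return self.scores[residue_name]
        except KeyError:
            raise KeyError(f"residue {residue_name!r} absent from hydrophobicity scale")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HydrophobicityScale":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(scores=dict(zip(df["residue"], df["score_kcal_mol"].astype(float))))

    @classmethod
    def wimley_white(cls) -> "HydrophobicityScale":
        """The packaged Wimley-White interface scale (charged Asp/Glu/Lys/Arg)."""
        with resources.as_file(
            resources.files("s100b_abeta.data").joinpath("wimley_white_interface.tsv")
        ) as p:
            return cls.from_tsv(p)


@dataclass
class AnalysisConfig:
    """Equilibration and smoothing conventions.

    ``burn_in_fraction`` of each replicate is discarded before equilibrium
    statistics (0.55 mirrors discarding the first 550 ns of a 1000 ns run);
    time series are smoothed with a trailing ``window_ns`` floating window
    (default 100 ns).
    """

    burn_in_fraction: float = 0.55
    window_ns: float = 100.0
    replicate_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.window_ns <= 0:
            raise ValueError("window_ns must be positive")


def _partner_sasas(
    frame: MolecularModel,
    part_a: np.ndarray,
    part_b: np.ndarray,
    probe_radius: float,
    n_sphere_points: int,
):
    part_a = np.asarray(part_a, dtype=int)
    part_b = np.asarray(part_b, dtype=int)
    if part_a.size == 0 or part_b.size == 0:
        raise ValueError("both partners must be non-empty")
    if np.intersect1d(part_a, part_b).size:
        raise ValueError("partners overlap")
    union = np.concatenate([part_a, part_b])
    kw = dict(probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    in_complex = compute_sasa(frame, atom_subset=union, **kw)
    alone_a = compute_sasa(frame, atom_subset=part_a, **kw)
    alone_b = compute_sasa(frame, atom_subset=part_b, **kw)
    return in_complex, alone_a, alone_b


def interfacial_area(
    frame: MolecularModel,
    part_a: np.ndarray,
    part_b: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_NM,
    n_sphere_points: int = DEFAULT_N_POINTS,
) -> float:
    """Both-surface-averaged interfacial area (nm^2) of one frame."""
    in_complex, alone_a, alone_b = _partner_sasas(
        frame, part_a, part_b, probe_radius, n_sphere_points
    )
    part_a = np.asarray(part_a, dtype=int)
    part_b = np.asarray(part_b, dtype=int)
    lost_a = alone_a.per_atom_area[part_a].sum() - in_complex.per_atom_area[part_a].sum()
    lost_b = alone_b.per_atom_area[part_b].sum() - in_complex.per_atom_area[part_b].sum()
    return float(0.5 * (lost_a + lost_b))


def per_residue_interfacial_sas(
    frame: MolecularModel,
    part_a: np.ndarray,
    part_b: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_NM,
    n_sphere_points: int = DEFAULT_N_POINTS,
) -> dict[tuple[str, int], float]:
    """Per-residue SASA lost on complex formation (nm^2), for every residue
    of both partners.

    With the shared deterministic lattice, burial can only grow when
    occluders are added, so every value is exactly >= 0 and the values sum to
    twice the averaged interfacial area.
    """
    in_complex, alone_a, alone_b = _partner_sasas(
        frame, part_a, part_b, probe_radius, n_sphere_points
    )
    out: dict[tuple[str, int], float] = {}
    for alone in (alone_a, alone_b):
        for key, area in alone.per_residue_area.items():
            diff = area - in_complex.per_residue_area.get(key, 0.0)
            out[key] = max(diff, 0.0)  # clamp quadrature noise; exact lattice makes this a no-op
    return out


@dataclass
class SASHydroResult:
    """Per-residue SAS^hydro indices (nm^2 * kcal/mol) and their sign split."""

    per_residue: dict[tuple[str, int], float]
    hydrophilic_sum: float
    hydrophobic_sum: float

    @property
    def net(self) -> float:
        return self.hydrophilic_sum + self.hydrophobic_sum


def sas_hydro(
    frame: MolecularModel,
    part_a: np.ndarray,
    part_b: np.ndarray,
    segment_keys: list[tuple[str, int]],
    scale: HydrophobicityScale,
    use_absolute_sasa: bool = False,
    probe_radius: float = DEFAULT_PROBE_NM,
    n_sphere_points: int = DEFAULT_N_POINTS,
) -> SASHydroResult:
    """SAS^hydro index over ``segment_keys`` ((chain, residue_seq) pairs).

    Each residue's interfacial SAS (or, with ``use_absolute_sasa``, its
    absolute in-complex SASA) is multiplied by its Wimley-White score;
    positive products accumulate into ``hydrophilic_sum`` and negative ones
    into ``hydrophobic_sum``.
    """
    resnames = {
        (str(c), int(r)): str(n)
        for c, r, n in zip(frame.chain_ids, frame.residue_seqs, frame.residue_names)
    }
    if use_absolute_sasa:
        union = np.concatenate([np.asarray(part_a, int), np.asarray(part_b, int)])
        sas = compute_sasa(
            frame, atom_subset=union, probe_radius=probe_radius, n_sphere_points=n_sphere_points
        ).per_residue_area
    else:
        sas = per_residue_interfacial_sas(
            frame, part_a, part_b, probe_radius=probe_radius, n_sphere_points=n_sphere_points
        )
    per_residue: dict[tuple[str, int], float] = {}
    phil = phob = 0.0
    for key in segment_keys:
        if key not in resnames:
            raise KeyError(f"residue {key} not present in frame")
        score = scale[resnames[key]]
        value = sas.get(key, 0.0) * score
        per_residue[key] = value
        if value > 0:
            phil += value
        else:
            phob += value
    return SASHydroResult(per_residue=per_residue, hydrophilic_sum=phil, hydrophobic_sum=phob)


def floating_window(times: np.ndarray, values: np.ndarray, window: float) -> np.ndarray:
    """Trailing (causal) mean over samples in (t - window, t]; same length."""
    if window <= 0:
        raise ValueError("window must be positive")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape:
        raise ValueError("times and values must be 1-D and congruent")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    out = np.empty_like(values)
    start = 0
    for i, t in enumerate(times):
        while times[start] <= t - window:
            start += 1
        out[i] = values[start:i + 1].mean()
    return out


def apply_burn_in(n_samples: int, burn_in_fraction: float) -> np.ndarray:
    """Indices of the equilibrated tail: drop the first floor(f*n) samples.

    A fraction of 0.55 on a 1000-sample replicate keeps exactly the last 450
    samples (the equilibrated segment convention).
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    n_drop = int(np.floor(burn_in_fraction * n_samples))
    return np.arange(n_drop, n_samples)


def replicate_stats(replicate_values: list[np.ndarray]) -> tuple[float, float]:
    """Mean and SEM over replicate means.

    Per-replicate means are taken first; the reported mean is their average
    and the SEM is their sample standard deviation divided by sqrt(n).  With
    a single replicate the SEM is undefined and returned as NaN.
    """
    if len(replicate_values) == 0:
        raise ValueError("need at least one replicate")
    means = np.array([float(np.mean(np.asarray(v, dtype=float))) for v in replicate_values])
    if len(means) == 1:
        return float(means[0]), float("nan")
    sem = float(np.std(means, ddof=1) / np.sqrt(len(means)))
    return float(np.mean(means)), sem


@dataclass
class InterfaceProfile:
    """Time series of interfacial area and SAS^hydro sums for one replicate."""

    times: np.ndarray
    area_nm2: np.ndarray
    hydrophilic_sum: np.ndarray
    hydrophobic_sum: np.ndarray
    per_residue_sashydro: pd.DataFrame  # frames x residues
    per_residue_interfacial_sas: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "area_nm2": self.area_nm2,
                "hydrophilic_sum": self.hydrophilic_sum,
                "hydrophobic_sum": self.hydrophobic_sum,
            }
        )


def profile_trajectory(
    trajectory: Trajectory,
    part_a: np.ndarray,
    part_b: np.ndarray,
    segment_keys: list[tuple[str, int]],
    scale: HydrophobicityScale | None = None,
    probe_radius: float = DEFAULT_PROBE_NM,
    n_sphere_points: int = DEFAULT_N_POINTS,
) -> InterfaceProfile:
    """Per-frame interfacial area and SAS^hydro over a trajectory."""
    scale = scale or HydrophobicityScale.wimley_white()
    areas = np.empty(trajectory.n_frames)
    phil = np.empty(trajectory.n_frames)
    phob = np.empty(trajectory.n_frames)
    rows_sh: list[dict] = []
    rows_is: list[dict] = []
    for k, frame in enumerate(trajectory):
        isas = per_residue_interfacial_sas(
            frame, part_a, part_b, probe_radius=probe_radius, n_sphere_points=n_sphere_points
        )
        areas[k] = 0.5 * sum(isas.values())
        sh = sas_hydro(
            frame, part_a, part_b, segment_keys, scale,
            probe_radius=probe_radius, n_sphere_points=n_sphere_points,
        )
        phil[k], phob[k] = sh.hydrophilic_sum, sh.hydrophobic_sum
        rows_sh.append({f"{c}:{r}": v for (c, r), v in sh.per_residue.items()})
        rows_is.append({f"{c}:{r}": v for (c, r), v in isas.items()})
    return InterfaceProfile(
        times=trajectory.times.copy(),
        area_nm2=areas,
        hydrophilic_sum=phil,
        hydrophobic_sum=phob,
        per_residue_sashydro=pd.DataFrame(rows_sh, index=trajectory.times),
        per_residue_interfacial_sas=pd.DataFrame(rows_is, index=trajectory.times),
    )
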