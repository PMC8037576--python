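"""Minimum-distance contact protocol.

A single probe atom (by default the sidechain nitrogen of the client lysine)
is tracked against every receptor residue: per-frame minimum distances, a
0.6 nm screen that discards weak or non-existent interactions, the fraction
of equilibrated frames within 0.35 nm ("persistence"), and pooled
probability-density histograms over replicates.  All thresholds are
inclusive (<=).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import MolecularModel, Trajectory


@dataclass(frozen=True)
class ContactConfig:
    """Probe selection and distance thresholds (nm)."""

    probe_chain: str = "L"
    probe_residue_seq: int = 28
    probe_atom_name: str = "NZ"
    screen_cutoff: float = 0.6
    strong_cutoff: float = 0.35
    histogram_bin: float = 0.01
    relevance_threshold: float = 0.1  # min persistence for "relevant" residues

    def __post_init__(self) -> None:
        if not 0 < self.strong_cutoff <= self.screen_cutoff:
            raise ValueError("require 0 < strong_cutoff <= screen_cutoff")
        if self.histogram_bin <= 0:
            raise ValueError("histogram_bin must be positive")


class ProbeError(ValueError):
    """The probe atom is missing from a frame."""


def _probe_index(frame: MolecularModel, config: ContactConfig) -> int:
    mask = (
        (frame.chain_ids == config.probe_chain)
        & (frame.residue_seqs == config.probe_residue_seq)
        & (frame.names == config.probe_atom_name)
    )
    idx = np.flatnonzero(mask)
    if idx.size != 1:
        raise ProbeError(
            f"probe {config.probe_chain}:{config.probe_residue_seq}:{config.probe_atom_name} "
            f"matched {idx.size} atoms"
        )
    return int(idx[0])


def min_distance_series(
    trajectory: Trajectory,
    config: ContactConfig,
    target_chain: str,
    target_residue_seq: int,
) -> np.ndarray:
    """Per-frame minimum distance (nm) from the probe atom to any atom of the
    target residue."""
    out = np.empty(trajectory.n_frames)
    for k, frame in enumerate(trajectory):
        try:
            p = _probe_index(frame, config)
        except ProbeError as exc:
            raise ProbeError(f"frame {k}: {exc}") from exc
        t_idx = frame.residue_atom_indices(target_chain, target_residue_seq)
        if t_idx.size == 0:
            raise ValueError(f"target residue {target_chain}:{target_residue_seq} is empty")
        d = np.linalg.norm(frame.positions[t_idx] - frame.positions[p], axis=1)
        out[k] = d.min()
    return out


def min_distance_profile(
    trajectory: Trajectory,
    config: ContactConfig,
    target_chain: str,
) -> pd.DataFrame:
    """Minimum-distance series for every residue of ``target_chain``;
    columns are residue_seq, index is frame time (ns)."""
    residues = sorted(
        {int(r) for c, r in zip(trajectory.frames[0].chain_ids,
                                trajectory.frames[0].residue_seqs) if c == target_chain}
    )
    if not residues:
        raise ValueError(f"no residues on chain {target_chain!r}")
    data = {
        res: min_distance_series(trajectory, config, target_chain, res) for res in residues
    }
    return pd.DataFrame(data, index=trajectory.times)


def screen_contacts(
    profiles: pd.DataFrame,
    screen_cutoff: float,
    equilibrated_mask: np.ndarray | None = None,
) -> list[int]:
    """Residues whose minimum distance over (equilibrated) frames ever comes
    within ``screen_cutoff`` (inclusive)."""
    if profiles.empty:
        raise ValueError("empty profiles")
    sub = profiles if equilibrated_mask is None else profiles.iloc[np.asarray(equilibrated_mask)]
    retained = [int(c) for c in sub.columns if float(sub[c].min()) <= screen_cutoff]
    return retained


def persistence(
    series: np.ndarray,
    strong_cutoff: float,
    equilibrated_mask: np.ndarray | None = None,
) -> float:
    """Fraction of equilibrated frames with distance <= strong_cutoff."""
    series = np.asarray(series, dtype=float)
    if equilibrated_mask is not None:
        series = series[np.asarray(equilibrated_mask)]
    if series.size == 0:
        raise ValueError("no frames selected")
    return float(np.mean(series <= strong_cutoff))


def pooled_density(
    replicate_series: list[np.ndarray],
    bin_width: float,
    range_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram density over frames pooled from all replicates.

    Returns (bin_edges, density); density integrates to 1 over the support.
    The range grows to cover the data so no mass is clipped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    data = np.concatenate([np.asarray(s, dtype=float) for s in replicate_series])
    if data.size == 0:
        raise ValueError("no data to histogram")
    hi = max(range_max or 0.0, float(data.max()) + bin_width)
    n_bins = int(np.ceil(hi / bin_width))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    counts, edges = np.histogram(data, bins=edges)
    density = counts / (data.size * bin_width)
    return edges, density


@dataclass
class ContactProfile:
    """Screening + persistence summary for one probe against one chain."""

    config: ContactConfig
    profiles: list[pd.DataFrame]  # one per replicate
    retained: list[int]
    persistence: pd.Series  # residue -> fraction, over retained residues
    relevant: list[int]

    def densities(
        self, residues: list[int] | None = None
    ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Pooled distance densities; defaults to the persistent residues."""
        out = {}
        for res in (self.relevant if residues is None else residues):
            series = [df[res].to_numpy() for df in self.profiles]
            out[res] = pooled_density(
                series, self.config.histogram_bin,
                range_max=self.config.screen_cutoff + 0.2,
            )
        return out


def contact_analysis(
    replicates: list[Trajectory],
    config: ContactConfig,
    target_chain: str,
    burn_in_fraction: float = 0.55,
) -> ContactProfile:
    """Full protocol over replicate trajectories: screen at 0.6 nm, compute
    persistence at 0.35 nm over equilibrated frames, pool histograms."""
    from .interface import apply_burn_in

    eq_profiles = []
    profiles = []
    for traj in replicates:
        df = min_distance_profile(traj, config, target_chain)
        keep = apply_burn_in(len(df), burn_in_fraction)
        profiles.append(df.iloc[keep])
        eq_profiles.append(df.iloc[keep])
    pooled = pd.concat(eq_profiles, axis=0)
    retained = screen_contacts(pooled, config.screen_cutoff)
    pers = pd.Series(
        {
            res: persistence(pooled[res].to_numpy(), config.strong_cutoff)
            for res in retained
        },
        dtype=float,
    )
    relevant = [int(r) for r in pers.index if pers[r] >= config.relevance_threshold]
    return ContactProfile(
        config=config,
        profiles=profiles,
        retained=retained,
        persistence=pers,
        relevant=relevant,
    )
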