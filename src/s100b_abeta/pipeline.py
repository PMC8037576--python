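"""Config-driven orchestration of the full analysis sequence.

One YAML config drives, in order: helical-content series, interfacial-area /
SAS^hydro profiles, minimum-distance contact mapping, MM-PBSA decomposition
and (optionally) ThT kinetics statistics.  The burn-in fraction is applied
once, consistently, to every equilibrium statistic.  Each stage writes TSV
(and JSON aggregate) outputs; a run manifest records the package version,
config hash, seed and per-stage status.  Re-running with an identical config
and seed reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import ContactConfig, contact_analysis
from .helix import helicity_series
from .interface import (
    AnalysisConfig,
    HydrophobicityScale,
    apply_burn_in,
    floating_window,
    profile_trajectory,
    replicate_stats,
)
from .mmpbsa import PBConfig, binding_energy
from .structure import (
    ParameterSet,
    SegmentSpec,
    Trajectory,
    assign_parameters,
    read_pdb_models,
    select_segment,
)

log = logging.getLogger("s100b_abeta.pipeline")


@dataclass
class PipelineConfig:
    """Validated view of the YAML pipeline configuration."""

    replicate_paths: list[Path]
    output_dir: Path
    seed: int = 0
    parameter_table: Path | None = None  # None -> packaged synthetic table
    segments: dict[str, SegmentSpec] = field(default_factory=dict)
    receptor_chain: str = "R"
    ligand_chain: str = "L"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    contact: ContactConfig = field(default_factory=ContactConfig)
    pb: PBConfig = field(default_factory=PBConfig)
    n_sphere_points: int = 960
    mmpbsa_stride: int = 5
    mmpbsa_gamma: float = 2.27
    kinetics_traces: dict[str, Path] = field(default_factory=dict)
    kinetics_control: str | None = None
    frame_dt_ns: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def respath(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        segments = {}
        for name, spec in (raw.get("segments") or {}).items():
            segments[name] = SegmentSpec(
                name=name,
                chain_id=str(spec["chain"]),
                residue_range=(int(spec["range"][0]), int(spec["range"][1])),
            )
        ana = raw.get("analysis") or {}
        con = raw.get("contacts") or {}
        pb = raw.get("pb") or {}
        kin = raw.get("kinetics") or {}
        probe = con.get("probe", "L:28:SC").split(":")
        return cls(
            replicate_paths=[respath(p) for p in raw["replicates"]],
            output_dir=respath(raw.get("output_dir", "pipeline_out")),
            seed=int(raw.get("seed", 0)),
            parameter_table=respath(raw["parameter_table"]) if raw.get("parameter_table") else None,
            segments=segments,
            receptor_chain=str(raw.get("receptor_chain", "R")),
            ligand_chain=str(raw.get("ligand_chain", "L")),
            analysis=AnalysisConfig(
                burn_in_fraction=float(ana.get("burn_in_fraction", 0.55)),
                window_ns=float(ana.get("window_ns", 100.0)),
            ),
            contact=ContactConfig(
                probe_chain=probe[0],
                probe_residue_seq=int(probe[1]),
                probe_atom_name=probe[2],
                screen_cutoff=float(con.get("screen_nm", 0.6)),
                strong_cutoff=float(con.get("strong_nm", 0.35)),
                histogram_bin=float(con.get("bin_nm", 0.01)),
                relevance_threshold=float(con.get("relevance_threshold", 0.1)),
            ),
            pb=PBConfig(
                solute_dielectric=float(pb.get("solute_dielectric", 4.0)),
                solvent_dielectric=float(pb.get("solvent_dielectric", 78.4)),
                ionic_strength=float(pb.get("ionic_strength", 0.1)),
                temperature=float(pb.get("temperature", 310.0)),
                grid_spacing=float(pb.get("grid_spacing", 0.15)),
                grid_padding=float(pb.get("grid_padding", 1.2)),
            ),
            n_sphere_points=int(raw.get("n_sphere_points", 960)),
            mmpbsa_stride=int(raw.get("mmpbsa_stride", 5)),
            mmpbsa_gamma=float(raw.get("mmpbsa_gamma", 2.27)),
            kinetics_traces={k: respath(v) for k, v in (kin.get("traces") or {}).items()},
            kinetics_control=kin.get("control"),
            frame_dt_ns=float(raw.get("frame_dt_ns", 1.0)),
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Report-only validation: missing files, threshold ordering, segments."""
    problems: list[str] = []
    if not config.replicate_paths:
        problems.append("no replicate trajectories configured")
    for p in config.replicate_paths:
        if not p.exists():
            problems.append(f"missing trajectory file: {p}")
    if config.parameter_table is not None and not config.parameter_table.exists():
        problems.append(f"missing parameter table: {config.parameter_table}")
    try:
        _ = config.contact
    except ValueError as exc:  # pragma: no cover - constructed eagerly
        problems.append(str(exc))
    if config.contact.strong_cutoff > config.contact.screen_cutoff:
        problems.append("strong_cutoff exceeds screen_cutoff")
    for name, path in config.kinetics_traces.items():
        if not path.exists():
            problems.append(f"missing kinetics trace {name!r}: {path}")
    if config.kinetics_control and config.kinetics_control not in config.kinetics_traces:
        problems.append(f"kinetics control {config.kinetics_control!r} not among traces")
    if config.replicate_paths and all(p.exists() for p in config.replicate_paths):
        try:
            traj = read_pdb_models(config.replicate_paths[0], frame_dt_ns=config.frame_dt_ns)
            for name, spec in config.segments.items():
                try:
                    select_segment(traj.frames[0], spec)
                except Exception as exc:
                    problems.append(f"segment {name!r} unresolvable: {exc}")
        except Exception as exc:
            problems.append(f"cannot read first trajectory: {exc}")
    return problems


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: dict[str, dict]

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")
        tmp.replace(path)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, Path):
            return str(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format="%.8g", index=index_label is not None,
              index_label=index_label)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every configured stage; returns (and writes) the manifest."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, config_hash=_config_hash(config),
        seed=config.seed, stages={},
    )
    log.info("pipeline start: %d replicates, burn-in %.2f, window %.0f ns, seed %d",
             len(config.replicate_paths), config.analysis.burn_in_fraction,
             config.analysis.window_ns, config.seed)
    log.info("contacts: probe %s:%d:%s screen %.2f nm strong %.2f nm bin %.3f nm",
             config.contact.probe_chain, config.contact.probe_residue_seq,
             config.contact.probe_atom_name, config.contact.screen_cutoff,
             config.contact.strong_cutoff, config.contact.histogram_bin)

    try:
        from .synthetic import default_parameter_set

        params = (
            ParameterSet.from_tsv(config.parameter_table)
            if config.parameter_table is not None
            else default_parameter_set()
        )
        replicates: list[Trajectory] = []
        for p in config.replicate_paths:
            traj = read_pdb_models(p, frame_dt_ns=config.frame_dt_ns)
            frames = [assign_parameters(fr, params) for fr in traj.frames]
            replicates.append(Trajectory(frames=frames, times=traj.times))
        first = replicates[0].frames[0]
        part_a = np.flatnonzero(first.chain_ids == config.receptor_chain)
        part_b = np.flatnonzero(first.chain_ids == config.ligand_chain)
        if part_a.size == 0 or part_b.size == 0:
            raise ValueError("receptor or ligand chain selects no atoms")

        # --- helicity ------------------------------------------------------
        seg_keys = {
            name: [(spec.chain_id, r) for r in range(spec.residue_range[0], spec.residue_range[1] + 1)]
            for name, spec in config.segments.items()
        }
        helicity_files = []
        for i, traj in enumerate(replicates):
            df = helicity_series(traj, seg_keys)
            f = out / f"helicity_rep{i}.tsv"
            _write_tsv(df, f, index_label="time_ns")
            helicity_files.append(str(f))
        manifest.stages["helicity"] = {"status": "ok", "outputs": helicity_files}

        # --- interface profile --------------------------------------------
        scale = HydrophobicityScale.wimley_white()
        core_keys = next(iter(seg_keys.values())) if seg_keys else [
            (c, r) for c, r in zip(first.chain_ids, first.residue_seqs)
        ]
        iface_files = []
        eq_area_means = []
        for i, traj in enumerate(replicates):
            prof = profile_trajectory(
                traj, part_a, part_b, core_keys, scale,
                n_sphere_points=config.n_sphere_points,
            )
            df = prof.to_frame()
            df["area_nm2_smoothed"] = floating_window(
                prof.times, prof.area_nm2, config.analysis.window_ns
            )
            f = out / f"interface_rep{i}.tsv"
            _write_tsv(df, f)
            iface_files.append(str(f))
            keep = apply_burn_in(len(df), config.analysis.burn_in_fraction)
            eq_area_means.append(prof.area_nm2[keep])
            fres = out / f"sashydro_rep{i}.tsv"
            _write_tsv(prof.per_residue_sashydro, fres, index_label="time_ns")
            iface_files.append(str(fres))
        mean_area, sem_area = replicate_stats(eq_area_means)
        (out / "interface_aggregate.json").write_text(json.dumps(
            {"area_nm2_mean": mean_area, "area_nm2_sem": sem_area,
             "n_replicates": len(replicates)}, indent=2, sort_keys=True) + "\n")
        iface_files.append(str(out / "interface_aggregate.json"))
        manifest.stages["interface"] = {"status": "ok", "outputs": iface_files}

        # --- contacts ------------------------------------------------------
        cp = contact_analysis(
            replicates, config.contact, config.receptor_chain,
            burn_in_fraction=config.analysis.burn_in_fraction,
        )
        pers_df = pd.DataFrame(
            {"residue_seq": cp.persistence.index, "persistence": cp.persistence.values}
        )
        f_pers = out / "contact_persistence.tsv"
        _write_tsv(pers_df, f_pers)
        contact_files = [str(f_pers)]
        for res, (edges, density) in cp.densities().items():
            df = pd.DataFrame({
                "bin_left_nm": edges[:-1], "bin_right_nm": edges[1:], "density": density,
            })
            f = out / f"contact_density_res{res}.tsv"
            _write_tsv(df, f)
            contact_files.append(str(f))
        manifest.stages["contacts"] = {"status": "ok", "outputs": contact_files}

        # --- MM-PBSA -------------------------------------------------------
        strided = [
            Trajectory(
                frames=t.frames[:: config.mmpbsa_stride],
                times=t.times[:: config.mmpbsa_stride],
            )
            for t in replicates
        ]
        per_frame, agg = binding_energy(
            strided, part_a, part_b, config.pb,
            burn_in_fraction=config.analysis.burn_in_fraction,
            gamma=config.mmpbsa_gamma,
            n_sphere_points=config.n_sphere_points,
        )
        f_pf = out / "mmpbsa_per_frame.tsv"
        _write_tsv(per_frame, f_pf)
        f_agg = out / "mmpbsa_aggregate.json"
        f_agg.write_text(json.dumps(
            {row["term"]: {"mean_kcal": row["mean_kcal"], "sem_kcal": row["sem_kcal"]}
             for _, row in agg.iterrows()}, indent=2, sort_keys=True) + "\n")
        manifest.stages["mmpbsa"] = {"status": "ok", "outputs": [str(f_pf), str(f_agg)]}

        # --- kinetics (optional) ------------------------------------------
        if config.kinetics_traces:
            from .kinetics import KineticTrace, normalize, summarize

            summaries = {}
            control_summary = None
            order = list(config.kinetics_traces)
            if config.kinetics_control:
                order = [config.kinetics_control] + [
                    k for k in order if k != config.kinetics_control
                ]
            for name in order:
                df = pd.read_csv(config.kinetics_traces[name])
                tr = KineticTrace(times=df["time_s"].to_numpy(), signal=df["signal"].to_numpy())
                s = summarize(normalize(tr), control=control_summary)
                if name == config.kinetics_control:
                    control_summary = s
                summaries[name] = s
            kin_df = pd.DataFrame(
                [
                    {
                        "condition": name,
                        "t_half_s": s.t_half,
                        "t_lag_s": s.t_lag,
                        "delta_t_half_s": s.delta_t_half if s.delta_t_half is not None else np.nan,
                    }
                    for name, s in summaries.items()
                ]
            )
            f_kin = out / "kinetics_summary.tsv"
            _write_tsv(kin_df, f_kin)
            manifest.stages["kinetics"] = {"status": "ok", "outputs": [str(f_kin)]}

    except Exception as exc:
        manifest.stages["error"] = {"status": "failed", "message": str(exc)}
        manifest.write(out / "run_manifest.json")
        raise

    manifest.write(out / "run_manifest.json")
    log.info("pipeline complete: %d stages", len(manifest.stages))
    return manifest
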