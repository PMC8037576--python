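#!/usr/bin/env python
"""MM-PBSA binding-energy decomposition of the synthetic complex.

Single-trajectory scheme over the equilibrated, strided frames of the three
replicates: vacuum Coulomb and Lennard-Jones terms, finite-difference
linearized PB polar solvation (solute dielectric 4, 0.1 M salt), and the
SASA-proportional apolar term; reported in kcal/mol as mean +/- SEM over
replicate means.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from s100b_abeta.mmpbsa import PBConfig, binding_energy
from s100b_abeta.structure import Trajectory, assign_parameters, read_pdb_models
from s100b_abeta.synthetic import default_parameter_set


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--in-dir", type=Path, default=Path("results/analysis/inputs"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    parser.add_argument("--burn-in", type=float, default=0.55)
    parser.add_argument("--stride", type=int, default=5)
    parser.add_argument("--grid-nm", type=float, default=0.15)
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    params = default_parameter_set()
    replicates = []
    for pdb in sorted(args.in_dir.glob("replicate_*.pdb")):
        traj = read_pdb_models(pdb)
        frames = [assign_parameters(f, params) for f in traj.frames[:: args.stride]]
        replicates.append(Trajectory(frames=frames, times=traj.times[:: args.stride]))
    first = replicates[0].frames[0]
    part_a = np.flatnonzero(first.chain_ids == "R")
    part_b = np.flatnonzero(first.chain_ids == "L")

    cfg = PBConfig(grid_spacing=args.grid_nm)
    per_frame, agg = binding_energy(
        replicates, part_a, part_b, cfg, burn_in_fraction=args.burn_in
    )
    per_frame.to_csv(out / "mmpbsa_per_frame.tsv", sep="\t", index=False,
                     float_format="%.6g")
    summary = {
        row["term"]: {"mean_kcal": row["mean_kcal"], "sem_kcal": row["sem_kcal"]}
        for _, row in agg.iterrows()
    }
    (out / "mmpbsa_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print("MM-PBSA decomposition (kcal/mol, mean +/- SEM over replicate means):")
    for term, v in summary.items():
        print(f"  {term:12s} {v['mean_kcal']:+9.2f} +/- {v['sem_kcal']:.2f}")
    print("note: the reduced rod-rod geometry with two net-acidic partners gives a "
          "repulsive net vacuum Coulomb term; magnitudes are not comparable to a "
          "folded protein complex")


if __name__ == "__main__":
    main()
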