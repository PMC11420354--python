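#!/usr/bin/env python
"""Generate the ground-truthed movies every later stage consumes.

Writes three datasets under <out>/sim/:
  gliding/   25 s dual-channel TIRF-like movie, cell at 2 um/s, myosin spots
             at -6 um/s in the cell frame (SNR 10), stripe artefacts
  reversal/  20 s movie with a quasi-instantaneous directional reversal at
             t = 10.05 s (cell and spot population both flip)
  population/ 5 min brightfield-like movie, 12 cells, log-normal speeds

Each directory holds the stack (TIFF), the ground truth (CSV) and the
scenario parameters (YAML).
"""

import argparse
import dataclasses
import os
import sys

import numpy as np
import pandas as pd
import yaml

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "helpers"))
from scenarios import population_speeds, reversal_scenario, standard_scenario  # noqa: E402

import glidekymo as gk  # noqa: E402


def truth_frame(truth: gk.GroundTruth) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(truth.t_s)),
            "t_s": truth.t_s,
            "cx_um": truth.center_um[:, 0],
            "cy_um": truth.center_um[:, 1],
            "angle_deg": truth.angle_deg,
            "v_um_s": truth.v_um_s,
        }
    )
    for j in range(truth.spot_pos_um.shape[1]):
        df[f"spot{j}_pos_um"] = truth.spot_pos_um[:, j]
        df[f"spot{j}_v_um_s"] = truth.spot_v_um_s[:, j]
    return df


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    for name, scenario in (
        ("gliding", standard_scenario(seed_offset=args.seed)),
        ("reversal", reversal_scenario(seed_offset=args.seed)),
    ):
        out = os.path.join(args.out, "sim", name)
        os.makedirs(out, exist_ok=True)
        stack, truth = gk.generate_gliding_movie(scenario)
        gk.write_stack(stack, os.path.join(out, "stack.tif"))
        truth_frame(truth).to_csv(os.path.join(out, "ground_truth.csv"), index=False)
        with open(os.path.join(out, "scenario.yaml"), "w") as fh:
            yaml.safe_dump(dataclasses.asdict(scenario), fh, sort_keys=True)
        print(
            f"{name}: {stack.n_frames} frames, {stack.shape[2]}x{stack.shape[3]} px, "
            f"events {truth.events}"
        )

    out = os.path.join(args.out, "sim", "population")
    os.makedirs(out, exist_ok=True)
    speeds = population_speeds(args.seed)
    stack, truth = gk.generate_population_movie(
        len(speeds), 300.0, speeds, rng_seed=args.seed + 1000, fov=(640, 640)
    )
    gk.write_stack(stack, os.path.join(out, "stack.tif"))
    pd.DataFrame(
        {
            "cell": np.arange(len(speeds)),
            "speed_um_s": speeds,
            "gt_mean_speed_um_s": truth.mean_speeds_um_s,
            "gt_path_length_um": truth.path_lengths_um,
        }
    ).to_csv(os.path.join(out, "ground_truth.csv"), index=False)
    print(f"population: {len(speeds)} cells, speeds {np.round(speeds, 2).tolist()} um/s")


if __name__ == "__main__":
    main()
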