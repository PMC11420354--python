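#!/usr/bin/env python
"""Register the GFP channel into the cell frame and build filtered kymographs.

Reads stacks and poses from 02, writes registered.tif, kymograph TIFFs and a
quick-look PNG per movie.
"""

import argparse
import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile

import glidekymo as gk


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    for name in ("gliding", "reversal"):
        d = os.path.join(args.out, "sim", name)
        stack = gk.read_stack(os.path.join(d, "stack.tif"))
        posedf = pd.read_csv(os.path.join(d, "pose.csv"))
        pose = gk.CellPose(
            posedf[["cx_px", "cy_px"]].to_numpy(),
            posedf["angle_deg"].to_numpy(),
            posedf["valid"].to_numpy(bool),
        )
        fov = (stack.data.shape[2], stack.data.shape[3])
        ref = gk.select_reference_frame(pose, fov)
        registered = gk.register_stack(stack, pose, ref, channel="gfp")
        gk.write_stack(registered, os.path.join(d, "registered.tif"))
        kymo = gk.build_kymograph(registered, channel="gfp")
        filtered = gk.fourier_stripe_filter(kymo)
        for label, k in (("kymo_raw", kymo), ("kymo_filtered", filtered)):
            tifffile.imwrite(
                os.path.join(d, f"{label}.tif"), k.data.astype(np.float32)
            )

        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, (label, k) in zip(axes, (("raw", kymo), ("stripe-filtered", filtered))):
            ax.imshow(k.data, cmap="gray_r", aspect="auto")
            ax.set(title=f"{name} ({label})", xlabel="x (px)")
        axes[0].set_ylabel("frame")
        fig.tight_layout()
        fig.savefig(os.path.join(d, "kymographs.png"), dpi=120)
        plt.close(fig)
        print(
            f"{name}: reference frame {ref.index} "
            f"(angle {ref.angle_deg:.2f} deg), kymograph {kymo.data.shape}"
        )


if __name__ == "__main__":
    main()
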