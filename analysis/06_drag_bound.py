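#!/usr/bin/env python
"""Viscous-drag bound: how much force does gliding actually require?

Evaluates the Stokes-regime drag on a hemispherically-capped cylinder
(prolate-spheroid surrogate) of diameter 6 um translating at 4 um/s through
water, sweeping cell length 6-50 um, and writes the sweep to CSV.
"""

import argparse
import os

import pandas as pd

import glidekymo as gk


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    lengths, forces = gk.drag_length_sweep(diameter=6.0, velocity=4.0, viscosity=1.0)
    os.makedirs(args.out, exist_ok=True)
    pd.DataFrame({"length_um": lengths, "drag_pN": forces}).to_csv(
        os.path.join(args.out, "drag_sweep.csv"), index=False
    )
    sphere = gk.stokes_drag(gk.DragModel("sphere", 6.0, 4.0))
    print(f"sphere (d=6 um, 4 um/s, water): {sphere:.4f} pN")
    print(
        f"capsule sweep 6-50 um: max {forces.max():.4f} pN at {lengths[forces.argmax()]:.0f} um"
        f" -> a single ~pN motor could overcome it"
    )


if __name__ == "__main__":
    main()
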