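"""Digital counting versus analog baselines across a density titration.

Sweeps the surface density over four orders of magnitude on a fixed array,
runs the full pipeline at each point, and prints the digital count N next
to the analog baselines (mean pixel, mean above-threshold pixel). The
digital count rises and saturates near full wire occupancy, while the mean
per-wire intensity I_avg only rises once wires carry multiple molecules.
"""

import numpy as np

from nwloc.array_model import generate_layout, place_molecules
from nwloc.image_synthesis import (
    CameraModel,
    OpticalModel,
    render_brightfield,
    render_fluorescence,
)
from nwloc.pipeline import run_pipeline
from nwloc.quantify import summarize_frame

layout = generate_layout(n_rows=16, n_cols=16, seed=100)
optics = OpticalModel()
camera = CameraModel.for_layout(layout, exposure_ms=100.0)
brightfield = render_brightfield(layout, camera, seed=101, noise_sd=0.01)
n_straight = int(np.sum(layout.status == "straight"))
print(f"array: {layout.n_sites} sites, {n_straight} straight wires\n")

print(f"{'density':>10} {'N':>5} {'I_avg':>8} {'i_px':>7} {'i_thr':>8}")
for i, density in enumerate([0.01, 0.05, 0.2, 1.22, 5.0, 10.0, 30.4]):
    truth = place_molecules(layout, density, seed=200 + 10 * i)
    frame = render_fluorescence(truth, layout, optics, camera,
                                seed=201 + 10 * i)
    res = run_pipeline(frame.image, brightfield, camera)
    s = summarize_frame(res.detections, frame.image, camera)
    i_avg = f"{s.i_avg:8.1f}" if s.i_avg is not None else "       -"
    print(f"{density:10.2f} {s.n:5d} {i_avg} {s.i_px:7.2f} {s.i_thr:8.1f}")

print("\nN saturates near the straight-wire count at high density;")
print("I_avg stays flat until wires carry multiple molecules.")
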