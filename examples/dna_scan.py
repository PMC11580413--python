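"""Constant-force imaging of an idealized B-DNA segment.

Builds a straight B-form duplex from canonical helical parameters, rasters
its van der Waals envelope (bottom 20% embedded in the substrate), scans it
with a 1.8 nm tip of 5-degree half-angle, and extracts the 100 pN
constant-force image with cross-section and longitudinal profiles.
"""

import numpy as np

from afm_softscan import (
    build_bdna,
    build_force_volume,
    get_preset,
    isoforce_image,
    molecule_height_field,
)

cfg = get_preset("dna")
atoms = build_bdna(30, axis="x")  # 30 bp keeps the example quick
field = molecule_height_field(atoms, spacing=cfg.sample_params["bin"],
                              cleave_fraction=0.20, y_range=(-2.5, 2.5))
print(f"sample: {len(atoms)} atoms, envelope height {field.h_max:.2f} nm")

scan_x = np.linspace(field.x[0], field.x[-1], 30)
scan_y = np.linspace(-2.0, 2.0, 8)
d = np.concatenate([[0.0], np.geomspace(0.05, 2.0, 8)])
vol = build_force_volume(cfg.tip, field, cfg.material, scan_x, scan_y=scan_y,
                         delta_grid=d, engine="halfspace")
img = isoforce_image(vol, cfg.setpoints[0])  # 100 pN

jmid = img.y.size // 2
longitudinal = img.heights[:, jmid]
i_peak = int(np.argmax(longitudinal))
cross = img.heights[i_peak, :]

print(f"\nimaged DNA height at 100 pN: {longitudinal.max():.2f} nm "
      f"(vdW envelope: {field.h_max:.2f} nm)")
print("cross-section (nm):   " + " ".join(f"{h:5.2f}" for h in cross))
print("longitudinal corrugation: "
      f"{longitudinal.max() - longitudinal[longitudinal > 0].min():.2f} nm "
      "(major/minor groove repeat, smoothed by the tip)")

print(
    "\nThe finite force compresses the molecule below its van der Waals\n"
    "height, and tip convolution widens the cross-section and smooths the\n"
    "helical groove pattern along the axis."
)
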