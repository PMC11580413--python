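"""Imaging an elastic hemisphere: tip convolution versus compression.

Scans a 5 nm hemisphere with a blunt tip (R/r = 1.4), extracts the
zero-force (unindented) trace and a constant-force topography, and compares
apparent width (FWHM) and grain volume with the true sample values.
"""

import math

import numpy as np

from afm_softscan import (
    Material,
    TipGeometry,
    apparent_volume,
    build_force_volume,
    fwhm,
    isoforce_image,
    make_hemisphere,
    zero_force_topography,
)

r = 5.0
hemi = make_hemisphere(r, spacing=0.2, extent=11.0)
tip = TipGeometry.from_degrees(R=1.4 * r, theta_deg=20.0)
material = Material(E=100.0, nu=0.3)

zero = zero_force_topography(tip, hemi, hemi.x, hemi.y)
v_true = (2 / 3) * math.pi * r**3
v_zero = apparent_volume(zero)
w_true = fwhm(hemi.heights[:, hemi.y.size // 2], x=hemi.x)
w_zero = fwhm(zero.heights[:, zero.y.size // 2], x=zero.x)

print(f"true hemisphere:    FWHM = {w_true:.2f} nm, volume = {v_true:.1f} nm^3")
print(f"zero-force image:   FWHM = {w_zero:.2f} nm, volume = {v_zero:.1f} nm^3 "
      f"({v_zero / v_true:.2f}x true)")

d = np.concatenate([[0.0], np.geomspace(0.05, 0.65 * tip.R, 12)])
vol = build_force_volume(tip, hemi, material, hemi.x[::4], scan_y=hemi.y[::4],
                         delta_grid=d)
img = isoforce_image(vol, 0.1, dimensionless=True)
hs = np.clip(img.heights, 0.0, None)
img.heights = hs
v_force = apparent_volume(img)
print(f"F/(E*R^2)=0.1 image: volume = {v_force:.1f} nm^3 ({v_force / v_true:.2f}x true)")

print(
    "\nAt zero force the blunt tip inflates the apparent volume several-fold\n"
    "(pure convolution); applying force compresses the particle and pulls the\n"
    "apparent volume back down - the two artefacts partially compete."
)
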