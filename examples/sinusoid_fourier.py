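"""Fourier analysis of an imaged periodic surface.

A cosine surface (wavelength = amplitude = 10 nm) is traced at zero force
by a sharp and a blunt tip; the cosine amplitudes A_n of the traces show
how tip convolution suppresses the fundamental and leaks power into
spurious higher orders.
"""

import numpy as np

from afm_softscan import (
    TipGeometry,
    fourier_coefficients,
    higher_order_content,
    make_sinusoid,
    zero_force_topography,
)

lam = amp = 10.0
M = 200
surface = make_sinusoid(lam, amp, spacing=lam / M)
i0 = int(np.searchsorted(surface.x, 0.0))
scan_x = surface.x[i0 : i0 + M]  # exactly one period, crest at x = 0

for label, tip in [
    ("point tip", TipGeometry(R=1e-9, theta=1e-3)),
    ("sharp tip R/lambda = 0.05", TipGeometry.from_degrees(0.5, 20.0)),
    ("blunt tip R/lambda = 0.45", TipGeometry.from_degrees(4.5, 20.0)),
]:
    img = zero_force_topography(tip, surface, scan_x)
    spec = fourier_coefficients(img.heights[:, 0], N=50, x=scan_x)
    hoc = higher_order_content(spec, N=50)
    print(f"{label:28s} A_1 = {spec.A[1]:6.3f} nm  "
          f"A_1/A_surface = {spec.A[1] / (amp / 2):.3f}  "
          f"higher-order RMS = {hoc:.4f} nm")

print(
    "\nThe point tip reports A_1 = A_surface with no higher orders (the ideal\n"
    "trace).  Blunter tips suppress the fundamental and generate artefactual\n"
    "high-order content: apparent fine detail that the surface does not have."
)
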