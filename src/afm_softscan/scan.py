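"""Imaging procedure: tip-sample first contact, force volumes, iso-force maps.

For each lateral scan position the apex height of first contact is the
grayscale dilation of the sample surface by the reflected tip shape — the
closest vertical approach may be at the tip apex or at its flank.  Lowering
the tip from there produces indentations delta >= 0 and forces from a
pluggable elastic engine; simulated AFM images are contours of equal
vertical force through the resulting F(x, y, z) volume, interpolated with a
monotone cubic in z and (optionally) bicubically refined laterally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator, RectBivariateSpline, CubicSpline

from .geometry import HeightField, Material, TipGeometry, tip_profile

__all__ = [
    "AFMImage",
    "ForceVolume",
    "boundary_radius",
    "closest_vertical_distance",
    "zero_force_topography",
    "build_force_volume",
    "isoforce_image",
]


def boundary_radius(tip: TipGeometry, h_max: float) -> float:
    """Largest lateral offset at which a feature of height <= h_max can touch the tip.

    Inverse of the tip profile at height ``h_max``: spherical branch
    ``sqrt(h (2R - h))`` below the tangent height, conical branch beyond.
    Used to prune the first-contact search.
    """
    if h_max < 0:
        raise ValueError("h_max must be nonnegative")
    if h_max <= tip.z_t:
        return math.sqrt(h_max * (2.0 * tip.R - h_max))
    return tip.rho_t + (h_max - tip.z_t) * math.tan(tip.theta)


def closest_vertical_distance(
    tip: TipGeometry, sample: HeightField, position
) -> float:
    """Apex height at first tip-sample contact for one lateral position (nm).

    ``max_p [h(p) - tip_profile(|p - position|)]`` over sample cells within
    the boundary radius of the tallest feature, floored at 0 (the apex can
    always rest on the substrate).  Equals the grayscale dilation of the
    height field by the reflected tip.
    """
    px, py = float(position[0]), float(position[1])
    rho_b = boundary_radius(tip, sample.h_max)
    xs = sample.x
    ys = sample.y
    # crop to the boundary-radius window (plus one cell of slack)
    pad = max(sample.dx, sample.dy)
    i0 = np.searchsorted(xs, px - rho_b - pad)
    i1 = np.searchsorted(xs, px + rho_b + pad, side="right")
    j0 = np.searchsorted(ys, py - rho_b - pad)
    j1 = np.searchsorted(ys, py + rho_b + pad, side="right")
    if i0 >= i1 or j0 >= j1:
        return 0.0
    xx = xs[i0:i1, None] - px
    yy = ys[None, j0:j1] - py
    d = np.sqrt(xx * xx + yy * yy)
    vals = sample.heights[i0:i1, j0:j1] - tip_profile(tip, d)
    return max(float(vals.max()), 0.0)


@dataclass
class AFMImage:
    """Simulated AFM topography h_AFM(x, y) at constant force (or zero force)."""

    x: np.ndarray
    y: np.ndarray
    heights: np.ndarray
    mode: str  # "zero-force" | "iso-force"
    setpoint_pn: float = 0.0
    setpoint_dimensionless: Optional[float] = None
    saturated: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.shape != (self.x.size, self.y.size):
            raise ValueError("heights shape does not match scan grid")

    def profile_x(self, j: Optional[int] = None) -> np.ndarray:
        """Cross-section along x (at the central y row by default)."""
        j = self.y.size // 2 if j is None else j
        return self.heights[:, j]


def zero_force_topography(
    tip: TipGeometry,
    sample: HeightField,
    scan_x: np.ndarray,
    scan_y: Optional[np.ndarray] = None,
) -> AFMImage:
    """Unindented AFM trace: first-contact apex height over the scan grid."""
    scan_x = np.atleast_1d(np.asarray(scan_x, dtype=float))
    scan_y = np.array([0.0]) if scan_y is None else np.atleast_1d(np.asarray(scan_y, float))
    h = np.empty((scan_x.size, scan_y.size))
    for i, px in enumerate(scan_x):
        for j, py in enumerate(scan_y):
            h[i, j] = closest_vertical_distance(tip, sample, (px, py))
    return AFMImage(scan_x, scan_y, h, mode="zero-force", setpoint_pn=0.0,
                    meta={"tip": tip})


@dataclass
class ForceVolume:
    """Vertical force sampled on a 3-D grid of tip-apex positions.

    Per scan position (x_i, y_j) the sampled apex heights are
    ``contact_height[i, j] - delta[k]`` so the delta axis is shared; force
    has shape (nx, ny, ndelta) and is zero in the delta = 0 layer.
    """

    x: np.ndarray
    y: np.ndarray
    contact_height: np.ndarray
    delta: np.ndarray
    force: np.ndarray
    tip: TipGeometry
    material: Material
    engine: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.force.shape != (self.x.size, self.y.size, self.delta.size):
            raise ValueError("force shape must be (nx, ny, ndelta)")

    def z_levels(self, i: int, j: int) -> np.ndarray:
        return self.contact_height[i, j] - self.delta

    def column(self, i: int, j: int):
        from .contact import ForceCurve

        return ForceCurve(delta=self.delta.copy(), force=self.force[i, j].copy())


def build_force_volume(
    tip: TipGeometry,
    sample: HeightField,
    material: Material,
    scan_x: np.ndarray,
    delta_grid: Optional[np.ndarray] = None,
    scan_y: Optional[np.ndarray] = None,
    engine: str = "local-analytic",
    **engine_kwargs,
) -> ForceVolume:
    """Sample F(x, y, z) over the scan grid with the selected elastic engine.

    ``delta_grid`` defaults to 30 geometrically spaced indentations from 0 to
    the spherical-validity limit 0.65 R.
    """
    from . import solver

    scan_x = np.atleast_1d(np.asarray(scan_x, dtype=float))
    scan_y = np.array([0.0]) if scan_y is None else np.atleast_1d(np.asarray(scan_y, float))
    if delta_grid is None:
        from .geometry import spherical_validity_limit

        dmax = spherical_validity_limit(tip)
        delta_grid = np.concatenate([[0.0], np.geomspace(dmax / 100.0, dmax, 29)])
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid[0] != 0.0:
        raise ValueError("delta_grid must start at 0")
    nx, ny, nd = scan_x.size, scan_y.size, delta_grid.size
    contact = np.empty((nx, ny))
    force = np.empty((nx, ny, nd))
    for i, px in enumerate(scan_x):
        for j, py in enumerate(scan_y):
            try:
                curve = solver.force_curve_at(
                    sample, tip, material, (px, py), delta_grid,
                    engine=engine, **engine_kwargs,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"force engine '{engine}' failed at scan position "
                    f"(x={px}, y={py}): {exc}"
                ) from exc
            contact[i, j] = curve.meta["contact_height"]
            force[i, j] = curve.force
    return ForceVolume(
        x=scan_x, y=scan_y, contact_height=contact, delta=delta_grid,
        force=force, tip=tip, material=material, engine=engine,
    )


def isoforce_image(
    volume: ForceVolume,
    setpoint: float,
    dimensionless: bool = False,
    upsample: int = 1,
) -> AFMImage:
    """Extract the constant-force topography at ``setpoint`` from a force volume.

    ``setpoint`` is in pN, or in F/(E* R^2) units when ``dimensionless`` is
    true.  Per column a shape-preserving (PCHIP) cubic of apex height versus
    force is evaluated at the setpoint; columns whose sampled force never
    reaches the setpoint are flagged saturated and mapped to the
    substrate-contact floor (apex height 0).  ``upsample > 1`` refines the
    lateral grid with bicubic interpolation of the extracted heights.
    """
    scale = volume.material.E_star * volume.tip.R**2
    sp_pn = setpoint * scale if dimensionless else float(setpoint)
    if sp_pn < 0:
        raise ValueError("force setpoint must be nonnegative")
    nx, ny = volume.x.size, volume.y.size
    heights = np.empty((nx, ny))
    saturated = np.zeros((nx, ny), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            f = volume.force[i, j]
            z = volume.contact_height[i, j] - volume.delta
            if sp_pn > f[-1]:
                heights[i, j] = 0.0
                saturated[i, j] = True
                continue
            if sp_pn <= 0.0:
                heights[i, j] = volume.contact_height[i, j]
                continue
            # keep a strictly increasing force abscissa (drop the flat F=0 head
            # except its last sample, i.e. the contact point)
            keep = np.concatenate([[True], np.diff(f) > 0])
            interp = PchipInterpolator(f[keep], z[keep])
            # apex height may go below the substrate plane on compliant flats
            heights[i, j] = float(interp(sp_pn))
    if saturated.any():
        warnings.warn(
            f"{int(saturated.sum())} scan column(s) saturated below setpoint "
            f"{sp_pn:.3g} pN; mapped to the substrate floor",
            stacklevel=2,
        )
    x, y = volume.x, volume.y
    if upsample > 1:
        xf = np.linspace(x[0], x[-1], (x.size - 1) * upsample + 1)
        if y.size >= 4:
            spline = RectBivariateSpline(x, y, heights, kx=3, ky=3)
            yf = np.linspace(y[0], y[-1], (y.size - 1) * upsample + 1)
            heights = spline(xf, yf)
            x, y = xf, yf
            saturated = None
        elif x.size >= 4:
            cs = CubicSpline(x, heights[:, 0])
            heights = cs(xf)[:, None]
            x = xf
            saturated = None
    return AFMImage(
        x, y, heights, mode="iso-force", setpoint_pn=sp_pn,
        setpoint_dimensionless=(setpoint if dimensionless else sp_pn / scale),
        saturated=saturated,
        meta={"tip": volume.tip, "material": volume.material, "engine": volume.engine},
    )
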