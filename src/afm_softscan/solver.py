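"""Elastic contact engines: force as a function of 3-D tip position.

Two pluggable engines compute the vertical tip-sample force for a rigid
probe pressed a distance ``delta`` past first contact with a deformable
sample:

* ``"halfspace"`` — a boundary-element solver for frictionless contact of a
  rigid indenter of arbitrary shape on an elastic half-space.  Surface
  deflections follow from the Boussinesq solution, assembled from the exact
  influence integral of uniform pressure on a rectangular cell, and the
  contact inequality constraints (nonnegative pressure, nonnegative gap,
  complementarity) are enforced by a conjugate-gradient active-set iteration
  in the style of Polonsky & Keer.
* ``"local-analytic"`` — a closed-form law driven by the local geometry at
  the first-contact point: Hertz with the effective radius combining the tip
  cap and the sample's principal convexities when contact is on the
  spherical cap, conical Sneddon when first contact is on the flank.

Both are validated against the classical closed forms (Hertz sphere,
flat punch); the half-space engine additionally resolves side and
double-sided contact that no single-contact-point law can represent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve

from .contact import ContactConfig, ForceCurve, hertz_force, sneddon_modified_force
from .geometry import HeightField, Material, TipGeometry, tip_profile

__all__ = [
    "GapFunction",
    "ContactSolution",
    "halfspace_contact_solve",
    "force_curve_at",
]


@dataclass
class GapFunction:
    """Initial tip-to-surface vertical separation per cell at a fixed apex height.

    Negative values mean geometric interference (the rigid tip would overlap
    the undeformed surface); the contact solver turns interference into
    pressure and elastic deflection.
    """

    x: np.ndarray
    y: np.ndarray
    gap: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.gap = np.asarray(self.gap, dtype=float)
        if self.gap.shape != (self.x.size, self.y.size):
            raise ValueError("gap shape must match grid")
        if not np.all(np.isfinite(self.gap)):
            raise ValueError("gap values must be finite")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])


@dataclass
class ContactSolution:
    """Pressure field (MPa), deflections (nm) and total force (pN) of one solve."""

    pressure: np.ndarray
    displacement: np.ndarray
    total_force: float
    contact_mask: np.ndarray
    iterations: int
    residual: float
    meta: dict = field(default_factory=dict)

    @property
    def contact_area(self) -> float:
        return float(self.meta.get("cell_area", 0.0) * self.contact_mask.sum())


def _patch_integral(x, y, a, b):
    """Boussinesq deflection integral of unit pressure on a rectangle.

    Deflection at (x, y) from uniform unit pressure over the rectangle
    |x'| <= a, |y'| <= b is this value divided by (pi E*).  Exact closed
    form, so cell self-terms are nonsingular.
    """
    xp, xm = x + a, x - a
    yp, ym = y + b, y - b

    def term(u, vp, vm):
        return u * np.log(
            (vp + np.sqrt(vp * vp + u * u)) / (vm + np.sqrt(vm * vm + u * u))
        )

    return term(xp, yp, ym) + term(yp, xp, xm) - term(xm, yp, ym) - term(ym, xp, xm)


def _influence_kernel(nx, ny, dx, dy, e_star):
    """Deflection (nm) at every cell-offset from unit pressure (MPa) on one cell."""
    ox = np.arange(-(nx - 1), nx) * dx
    oy = np.arange(-(ny - 1), ny) * dy
    xx, yy = np.meshgrid(ox, oy, indexing="ij")
    return _patch_integral(xx, yy, dx / 2.0, dy / 2.0) / (math.pi * e_star)


def halfspace_contact_solve(
    gap: GapFunction,
    material: Material,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> ContactSolution:
    """Solve rigid-indenter-on-elastic-half-space contact for a gap function.

    Enforces p >= 0, deformed gap g + u >= 0 and p (g + u) = 0 by a
    conjugate-gradient iteration restricted to the active contact set, with
    projection of negative pressures and admission of newly overlapping
    cells.  ``tol`` is the relative complementarity/force tolerance.
    Returns pressures in MPa, deflections in nm and total force in pN.
    """
    g = gap.gap
    nx, ny = g.shape
    dx, dy = gap.dx, gap.dy
    cell_area = dx * dy
    kernel = _influence_kernel(nx, ny, dx, dy, material.E_star)

    def deflect(p):
        return fftconvolve(p, kernel, mode="full")[nx - 1 : 2 * nx - 1, ny - 1 : 2 * ny - 1]

    overlap = g < 0
    if not overlap.any():
        zeros = np.zeros_like(g)
        return ContactSolution(
            pressure=zeros, displacement=zeros.copy(), total_force=0.0,
            contact_mask=overlap, iterations=0, residual=0.0,
            meta={"cell_area": cell_area},
        )
    # initial guess: pressure proportional to interference
    p = np.where(overlap, -g, 0.0) * material.E_star / max(dx, dy)
    g_scale = float(-g.min())
    d = np.zeros_like(p)
    G_old = 1.0
    use_conj = False
    it = 0
    residual = np.inf
    for it in range(1, max_iter + 1):
        u = deflect(p)
        h = g + u  # deformed gap
        S = p > 0
        if not S.any():
            S = overlap
        r = h
        G = float(np.sum(r[S] ** 2))
        d = np.where(S, r + (G / G_old) * d if use_conj else r, 0.0)
        G_old = max(G, 1e-300)
        q = deflect(d)
        denom = float(np.sum(d[S] * q[S]))
        if denom <= 0:
            tau = 0.0
        else:
            tau = float(np.sum(r[S] * d[S])) / denom
        p_new = p - tau * d
        neg = p_new < 0
        p_new[neg] = 0.0
        # admit exterior cells that the rigid body now penetrates
        R_set = (~S) & (h < 0)
        changed = bool(neg[S].any() or R_set.any())
        if R_set.any() and tau > 0:
            p_new[R_set] -= tau * h[R_set]
        use_conj = not changed
        p = p_new
        # convergence: complementarity on contact set + no unaccounted overlap
        in_c = p > 0
        residual = 0.0
        if in_c.any():
            residual = float(np.abs(h[in_c]).max()) / max(g_scale, 1e-30)
        overlap_out = float(-(h[~in_c].min())) / max(g_scale, 1e-30) if (~in_c).any() else 0.0
        if max(residual, overlap_out) < tol:
            break
    else:
        raise RuntimeError(
            f"half-space contact solve did not converge in {max_iter} iterations "
            f"(relative residual {residual:.3e})"
        )
    u = deflect(p)
    return ContactSolution(
        pressure=p,
        displacement=u,
        total_force=float(p.sum() * cell_area),
        contact_mask=p > 0,
        iterations=it,
        residual=residual,
        meta={"cell_area": cell_area},
    )


def _tip_gap(
    sample: HeightField,
    tip: TipGeometry,
    position,
    apex_height: float,
    window: Optional[float] = None,
    spacing: Optional[float] = None,
) -> GapFunction:
    """Gap between the tip surface and the sample around one scan position."""
    px, py = float(position[0]), float(position[1])
    from .scan import boundary_radius

    if window is None:
        window = boundary_radius(tip, sample.h_max) + tip.R
    if spacing is None:
        spacing = min(sample.dx if sample.dx > 0 else window / 32,
                      sample.dy if sample.dy > 0 else window / 32)
    n = max(int(round(window / spacing)), 8)
    x = px + np.arange(-n, n + 1) * spacing
    y = py + np.arange(-n, n + 1) * spacing
    # sample heights on the window grid (bilinear off-node; fields are smooth)
    hs = _bilinear(sample, x, y)
    xx, yy = np.meshgrid(x - px, y - py, indexing="ij")
    tp = tip_profile(tip, np.sqrt(xx * xx + yy * yy))
    return GapFunction(x, y, apex_height + tp - hs)


def _bilinear(sample: HeightField, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xi = np.clip((x - sample.x[0]) / (sample.dx or 1.0), 0, sample.x.size - 1)
    yi = (
        np.clip((y - sample.y[0]) / (sample.dy or 1.0), 0, sample.y.size - 1)
        if sample.y.size > 1
        else np.zeros_like(y)
    )
    i0 = np.floor(xi).astype(int)
    j0 = np.floor(yi).astype(int)
    i1 = np.minimum(i0 + 1, sample.x.size - 1)
    j1 = np.minimum(j0 + 1, sample.y.size - 1)
    fx = (xi - i0)[:, None]
    fy = (yi - j0)[None, :]
    h = sample.heights
    return (
        h[np.ix_(i0, j0)] * (1 - fx) * (1 - fy)
        + h[np.ix_(i1, j0)] * fx * (1 - fy)
        + h[np.ix_(i0, j1)] * (1 - fx) * fy
        + h[np.ix_(i1, j1)] * fx * fy
    )


def _local_analytic_force(
    sample: HeightField,
    tip: TipGeometry,
    material: Material,
    position,
    contact_point,
    delta: np.ndarray,
) -> np.ndarray:
    """Hertz/Sneddon force from the local sample geometry at first contact."""
    px, py = position
    cx, cy = contact_point
    offset = math.hypot(cx - px, cy - py)
    if offset <= tip.rho_t + 1e-12:
        k1, k2 = sample.curvatures_at(cx, cy)
        # Hertz effective radius: combine tip cap with each principal
        # convexity; equivalent axisymmetric radius = geometric mean.
        inv1 = 1.0 / tip.R + k1
        inv2 = 1.0 / tip.R + k2
        cap = 1e6 * tip.R  # concave samples wrapped around the tip: near-flat limit
        r1 = 1.0 / inv1 if inv1 > 1.0 / cap else cap
        r2 = 1.0 / inv2 if inv2 > 1.0 / cap else cap
        r_eff = math.sqrt(r1 * r2)
        return hertz_force(material, ContactConfig(R=r_eff, r=math.inf), delta)
    return sneddon_modified_force(material, tip, math.inf, delta)


def force_curve_at(
    sample: HeightField,
    tip: TipGeometry,
    material: Material,
    position,
    delta_grid: np.ndarray,
    engine: str = "local-analytic",
    window: Optional[float] = None,
    spacing: Optional[float] = None,
) -> ForceCurve:
    """Force-indentation curve at one lateral scan position.

    ``delta_grid`` must be nonnegative, increasing and start at 0; the apex
    height at each sample is (first-contact height - delta).  The returned
    curve's ``meta`` records the contact height and engine.
    """
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid[0] != 0.0 or np.any(np.diff(delta_grid) <= 0) or np.any(delta_grid < 0):
        raise ValueError("delta_grid must be increasing and start at 0")
    px, py = float(position[0]), float(position[1])
    if not (sample.x[0] <= px <= sample.x[-1]):
        raise ValueError(f"scan x={px} outside the sample grid")
    if sample.y.size > 1 and not (sample.y[0] <= py <= sample.y[-1]):
        raise ValueError(f"scan y={py} outside the sample grid")
    from .scan import boundary_radius

    # first contact: dilation over the sample grid, and the touching point
    rho_b = boundary_radius(tip, sample.h_max)
    xs, ys = sample.x, sample.y
    xx = xs[:, None] - px
    yy = ys[None, :] - py
    d = np.sqrt(xx * xx + yy * yy)
    vals = np.where(d <= rho_b + max(sample.dx, sample.dy),
                    sample.heights - tip_profile(tip, d), -np.inf)
    i_c, j_c = np.unravel_index(int(np.argmax(vals)), vals.shape)
    z0 = max(float(vals[i_c, j_c]), 0.0)

    force = np.zeros_like(delta_grid)
    if engine == "local-analytic":
        contact_point = (float(xs[i_c]), float(ys[j_c])) if vals[i_c, j_c] >= 0 else (px, py)
        force = _local_analytic_force(sample, tip, material, (px, py),
                                      contact_point, delta_grid)
    elif engine == "halfspace":
        for k, dlt in enumerate(delta_grid):
            if dlt == 0.0:
                continue
            gap = _tip_gap(sample, tip, (px, py), z0 - dlt,
                           window=window, spacing=spacing)
            sol = halfspace_contact_solve(gap, material)
            force[k] = sol.total_force
    else:
        raise ValueError(f"unknown engine '{engine}'")
    return ForceCurve(
        delta=delta_grid.copy(),
        force=np.asarray(force, dtype=float),
        meta={"contact_height": z0, "engine": engine, "position": (px, py)},
    )
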