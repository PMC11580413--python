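"""Closed-form and semi-analytic force-indentation laws.

Three contact models for a rigid probe on an elastic body:

* Hertz: sphere of radius R on a spherical surface of radius r,
  ``F = (4/3) E* sqrt(R*) delta^(3/2)`` with ``1/R* = 1/R + 1/r``.
* Sneddon (cone): ``F = (2/pi) E* tan(theta) delta^2``, optionally modified
  by a multiplicative, empirically fitted correction ``f(delta)`` for
  indentation into curved samples.  The correction is a pluggable callable;
  the default ``f = 1`` recovers the classical flat-surface cone law.
* Double contact: a soft sphere of radius r on a rigid substrate is
  compressed both at the tip contact (indentation delta_I) and at its base
  (compression delta_C), the same force F transmitting through both Hertzian
  contacts in series.  The measured indentation is delta = delta_I + delta_C,
  and F(delta) is obtained by inverting the monotone forward map delta(F).

Units: nm, pN, MPa throughout (1 MPa nm^2 = 1 pN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .geometry import Material, TipGeometry

__all__ = [
    "ContactConfig",
    "ForceCurve",
    "DimensionlessCurve",
    "hertz_force",
    "hertz_indentation",
    "sneddon_modified_force",
    "double_contact_delta",
    "double_contact_force",
    "nondimensionalize",
]


@dataclass(frozen=True)
class ContactConfig:
    """Tip radius R and sample radius of curvature r (nm; r may be inf)."""

    R: float
    r: float = math.inf

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError("tip radius R must be positive")
        if not self.r > 0:
            raise ValueError("sample radius r must be positive (or inf)")

    @property
    def R_star(self) -> float:
        """Effective contact radius, 1/R* = 1/R + 1/r."""
        if math.isinf(self.r):
            return self.R
        return 1.0 / (1.0 / self.R + 1.0 / self.r)


@dataclass
class ForceCurve:
    """Paired indentation (nm) and vertical force (pN) samples at one position.

    ``delta`` is the total measured tip displacement from first contact; when
    the double-contact split is known, ``delta_i`` (tip contact) and
    ``delta_c`` (base compression) satisfy delta = delta_i + delta_c.
    """

    delta: np.ndarray
    force: np.ndarray
    delta_i: Optional[np.ndarray] = None
    delta_c: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.delta.shape != self.force.shape or self.delta.ndim != 1:
            raise ValueError("delta and force must be 1-D arrays of equal length")
        if np.any(self.delta < 0):
            raise ValueError("indentation samples must be nonnegative")
        if np.any(np.diff(self.delta) <= 0):
            raise ValueError("indentation samples must be strictly increasing")
        if self.delta_i is not None and self.delta_c is not None:
            s = np.asarray(self.delta_i) + np.asarray(self.delta_c)
            if not np.allclose(s, self.delta, rtol=1e-9, atol=1e-12):
                raise ValueError("delta_i + delta_c must equal delta")

    def __len__(self) -> int:
        return int(self.delta.size)


@dataclass
class DimensionlessCurve:
    """Force curve in the dimensionless variables F/(E* R^2) vs delta/R."""

    delta_ratio: np.ndarray
    force_ratio: np.ndarray

    def dimensionalize(self, material: Material, R: float) -> ForceCurve:
        return ForceCurve(
            delta=np.asarray(self.delta_ratio) * R,
            force=np.asarray(self.force_ratio) * material.E_star * R * R,
        )


def hertz_force(material: Material, config: ContactConfig, delta):
    """Hertz force (pN) for indentation ``delta`` (nm): (4/3) E* sqrt(R*) d^1.5."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be nonnegative")
    out = (4.0 / 3.0) * material.E_star * math.sqrt(config.R_star) * delta**1.5
    return out if out.ndim else float(out)


def hertz_indentation(material: Material, config: ContactConfig, force):
    """Inverse Hertz law: indentation (nm) producing ``force`` (pN)."""
    force = np.asarray(force, dtype=float)
    if np.any(force < 0):
        raise ValueError("force must be nonnegative")
    out = (3.0 * force / (4.0 * material.E_star * math.sqrt(config.R_star))) ** (2.0 / 3.0)
    return out if out.ndim else float(out)


def sneddon_modified_force(
    material: Material,
    tip: TipGeometry,
    r: float,
    delta,
    f: Optional[Callable] = None,
):
    """Conical (Sneddon) force with an optional sample-curvature correction.

    ``F = (2/pi) E* tan(theta) delta^2 * f(delta, r)``.  The correction
    ``f`` is an empirically fitted function of indentation for spherical
    samples of radius ``r``; by default (``f=None`` or ``r=inf``) it is 1 and
    the classical cone-on-half-space law is returned.
    """
    if not r > 0:
        raise ValueError("sample radius r must be positive (or inf)")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be nonnegative")
    base = (2.0 / math.pi) * material.E_star * math.tan(tip.theta) * delta**2
    if f is not None and not math.isinf(r):
        base = base * np.asarray(f(delta, r), dtype=float)
    return base if base.ndim else float(base)


def double_contact_delta(material: Material, R: float, r: float, force):
    """Forward double-contact map: measured indentation delta(F) (nm).

    delta = delta_I + delta_C with both contacts Hertzian: the tip contact
    uses the effective radius R* (1/R* = 1/R + 1/r) and the sphere-substrate
    contact uses the sphere radius r (sphere on a rigid plane).
    """
    if not (R > 0 and r > 0 and math.isfinite(r)):
        raise ValueError("R must be positive and r positive and finite")
    force = np.asarray(force, dtype=float)
    R_star = ContactConfig(R=R, r=r).R_star
    coef = (3.0 / (4.0 * material.E_star)) ** (2.0 / 3.0)
    out = coef * force ** (2.0 / 3.0) * (R_star ** (-1.0 / 3.0) + r ** (-1.0 / 3.0))
    return out if out.ndim else float(out)


def double_contact_force(material: Material, R: float, r: float, delta):
    """Double-contact force F(delta) (pN) by inverting the forward map.

    The forward map delta(F) is strictly increasing, so the root is unique;
    it is bracketed by [0, F_Hertz(delta; R*)] because the series compliance
    can only soften the response.  Solved to 1e-12 relative tolerance.
    """
    if not (R > 0 and r > 0 and math.isfinite(r)):
        raise ValueError("R must be positive and r positive and finite")
    delta_arr = np.atleast_1d(np.asarray(delta, dtype=float))
    if np.any(delta_arr < 0):
        raise ValueError("indentation must be nonnegative")
    cfg = ContactConfig(R=R, r=r)
    out = np.zeros_like(delta_arr)
    for i, d in enumerate(delta_arr):
        if d == 0.0:
            continue
        f_hi = hertz_force(material, cfg, d)
        try:
            out[i] = brentq(
                lambda F: double_contact_delta(material, R, r, F) - d,
                0.0,
                f_hi,
                xtol=1e-15,
                rtol=1e-13,
                maxiter=200,
            )
        except (ValueError, RuntimeError) as exc:  # pragma: no cover - diagnostics
            raise RuntimeError(
                f"double-contact solve failed at delta={d} nm "
                f"(bracket [0, {f_hi}] pN): {exc}"
            ) from exc
    return out if np.ndim(delta) else float(out[0])


def nondimensionalize(curve: ForceCurve, material: Material, R: float) -> DimensionlessCurve:
    """Scale a force curve to F/(E* R^2) vs delta/R (both dimensionless)."""
    if not R > 0:
        raise ValueError("R must be positive")
    scale = material.E_star * R * R
    return DimensionlessCurve(
        delta_ratio=curve.delta / R, force_ratio=curve.force / scale
    )
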