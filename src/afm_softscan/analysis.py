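"""Quantification of simulated AFM images and force data.

Metrics mirror common AFM practice: full-width half-maximum of a feature
profile, apparent volume from grain analysis, cosine Fourier amplitudes of
periodic traces, and apparent Young's moduli E_AFM from contact-model fits
to force-indentation curves clipped at a force ceiling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .contact import (
    ContactConfig,
    ForceCurve,
    double_contact_force,
    hertz_force,
    sneddon_modified_force,
)
from .geometry import Material, TipGeometry
from .scan import AFMImage, ForceVolume

__all__ = [
    "FourierSpectrum",
    "ModulusMap",
    "fwhm",
    "apparent_volume",
    "fourier_coefficients",
    "higher_order_content",
    "fit_modulus",
    "modulus_map",
]


def fwhm(profile: np.ndarray, x: Optional[np.ndarray] = None, baseline: float = 0.0) -> float:
    """Full width at half maximum of a 1-D profile (nm).

    The half-maximum level is baseline + (max - baseline)/2 with the baseline
    at the substrate (0 by default).  Crossings on either side of the global
    maximum are located by linear interpolation.
    """
    profile = np.asarray(profile, dtype=float)
    x = np.arange(profile.size, dtype=float) if x is None else np.asarray(x, float)
    i_max = int(np.argmax(profile))
    peak = profile[i_max]
    if peak <= baseline:
        raise ValueError("profile never rises above the baseline")
    half = baseline + 0.5 * (peak - baseline)

    def cross(idx_range, forward):
        prev = i_max
        for i in idx_range:
            if profile[i] < half:
                x0, x1 = x[i], x[prev]
                y0, y1 = profile[i], profile[prev]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = i
        return x[idx_range[-1]] if len(idx_range) else x[i_max]

    left = cross(range(i_max - 1, -1, -1), False)
    right = cross(range(i_max + 1, profile.size), True)
    return float(right - left)


def apparent_volume(image: AFMImage, footprint: str = "above-baseline") -> float:
    """Apparent volume (nm^3) under an image, as in AFM grain analysis.

    Trapezoidal integral of height over the footprint: all cells above the
    substrate baseline (default), or only cells at or above half the maximum
    ("half-max").
    """
    h = image.heights.copy()
    if footprint == "half-max":
        h[h < 0.5 * h.max()] = 0.0
    elif footprint != "above-baseline":
        raise ValueError(f"unknown footprint rule '{footprint}'")
    if not (h > 0).any():
        warnings.warn("image has no cells above the baseline; volume is 0", stacklevel=2)
        return 0.0
    if image.y.size > 1:
        return float(np.trapezoid(np.trapezoid(h, image.y, axis=1), image.x))
    return float(np.trapezoid(h[:, 0], image.x))


@dataclass
class FourierSpectrum:
    """Cosine amplitudes A_n of a periodic trace, n = 0..N.

    Wave numbers are k_n = 2 pi n / lambda_1; A_0 is the mean offset.  For a
    trace symmetric about x = 0 the sine content vanishes, so the cosine
    series is complete.
    """

    A: np.ndarray
    lambda1: float

    @property
    def N(self) -> int:
        return self.A.size - 1

    @property
    def k(self) -> np.ndarray:
        return 2.0 * math.pi * np.arange(self.A.size) / self.lambda1

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        n = np.arange(self.A.size)
        return (self.A[None, :] * np.cos(np.outer(x, 2 * math.pi * n / self.lambda1))).sum(axis=1)


def fourier_coefficients(
    profile: np.ndarray,
    N: int,
    x: Optional[np.ndarray] = None,
    period: Optional[float] = None,
) -> FourierSpectrum:
    """Cosine projection of a profile sampled uniformly over exactly one period.

    The M samples are assumed to cover [0, lambda) with the symmetry point at
    x = 0 (first sample); A_n = (2/M) sum_j h_j cos(2 pi n j / M), A_0 the
    mean.  Raises on non-uniform sampling.
    """
    profile = np.asarray(profile, dtype=float)
    M = profile.size
    if x is not None:
        x = np.asarray(x, dtype=float)
        steps = np.diff(x)
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
            raise ValueError("profile must be uniformly sampled")
        lam = float(M * steps[0])
    else:
        lam = float(period) if period is not None else float(M)
    if N >= M // 2:
        raise ValueError(f"N={N} requires more than {2 * N} samples per period")
    j = np.arange(M)
    n = np.arange(N + 1)
    basis = np.cos(2.0 * math.pi * np.outer(n, j) / M)
    A = (2.0 / M) * basis @ profile
    A[0] = profile.mean()
    return FourierSpectrum(A=A, lambda1=lam)


def higher_order_content(spectrum: FourierSpectrum, N: int = 50, mode: str = "rms") -> float:
    """Aggregate magnitude of the above-fundamental amplitudes A_2..A_N.

    ``mode="rms"`` (default) is the root mean square, ``"rss"`` the root sum
    of squares.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    hi = spectrum.A[2 : N + 1]
    if hi.size == 0:
        return 0.0
    if mode == "rms":
        return float(np.sqrt(np.mean(hi**2)))
    if mode == "rss":
        return float(np.sqrt(np.sum(hi**2)))
    raise ValueError(f"unknown mode '{mode}'")


@dataclass
class ModulusMap:
    """Apparent Young's modulus per scan position from per-column fits."""

    positions: np.ndarray
    E_AFM: np.ndarray
    residuals: np.ndarray
    model: str
    force_ceiling: Optional[float]
    failures: list = field(default_factory=list)


def _model_force(model, E, nu, R, r, theta, delta):
    mat = Material(E=E, nu=nu)
    if model == "hertz":
        # AFM convention: the sample curvature is unknown, fit with R* -> R
        return hertz_force(mat, ContactConfig(R=R, r=math.inf), delta)
    if model == "sneddon":
        tip = TipGeometry(R=R, theta=theta if theta else math.radians(20.0))
        return sneddon_modified_force(mat, tip, math.inf, delta)
    if model == "double_contact":
        if r is None or not math.isfinite(r):
            raise ValueError("double_contact fit requires a finite sample radius r")
        return double_contact_force(mat, R, r, delta)
    raise ValueError(f"unknown model '{model}'")


def fit_modulus(
    curve: ForceCurve,
    model: str,
    R: float,
    r: Optional[float] = None,
    theta: Optional[float] = None,
    nu: float = 0.3,
    force_ceiling_pn: Optional[float] = None,
    E0: float = 100.0,
) -> tuple:
    """Fit a contact model to a force curve with E as the only free parameter.

    Per AFM convention the Hertz fit substitutes R for R* (the sample's local
    curvature is treated as unknown).  Data are clipped to
    F <= force_ceiling_pn (closed interval) when a ceiling is given.  E is
    log-parameterized to enforce positivity; returns (E_AFM MPa, rms residual pN).
    """
    delta, force = curve.delta, curve.force
    if force_ceiling_pn is not None:
        keep = force <= force_ceiling_pn
        delta, force = delta[keep], force[keep]
    if delta.size < 5:
        raise ValueError("need at least 5 samples below the force ceiling to fit")

    def resid(logE):
        return _model_force(model, math.exp(logE[0]), nu, R, r, theta, delta) - force

    res = least_squares(resid, x0=[math.log(E0)], method="trf", xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise RuntimeError(f"modulus fit did not converge: {res.message}")
    E_fit = math.exp(res.x[0])
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return E_fit, rms


def modulus_map(
    volume: ForceVolume,
    model: str = "hertz",
    force_ceiling: Optional[float] = 0.1,
    r: Optional[float] = None,
) -> ModulusMap:
    """Per-column E_AFM over a force volume, clipped at a dimensionless ceiling.

    ``force_ceiling`` is in F/(E* R^2) units of the generating material and
    tip (None disables clipping).  Columns that fail to fit are recorded and
    skipped, not fatal.
    """
    R = volume.tip.R
    ceiling_pn = (
        force_ceiling * volume.material.E_star * R * R
        if force_ceiling is not None
        else None
    )
    nx, ny = volume.x.size, volume.y.size
    E = np.full((nx, ny), np.nan)
    resids = np.full((nx, ny), np.nan)
    failures = []
    for i in range(nx):
        for j in range(ny):
            try:
                E[i, j], resids[i, j] = fit_modulus(
                    volume.column(i, j), model, R, r=r, theta=volume.tip.theta,
                    nu=volume.material.nu, force_ceiling_pn=ceiling_pn,
                )
            except (ValueError, RuntimeError) as exc:
                failures.append(((i, j), str(exc)))
    return ModulusMap(
        positions=volume.x.copy(),
        E_AFM=E[:, 0] if ny == 1 else E,
        residuals=resids[:, 0] if ny == 1 else resids,
        model=model,
        force_ceiling=force_ceiling,
        failures=failures,
    )
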