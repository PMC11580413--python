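"""Tip and sample geometry.

The probe is a rigid cone of half-opening angle ``theta`` terminated by a
spherical cap of radius ``R``; the two branches meet tangentially at lateral
offset ``rho_t = R cos(theta)`` and height ``z_t = R (1 - sin(theta))`` above
the apex, so the profile is C1-continuous.  Samples are single-valued top
surfaces ``h(x, y)`` over a rigid substrate plane at ``z = 0`` (heights in
nm), either parametric (hemisphere, 1-D sinusoid) or the van der Waals upper
envelope of a molecular structure.

Internal units are nm, pN and MPa (1 MPa nm^2 = 1 pN, so dimensionless force
``F/(E* R^2)`` needs no conversion factor).  Molecular coordinates arrive in
angstroms and are converted on construction of the height field.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "TipGeometry",
    "Material",
    "HeightField",
    "AtomSet",
    "VDW_RADII",
    "FALLBACK_VDW_RADIUS",
    "tip_profile",
    "spherical_validity_limit",
    "make_hemisphere",
    "make_sinusoid",
    "molecule_height_field",
    "build_bdna",
]

#: van der Waals radii (angstrom), half the UFF nonbonded distance x_i.
VDW_RADII = {
    "H": 1.443,
    "C": 1.926,
    "N": 1.830,
    "O": 1.750,
    "P": 2.074,
    "S": 2.018,
}

FALLBACK_VDW_RADIUS = 1.70  # angstrom, used for elements missing from the table


@dataclass(frozen=True)
class TipGeometry:
    """Rigid cone + spherical-cap probe.

    Parameters
    ----------
    R : float
        Spherical-cap radius in nm.
    theta : float
        Cone half-opening angle in radians, in (0, pi/2).
    """

    R: float
    theta: float

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"tip radius must be positive, got R={self.R}")
        if not 0 < self.theta < math.pi / 2:
            raise ValueError(
                f"cone half-angle must lie in (0, pi/2) rad, got theta={self.theta}"
            )

    @property
    def rho_t(self) -> float:
        """Lateral offset of the sphere-cone tangent point (nm)."""
        return self.R * math.cos(self.theta)

    @property
    def z_t(self) -> float:
        """Height of the tangent point above the apex (nm)."""
        return self.R * (1.0 - math.sin(self.theta))

    def profile(self, rho):
        return tip_profile(self, rho)

    @classmethod
    def from_degrees(cls, R: float, theta_deg: float) -> "TipGeometry":
        return cls(R=R, theta=math.radians(theta_deg))


def tip_profile(tip: TipGeometry, rho):
    """Height of the tip surface above the apex at lateral offset ``rho`` (nm).

    Spherical branch ``R - sqrt(R^2 - rho^2)`` for ``rho <= R cos(theta)``,
    conical branch ``z_t + (rho - rho_t)/tan(theta)`` beyond.  Vectorized.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("lateral offset rho must be nonnegative")
    R, rho_t, z_t = tip.R, tip.rho_t, tip.z_t
    sphere = R - np.sqrt(np.clip(R * R - np.minimum(rho, rho_t) ** 2, 0.0, None))
    cone = z_t + (rho - rho_t) / math.tan(tip.theta)
    out = np.where(rho <= rho_t, sphere, cone)
    return out if out.ndim else float(out)


def spherical_validity_limit(tip: TipGeometry) -> float:
    """Largest indentation (nm) for which contact stays on the spherical cap.

    Equals ``R (1 - sin theta)``, the tangent-point height: deeper than this
    the conical flank enters the contact and sphere-based contact laws no
    longer describe the tip.
    """
    return tip.R * (1.0 - math.sin(tip.theta))


@dataclass(frozen=True)
class Material:
    """Linear-elastic, isotropic sample material.

    E is the Young's modulus in MPa, nu the Poisson ratio.  ``E_star`` is the
    reduced modulus E/(1 - nu^2) of a rigid indenter on this material.
    """

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not 0 <= self.nu < 0.5:
            raise ValueError(f"Poisson ratio must lie in [0, 0.5), got {self.nu}")

    @property
    def E_star(self) -> float:
        return self.E / (1.0 - self.nu**2)


@dataclass
class HeightField:
    """Single-valued sample top surface h(x, y) on a uniform lateral grid.

    ``heights`` has shape ``(len(x), len(y))`` with the substrate plane at 0.
    ``principal_curvatures``, when set by a parametric constructor, returns
    the exact sample surface convexities (1/nm, positive = convex bump) at a
    lateral point; discrete fields fall back to finite differences.
    """

    x: np.ndarray
    y: np.ndarray
    heights: np.ndarray
    principal_curvatures: Optional[Callable[[float, float], tuple]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.shape != (self.x.size, self.y.size):
            raise ValueError(
                f"heights shape {self.heights.shape} does not match grid "
                f"({self.x.size}, {self.y.size})"
            )
        for name, axis in (("x", self.x), ("y", self.y)):
            if axis.size > 1:
                steps = np.diff(axis)
                if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
                    raise ValueError(f"{name} grid spacing is not uniform")
        if np.any(self.heights < -1e-12):
            raise ValueError("heights must be nonnegative (substrate at z=0)")
        self.heights = np.clip(self.heights, 0.0, None)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 0.0

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0]) if self.y.size > 1 else 0.0

    @property
    def h_max(self) -> float:
        return float(self.heights.max())

    def curvatures_at(self, xq: float, yq: float) -> tuple:
        """Principal sample convexities (1/nm) at the lateral point (xq, yq).

        Uses the analytic callable when available, otherwise a centered
        finite-difference Hessian of the sampled surface (convexity is the
        negated Hessian eigenvalue: positive for a bump).
        """
        if self.principal_curvatures is not None:
            k1, k2 = self.principal_curvatures(xq, yq)
            return float(k1), float(k2)
        i = int(np.clip(np.searchsorted(self.x, xq), 1, self.x.size - 2))
        j = int(np.clip(np.searchsorted(self.y, yq), 1, self.y.size - 2)) if self.y.size > 2 else 0
        h = self.heights
        hxx = (h[i + 1, j] - 2 * h[i, j] + h[i - 1, j]) / self.dx**2 if self.x.size > 2 else 0.0
        if self.y.size > 2:
            hyy = (h[i, j + 1] - 2 * h[i, j] + h[i, j - 1]) / self.dy**2
            hxy = (
                h[i + 1, j + 1] - h[i + 1, j - 1] - h[i - 1, j + 1] + h[i - 1, j - 1]
            ) / (4 * self.dx * self.dy)
        else:
            hyy = 0.0
            hxy = 0.0
        hess = np.array([[hxx, hxy], [hxy, hyy]])
        eigs = np.linalg.eigvalsh(hess)
        return float(-eigs[1]), float(-eigs[0])


def _grid_1d(half_extent: float, spacing: float) -> np.ndarray:
    n = int(round(half_extent / spacing))
    return np.arange(-n, n + 1) * spacing


def make_hemisphere(
    r: float,
    spacing: Optional[float] = None,
    extent: Optional[float] = None,
) -> HeightField:
    """Elastic hemisphere of radius ``r`` (nm) resting on the substrate.

    h(x, y) = sqrt(r^2 - x^2 - y^2) inside the footprint, 0 outside.
    ``extent`` is the half-width of the square grid (default ``2 r`` so that
    dilated images of moderately blunt tips stay inside the field).
    """
    if not r > 0:
        raise ValueError("hemisphere radius must be positive")
    spacing = r / 50.0 if spacing is None else float(spacing)
    extent = 2.0 * r if extent is None else float(extent)
    if 2.0 * r / spacing < 8:
        warnings.warn(
            f"grid spacing {spacing} nm resolves the hemisphere diameter with "
            "fewer than 8 cells; results will be coarse",
            stacklevel=2,
        )
    x = _grid_1d(extent, spacing)
    y = _grid_1d(extent, spacing)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rho2 = xx**2 + yy**2
    h = np.sqrt(np.clip(r * r - rho2, 0.0, None))
    h[rho2 > r * r] = 0.0
    return HeightField(x, y, h, principal_curvatures=lambda xq, yq: (1.0 / r, 1.0 / r))


def make_sinusoid(
    wavelength: float,
    amplitude: float,
    width: Optional[float] = None,
    spacing: Optional[float] = None,
    y_extent: Optional[float] = None,
) -> HeightField:
    """1-D periodic surface, crests along y: h(x) = A (1 + cos(2 pi x / lam)) / 2.

    Peak-to-trough amplitude equals ``amplitude``; troughs sit on the
    substrate at h = 0 and a crest is centered at x = 0.  ``width`` is the
    total x extent (default 4 wavelengths).
    """
    if not wavelength > 0:
        raise ValueError("wavelength must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    lam = float(wavelength)
    width = 4.0 * lam if width is None else float(width)
    spacing = lam / 100.0 if spacing is None else float(spacing)
    y_half = lam / 2.0 if y_extent is None else float(y_extent) / 2.0
    x = _grid_1d(width / 2.0, spacing)
    y = _grid_1d(y_half, spacing)
    h1d = amplitude * (1.0 + np.cos(2.0 * np.pi * x / lam)) / 2.0
    h = np.repeat(h1d[:, None], y.size, axis=1)
    k = 2.0 * np.pi / lam

    def curv(xq: float, yq: float) -> tuple:
        # convexity along x: -h''(x); flat along y
        return (amplitude / 2.0) * k * k * math.cos(k * xq), 0.0

    return HeightField(x, y, h, principal_curvatures=curv)


@dataclass
class AtomSet:
    """Atoms as spheres: element symbols, centers (angstrom), vdW radii (angstrom)."""

    elements: np.ndarray
    coords: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        n = self.elements.size
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if self.radii.shape != (n,):
            raise ValueError("radii must have shape (n_atoms,)")
        if n and not np.all(self.radii > 0):
            raise ValueError("all van der Waals radii must be positive")

    def __len__(self) -> int:
        return int(self.elements.size)

    @classmethod
    def from_elements(cls, elements, coords) -> "AtomSet":
        """Build from symbols + coordinates, radii from the bundled vdW table."""
        elements = np.asarray(elements, dtype=object)
        radii = np.empty(elements.size)
        unknown = set()
        for i, el in enumerate(elements):
            key = str(el).strip().capitalize()
            if key in VDW_RADII:
                radii[i] = VDW_RADII[key]
            else:
                radii[i] = FALLBACK_VDW_RADIUS
                unknown.add(key)
        if unknown:
            warnings.warn(
                f"unknown element(s) {sorted(unknown)}: using fallback vdW radius "
                f"{FALLBACK_VDW_RADIUS} A",
                stacklevel=2,
            )
        return cls(elements=elements, coords=np.asarray(coords, float), radii=radii)


def molecule_height_field(
    atoms: AtomSet,
    spacing: float = 0.55,
    cleave_fraction: float = 0.0,
    margin: float = 0.5,
    x_range: Optional[tuple] = None,
    y_range: Optional[tuple] = None,
) -> HeightField:
    """Upper van der Waals envelope of a molecule lying on the substrate.

    The molecule is translated so its lowest sphere touches z = 0, the upper
    envelope ``max_i [z_i + sqrt(r_i^2 - d_i^2)]`` is rasterized on a uniform
    grid (``spacing`` in nm; molecular input is in angstrom and converted),
    then shifted down by ``cleave_fraction`` of the molecular height —
    emulating partial embedding of the molecule in a rigid base — and clipped
    at the substrate.

    Parameters are in nm except the AtomSet, which follows PDB conventions
    (angstrom).
    """
    if len(atoms) == 0:
        raise ValueError("AtomSet is empty")
    if not 0 <= cleave_fraction < 1:
        raise ValueError("cleave_fraction must lie in [0, 1)")
    coords = atoms.coords / 10.0  # A -> nm
    radii = atoms.radii / 10.0
    z = coords[:, 2] - (coords[:, 2] - radii).min()  # rest lowest sphere on z=0
    mol_height = float((z + radii).max())
    if x_range is None:
        x_range = (coords[:, 0].min() - radii.max() - margin,
                   coords[:, 0].max() + radii.max() + margin)
    if y_range is None:
        y_range = (coords[:, 1].min() - radii.max() - margin,
                   coords[:, 1].max() + radii.max() + margin)
    # snap bins to multiples of the spacing so symmetry points fall on nodes
    x = spacing * np.arange(math.floor(x_range[0] / spacing),
                            math.ceil(x_range[1] / spacing) + 1)
    y = spacing * np.arange(math.floor(y_range[0] / spacing),
                            math.ceil(y_range[1] / spacing) + 1)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    env = np.zeros_like(xx)
    for xa, ya, za, ra in zip(coords[:, 0], coords[:, 1], z, radii):
        d2 = (xx - xa) ** 2 + (yy - ya) ** 2
        cap = za + np.sqrt(np.clip(ra * ra - d2, 0.0, None))
        np.maximum(env, np.where(d2 <= ra * ra, cap, 0.0), out=env)
    env -= cleave_fraction * mol_height
    if env.max() <= 0:
        raise ValueError("cleave_fraction removed the entire molecule")
    return HeightField(x, y, np.clip(env, 0.0, None))


# --- idealized B-DNA fixture ------------------------------------------------

# Per-strand, per-base-pair template in cylindrical coordinates:
# (element, radial offset A, azimuth offset deg, axial offset A).
# Coarse-grained to one sphere per chemical group (phosphate, sugar carbons,
# base ring atoms), sized to reproduce the ~20 A vdW envelope of B-DNA.
_BDNA_STRAND_TEMPLATE = [
    ("P", 8.91, 0.0, 0.0),
    ("O", 9.3, 6.0, 1.0),
    ("O", 9.3, -6.0, -1.0),
    ("C", 7.9, 12.0, 0.4),   # sugar C5'/C4'
    ("C", 7.0, 20.0, 0.0),   # sugar C1'
    ("N", 5.3, 26.0, 0.0),   # glycosidic nitrogen
    ("C", 3.8, 32.0, 0.0),   # base ring
    ("N", 2.4, 40.0, 0.0),   # base ring
    ("C", 1.0, 55.0, 0.0),   # ring atom near the helix axis
]

_BDNA_RISE = 3.4     # A per base pair
_BDNA_TWIST = 36.0   # deg per base pair
_BDNA_STRAND_OFFSET = 140.0  # deg between strand azimuths (major/minor grooves)


def build_bdna(n_bp: int, axis: str = "z") -> AtomSet:
    """Idealized straight B-form DNA duplex of ``n_bp`` base pairs.

    Built from the canonical helical parameters (rise 3.4 A, twist 36 deg per
    base pair) with a coarse one-sphere-per-group template per strand, giving
    a ~20 A diameter van der Waals envelope with major/minor grooves from the
    140 deg inter-strand azimuth offset.  Deterministic given ``n_bp``.

    ``axis`` selects the helix axis orientation: "z" (canonical) or "x"
    (lying on the substrate, ready for imaging).  Coordinates in angstrom,
    centered on the helix axis.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    elements, coords = [], []
    for i in range(n_bp):
        phi0 = math.radians(_BDNA_TWIST) * i
        z0 = _BDNA_RISE * i
        for strand_sign, strand_phi in ((1.0, 0.0), (-1.0, math.radians(_BDNA_STRAND_OFFSET))):
            for el, rad, dphi_deg, dz in _BDNA_STRAND_TEMPLATE:
                phi = phi0 + strand_phi + strand_sign * math.radians(dphi_deg)
                elements.append(el)
                coords.append(
                    (rad * math.cos(phi), rad * math.sin(phi), z0 + strand_sign * dz)
                )
    coords = np.asarray(coords)
    coords[:, 2] -= coords[:, 2].mean()
    if axis == "x":
        coords = coords[:, [2, 0, 1]]
    elif axis != "z":
        raise ValueError("axis must be 'z' or 'x'")
    return AtomSet.from_elements(elements, coords)
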