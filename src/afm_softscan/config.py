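"""Run configuration and named reproduction presets.

A RunConfig collects every knob of a simulation run — tip, material, sample
specification, scan and indentation grids, engine and force setpoints — and
round-trips losslessly through YAML.  The named presets reproduce the study
conditions of the bundled scenarios: sphere-on-support model validation,
hemisphere imaging, periodic (sinusoid) imaging, and the DNA scan.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .geometry import Material, TipGeometry

__all__ = ["RunConfig", "dna_preset", "hemisphere_preset", "sinusoid_preset",
           "sphere_validation_preset", "PRESETS", "get_preset"]


@dataclass
class RunConfig:
    """Declarative description of one simulation run (units: nm, MPa, pN, deg)."""

    tip_radius: float
    cone_angle_deg: float
    youngs_modulus: float = 100.0
    poisson_ratio: float = 0.3
    sample: str = "hemisphere"
    sample_params: dict = field(default_factory=dict)
    scan_spacing: float = 0.5
    scan_extent: Optional[float] = None
    n_scan_positions: Optional[int] = None
    delta_max: Optional[float] = None
    n_delta: int = 30
    engine: str = "local-analytic"
    setpoints: tuple = ()
    setpoints_dimensionless: bool = True
    seed: int = 0
    output_dir: str = "afm_softscan_out"

    def __post_init__(self) -> None:
        if self.tip_radius <= 0:
            raise ValueError("tip radius must be positive")
        if not 0 < self.cone_angle_deg < 90:
            raise ValueError("cone angle must lie in (0, 90) degrees")
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        self.setpoints = tuple(float(s) for s in self.setpoints)

    @property
    def tip(self) -> TipGeometry:
        return TipGeometry.from_degrees(self.tip_radius, self.cone_angle_deg)

    @property
    def material(self) -> Material:
        return Material(E=self.youngs_modulus, nu=self.poisson_ratio)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        data["setpoints"] = tuple(data.get("setpoints", ()))
        data["sample_params"] = dict(data.get("sample_params", {}))
        return cls(**data)

    def digest(self) -> str:
        """Short provenance hash of the full configuration."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def sphere_validation_preset(r_over_R: float = 3.0, R: float = 1.0) -> RunConfig:
    """Sphere-on-rigid-support validation of the contact engines (tip 20 deg)."""
    return RunConfig(
        tip_radius=R, cone_angle_deg=20.0, sample="sphere",
        sample_params={"r": r_over_R * R}, delta_max=0.3 * R,
    )


def hemisphere_preset(R_over_r: float = 1.4, r: float = 5.0) -> RunConfig:
    """Elastic hemisphere (r = 5 nm) probed by a cone+cap tip, 20 deg."""
    return RunConfig(
        tip_radius=R_over_r * r, cone_angle_deg=20.0, sample="hemisphere",
        sample_params={"r": r}, scan_spacing=0.1,
    )


def sinusoid_preset(R_over_lambda: float = 0.2, wavelength: float = 10.0) -> RunConfig:
    """1-D sinusoidal surface, amplitude = wavelength = 10 nm, width 4 wavelengths."""
    return RunConfig(
        tip_radius=R_over_lambda * wavelength, cone_angle_deg=20.0,
        sample="sinusoid",
        sample_params={"wavelength": wavelength, "amplitude": wavelength,
                       "width": 4.0 * wavelength},
        scan_spacing=wavelength / 100.0,
    )


def dna_preset() -> RunConfig:
    """80-bp B-DNA on a 5 nm x 20 nm base: tip R = 1.8 nm, half-angle 5 deg.

    The sample field uses 0.55 nm bins; the scan grid is 8 x 30 = 240
    positions over the base.  Imaging setpoint 100 pN.
    """
    return RunConfig(
        tip_radius=1.8, cone_angle_deg=5.0, youngs_modulus=100.0,
        poisson_ratio=0.3, sample="bdna",
        sample_params={"n_bp": 80, "cleave_fraction": 0.20, "bin": 0.55,
                       "base_width": 5.0, "base_length": 20.0,
                       "scan_nx": 30, "scan_ny": 8},
        n_scan_positions=240, setpoints=(100.0,), setpoints_dimensionless=False,
    )


PRESETS = {
    "sphere-validation": sphere_validation_preset,
    "hemisphere": hemisphere_preset,
    "sinusoid": sinusoid_preset,
    "dna": dna_preset,
}


def get_preset(name: str) -> RunConfig:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset '{name}'; available: {sorted(PRESETS)}")
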