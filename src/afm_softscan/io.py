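"""Readers and writers: PDB structures, height fields, curves, images.

PDB parsing goes through biotite; all other formats are small plain-text
containers (header + matrix, or CSV via pandas) so results remain diffable
and portable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .contact import ForceCurve
from .geometry import AtomSet, HeightField
from .scan import AFMImage

__all__ = [
    "read_pdb",
    "write_pdb",
    "write_height_field",
    "read_height_field",
    "write_force_curve",
    "read_force_curve",
    "write_image_csv",
]


def read_pdb(path) -> AtomSet:
    """Read ATOM/HETATM records into an AtomSet (model 1, altloc 'A'/blank).

    Elements come from the element column with fallback to the atom name;
    van der Waals radii are assigned from the bundled table (unknown
    elements get the fallback radius with a warning).
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    if atoms.array_length() == 0:
        raise ValueError(f"no atoms parsed from {path}")
    elements = []
    for el, name in zip(atoms.element, atoms.atom_name):
        el = str(el).strip()
        if not el:
            el = "".join(c for c in str(name).strip() if c.isalpha())[:1]
        elements.append(el.capitalize())
    return AtomSet.from_elements(elements, atoms.coord)


def write_pdb(path, atom_set: AtomSet) -> None:
    """Write an AtomSet as a minimal single-model PDB file."""
    n = len(atom_set)
    atoms = struc.AtomArray(n)
    atoms.coord = atom_set.coords.astype(np.float32)
    atoms.element = np.array([str(e).upper() for e in atom_set.elements])
    atoms.atom_name = atoms.element
    atoms.res_name = np.full(n, "DNA")
    atoms.res_id = np.ones(n, dtype=int)
    atoms.chain_id = np.full(n, "A")
    atoms.hetero = np.full(n, True)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


_HF_MAGIC = "# afm-softscan height field v1"


def write_height_field(path, hf: HeightField) -> None:
    """Plain-text matrix with a small grid header (origin, spacing, nm)."""
    with open(path, "w") as fh:
        fh.write(_HF_MAGIC + "\n")
        fh.write(f"# x0={float(hf.x[0])!r} dx={float(hf.dx)!r} nx={hf.x.size}\n")
        fh.write(f"# y0={float(hf.y[0])!r} dy={float(hf.dy)!r} ny={hf.y.size}\n")
        fh.write("# units=nm rows=x cols=y\n")
        np.savetxt(fh, hf.heights, fmt="%.17g")


def read_height_field(path) -> HeightField:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _HF_MAGIC.strip("# ").strip() and magic != _HF_MAGIC:
            raise ValueError(f"{path} is not a height-field file")
        xline = dict(kv.split("=") for kv in fh.readline().strip("#\n ").split())
        yline = dict(kv.split("=") for kv in fh.readline().strip("#\n ").split())
        fh.readline()
        heights = np.loadtxt(fh, ndmin=2)
    x = float(xline["x0"]) + float(xline["dx"]) * np.arange(int(xline["nx"]))
    y = float(yline["y0"]) + float(yline["dy"]) * np.arange(int(yline["ny"]))
    return HeightField(x, y, heights)


def write_force_curve(path, curve: ForceCurve) -> None:
    df = pd.DataFrame({"delta_nm": curve.delta, "force_pN": curve.force})
    df.to_csv(path, index=False)


def read_force_curve(path) -> ForceCurve:
    df = pd.read_csv(path)
    return ForceCurve(delta=df["delta_nm"].to_numpy(), force=df["force_pN"].to_numpy())


def write_image_csv(path, image: AFMImage) -> None:
    """AFM image as tidy CSV (x_nm, y_nm, height_nm) with setpoint metadata."""
    xx, yy = np.meshgrid(image.x, image.y, indexing="ij")
    df = pd.DataFrame(
        {"x_nm": xx.ravel(), "y_nm": yy.ravel(), "height_nm": image.heights.ravel()}
    )
    with open(path, "w") as fh:
        fh.write(f"# mode={image.mode} setpoint_pN={image.setpoint_pn!r}\n")
        df.to_csv(fh, index=False)
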