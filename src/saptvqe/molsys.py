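"""Molecular geometries, XYZ I/O, and deterministic benchmark fixtures.

Coordinates are stored internally in bohr; XYZ files are read and written in
angstrom. All fixture generators are pure functions of their arguments so
that test systems are bit-for-bit reproducible without downloads.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_RADIUS_ANGSTROM, atomic_number

__all__ = [
    "Molecule",
    "DimerSystem",
    "XYZParseError",
    "load_xyz",
    "write_xyz",
    "make_water_dimer",
    "make_benzene_pbenzyne_tshape",
    "make_toy_dimer",
]


class XYZParseError(ValueError):
    """Raised when an XYZ file cannot be parsed; the message names the line."""


@dataclass(frozen=True)
class Molecule:
    """A rigid molecule: element symbols, coordinates (bohr), charge, multiplicity."""

    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), bohr
    charge: int = 0
    multiplicity: int = 1
    label: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) == 0:
            raise ValueError("molecule must contain at least one atom")
        if coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} inconsistent with "
                f"{len(self.elements)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        # resolves unknown symbols early
        zs = [atomic_number(e) for e in self.elements]
        n_elec = sum(zs) - self.charge
        if n_elec <= 0:
            raise ValueError("molecule has no electrons")
        if (n_elec - (self.multiplicity - 1)) % 2 != 0:
            raise ValueError(
                f"electron count {n_elec} inconsistent with multiplicity "
                f"{self.multiplicity}"
            )
        if len(self.elements) > 1:
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 0.1 * ANGSTROM_TO_BOHR:
                raise ValueError("two atoms closer than 0.1 angstrom")

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([atomic_number(e) for e in self.elements], dtype=int)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def nuclear_repulsion(self) -> float:
        """Internal nuclear repulsion energy, hartree."""
        z = self.atomic_numbers.astype(float)
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += z[i] * z[j] / np.linalg.norm(self.coords[i] - self.coords[j])
        return e

    def translated(self, shift_bohr) -> "Molecule":
        return replace(self, coords=self.coords + np.asarray(shift_bohr, float))


@dataclass(frozen=True)
class DimerSystem:
    """Two geometrically disjoint monomers with monomer-centered basis names."""

    monomer_a: Molecule
    monomer_b: Molecule
    basis_a: str = "sto-3g"
    basis_b: str = "sto-3g"

    def __post_init__(self):
        d = np.linalg.norm(
            self.monomer_a.coords[:, None, :] - self.monomer_b.coords[None, :, :],
            axis=-1,
        )
        if d.min() <= 0.5 * ANGSTROM_TO_BOHR:
            raise ValueError("monomers are not geometrically disjoint (>0.5 angstrom)")

    def min_separation_angstrom(self) -> float:
        d = np.linalg.norm(
            self.monomer_a.coords[:, None, :] - self.monomer_b.coords[None, :, :],
            axis=-1,
        )
        return float(d.min()) * BOHR_RADIUS_ANGSTROM

    def nuclear_repulsion_cross(self) -> float:
        """Intermolecular nuclear repulsion, hartree."""
        za = self.monomer_a.atomic_numbers.astype(float)
        zb = self.monomer_b.atomic_numbers.astype(float)
        d = np.linalg.norm(
            self.monomer_a.coords[:, None, :] - self.monomer_b.coords[None, :, :],
            axis=-1,
        )
        return float((za[:, None] * zb[None, :] / d).sum())

    def translated(self, shift_bohr) -> "DimerSystem":
        return DimerSystem(
            self.monomer_a.translated(shift_bohr),
            self.monomer_b.translated(shift_bohr),
            self.basis_a,
            self.basis_b,
        )


def load_xyz(path) -> Molecule:
    """Read a standard XYZ file (count line, comment line, `El x y z` rows, angstrom).

    The comment line may carry ``charge=<c> mult=<m>``; defaults are 0 and 1.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: line 1: empty file")
    try:
        n_atoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}: line 1: malformed atom-count line {lines[0]!r}")
    if len(lines) < 2 + n_atoms:
        raise XYZParseError(
            f"{path}: line {len(lines) + 1}: expected {n_atoms} atom rows, "
            f"found {max(len(lines) - 2, 0)}"
        )
    comment = lines[1] if len(lines) > 1 else ""
    charge, mult = 0, 1
    for tok in comment.split():
        if tok.startswith("charge="):
            charge = int(tok[len("charge="):])
        elif tok.startswith("mult="):
            mult = int(tok[len("mult="):])
    elements, coords = [], []
    for k in range(n_atoms):
        lineno = 3 + k
        parts = lines[2 + k].split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {lineno}: malformed atom row")
        sym = parts[0]
        try:
            atomic_number(sym)
        except KeyError:
            raise XYZParseError(f"{path}: line {lineno}: unknown element {sym!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}: line {lineno}: coordinate parse failure")
        elements.append(sym.capitalize())
        coords.append(xyz)
    return Molecule(
        elements=tuple(elements),
        coords=np.asarray(coords) * ANGSTROM_TO_BOHR,
        charge=charge,
        multiplicity=mult,
        label=comment.strip(),
    )


def write_xyz(mol: Molecule, path) -> None:
    """Write a standard XYZ file in angstrom with 10 decimal places."""
    with open(path, "w") as fh:
        fh.write(f"{mol.n_atoms}\n")
        fh.write(f"charge={mol.charge} mult={mol.multiplicity} {mol.label}".strip() + "\n")
        for el, xyz in zip(mol.elements, mol.coords * BOHR_RADIUS_ANGSTROM):
            fh.write(f"{el:<2s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}\n")


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

_R_OH_EQ = 0.9572  # angstrom, equilibrium water
_A_HOH = 104.52    # degrees
_R_OO = 2.91       # angstrom, O...O hydrogen-bond distance (fixed)


def _water_stretched(r_oh: float) -> Molecule:
    """The hydrogen-bond *accepting* water at the origin, hydrogens in the
    xz plane with the HOH bisector along -x (pointing away from the partner).

    Both O-H bonds have length ``r_oh`` (angstrom); the HOH angle and the
    orientation are held fixed as the bonds stretch, so the stretch moves the
    hydrogens away from the partner monomer and the hydrogen bond itself is
    untouched.
    """
    half = math.radians(_A_HOH / 2.0)
    o = np.array([0.0, 0.0, 0.0])
    h1 = o + r_oh * np.array([-math.cos(half), 0.0, math.sin(half)])
    h2 = o + r_oh * np.array([-math.cos(half), 0.0, -math.sin(half)])
    return Molecule(
        ("O", "H", "H"),
        np.array([o, h1, h2]) * ANGSTROM_TO_BOHR,
        label=f"water (stretched r_OH={r_oh:g} A)",
    )


def _water_donor_eq() -> Molecule:
    """Equilibrium water donating a collinear O-H...O hydrogen bond along -x
    toward the origin; its geometry never depends on the stretch."""
    ang = math.radians(_A_HOH)
    o = np.array([_R_OO, 0.0, 0.0])
    h1 = o + _R_OH_EQ * np.array([-1.0, 0.0, 0.0])  # points at the partner O
    h2 = o + _R_OH_EQ * np.array([-math.cos(ang), math.sin(ang), 0.0])
    return Molecule(
        ("O", "H", "H"),
        np.array([o, h1, h2]) * ANGSTROM_TO_BOHR,
        label="water donor (equilibrium)",
    )


def make_water_dimer(r_oh_stretch: float = _R_OH_EQ,
                     basis: str = "6-31g") -> DimerSystem:
    """Hydrogen-bonded water dimer in which one monomer's two O-H bonds are
    symmetrically set to ``r_oh_stretch`` (angstrom) with everything else —
    including the intermonomer O...O separation — held fixed.

    Monomer A is the stretched water (the hydrogen-bond acceptor, so its
    hydrogens move away from the partner as they stretch); monomer B is the
    equilibrium donor.
    """
    if not (0.5 <= r_oh_stretch <= 3.0):
        raise ValueError("r_oh_stretch must lie in [0.5, 3.0] angstrom")
    return DimerSystem(_water_stretched(r_oh_stretch), _water_donor_eq(),
                       basis, basis)


_R_CC = 1.397  # angstrom, benzene C-C
_R_CH = 1.084  # angstrom, benzene C-H


def _ring(center, normal_axis: str, remove_para_h: bool, label: str,
          ring_axis_offset_deg: float = 0.0) -> Molecule:
    """Regular hexagonal C6 ring with radial H's; optionally drop the two H
    on the ring x axis (for p-benzyne)."""
    elements, coords = [], []
    for k in range(6):
        th = math.radians(60.0 * k + ring_axis_offset_deg)
        u = np.array([math.cos(th), math.sin(th), 0.0])
        if normal_axis == "y":  # ring in the xz plane
            u = np.array([math.cos(th), 0.0, math.sin(th)])
        c = np.asarray(center) + _R_CC * u
        elements.append("C")
        coords.append(c)
        on_para_axis = k in (0, 3)
        if remove_para_h and on_para_axis:
            continue
        elements.append("H")
        coords.append(np.asarray(center) + (_R_CC + _R_CH) * u)
    return Molecule(tuple(elements), np.array(coords) * ANGSTROM_TO_BOHR, label=label)


def make_benzene_pbenzyne_tshape(r_centers: float = 4.45,
                                 basis: str = "6-31g") -> DimerSystem:
    """T-shaped benzene / p-benzyne dimer with centroid separation ``r_centers``
    (angstrom).

    Benzene (monomer B) lies in the xy plane centered at the origin;
    p-benzyne (monomer A) lies in the xz plane centered at (0, 0, R), so the
    ring planes are perpendicular. The p-benzyne radical carbons sit on its
    ring x axis, leaving an intact C-H pointing at the benzene face.
    p-Benzyne is treated as a low-spin (singlet) biradical.
    """
    if r_centers < 3.0:
        raise ValueError("center-to-center distance must be >= 3.0 angstrom")
    benzene = _ring((0.0, 0.0, 0.0), "z", False, "benzene")
    pbenzyne = _ring((0.0, 0.0, r_centers), "y", True, "p-benzyne",
                     ring_axis_offset_deg=0.0)
    return DimerSystem(pbenzyne, benzene, basis, basis)


_R_HH = 0.7414  # angstrom, H2 bond


def make_toy_dimer(kind: str, r: float, basis: str = "sto-3g") -> DimerSystem:
    """Tiny test dimers: two collinear H2 (center-to-center separation ``r``,
    angstrom) or two He atoms at distance ``r``."""
    if r <= 0.5:
        raise ValueError("separation must exceed 0.5 angstrom")
    if kind == "h2h2":
        a = Molecule(("H", "H"),
                     np.array([[-_R_HH / 2, 0, 0], [_R_HH / 2, 0, 0]])
                     * ANGSTROM_TO_BOHR, label="H2")
        b = Molecule(("H", "H"),
                     np.array([[r - _R_HH / 2, 0, 0], [r + _R_HH / 2, 0, 0]])
                     * ANGSTROM_TO_BOHR, label="H2'")
    elif kind == "hehe":
        a = Molecule(("He",), np.zeros((1, 3)), label="He")
        b = Molecule(("He",), np.array([[r, 0.0, 0.0]]) * ANGSTROM_TO_BOHR,
                     label="He'")
    else:
        raise ValueError(f"unknown toy dimer kind: {kind!r}")
    return DimerSystem(a, b, basis, basis)
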