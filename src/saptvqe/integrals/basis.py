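"""Gaussian basis sets: data-file parsing, shell construction, normalization.

Basis data ship as plain-text files (``data/*.bas``) holding the standard
published exponents/coefficients. Shells are contracted Cartesian Gaussians;
d shells are transformed to the 5 real spherical components. Every AO is
unit-normalized at construction time.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ..molsys import Molecule

MAX_L = 2  # s, p, d are sufficient for the supported basis sets

# Cartesian component exponent triples per angular momentum, fixed order
CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, l: int) -> float:
    """Norm of the axial Cartesian primitive x^l exp(-alpha r^2)."""
    return math.sqrt(
        (2.0 * alpha / math.pi) ** 1.5
        * (4.0 * alpha) ** l
        / _double_factorial(2 * l - 1)
    )


def _cart_metric(l: int) -> np.ndarray:
    """Overlap metric between same-center Cartesian monomial components,
    in the axial-normalized convention (diagonal = 1 for axial components)."""
    comps = CART_COMPONENTS[l]
    n = len(comps)
    m = np.zeros((n, n))
    norm_ax = _double_factorial(2 * l - 1)
    for i, (a, b, c) in enumerate(comps):
        for j, (d, e, f) in enumerate(comps):
            if (a + d) % 2 or (b + e) % 2 or (c + f) % 2:
                continue
            m[i, j] = (
                _double_factorial(a + d - 1)
                * _double_factorial(b + e - 1)
                * _double_factorial(c + f - 1)
                / norm_ax
            )
    return m


def _sph_transform_d() -> np.ndarray:
    """5x6 real-spherical transform for d shells (rows m = -2..2), rows
    normalized against the Cartesian metric."""
    raw = np.array(
        [
            # xx  xy  xz  yy  yz  zz
            [0, 1, 0, 0, 0, 0],     # m = -2 : xy
            [0, 0, 0, 0, 1, 0],     # m = -1 : yz
            [-1, 0, 0, -1, 0, 2],   # m =  0 : 3z^2 - r^2
            [0, 0, 1, 0, 0, 0],     # m = +1 : xz
            [1, 0, 0, -1, 0, 0],    # m = +2 : x^2 - y^2
        ],
        dtype=float,
    )
    metric = _cart_metric(2)
    for r in range(5):
        raw[r] /= math.sqrt(raw[r] @ metric @ raw[r])
    return raw


SPH_D = _sph_transform_d()


def shell_transform(l: int) -> np.ndarray:
    """(n_func x n_cart) Cartesian->AO transform for one shell."""
    if l < 2:
        return np.eye(len(CART_COMPONENTS[l]))
    return SPH_D


@dataclass(frozen=True)
class Shell:
    """One contracted shell on one center. Coefficients include the axial
    primitive norms."""

    l: int
    center: np.ndarray          # (3,), bohr
    exponents: np.ndarray       # (nprim,)
    coefficients: np.ndarray    # (nprim,), axial-normalized primitives
    atom_index: int

    @property
    def n_cart(self) -> int:
        return len(CART_COMPONENTS[self.l])

    @property
    def n_func(self) -> int:
        return 5 if self.l == 2 else self.n_cart


_ANGULAR = {"S": 0, "P": 1, "D": 2}


def _parse_basis_file(name: str) -> dict[str, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Parse a .bas file into {element: [(l, exps, coefs), ...]}."""
    fname = name.lower() + ".bas"
    try:
        text = (resources.files(__package__) / "data" / fname).read_text()
    except FileNotFoundError:
        raise ValueError(f"unknown basis set: {name!r}") from None
    blocks: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    element = None
    shell_kind = None
    rows: list[list[float]] = []

    def flush():
        nonlocal rows, shell_kind
        if shell_kind is None or not rows:
            rows, shell_kind = [], None
            return
        arr = np.array(rows)
        if shell_kind == "SP":
            blocks[element].append((0, arr[:, 0].copy(), arr[:, 1].copy()))
            blocks[element].append((1, arr[:, 0].copy(), arr[:, 2].copy()))
        else:
            blocks[element].append((_ANGULAR[shell_kind], arr[:, 0].copy(),
                                    arr[:, 1].copy()))
        rows, shell_kind = [], None

    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        if line.startswith("element"):
            flush()
            element = line.split()[1].capitalize()
            blocks[element] = []
        elif line[0].isalpha():
            flush()
            shell_kind = line.upper()
            if shell_kind not in ("S", "P", "D", "SP"):
                raise ValueError(f"unsupported shell type {shell_kind!r} in {fname}")
        else:
            rows.append([float(tok) for tok in line.split()])
    flush()
    return blocks


class BasisSet:
    """All shells for a molecule, with AO bookkeeping and normalization."""

    def __init__(self, mol: Molecule, name: str):
        data = _parse_basis_file(name.lower())
        shells: list[Shell] = []
        for ia, (el, xyz) in enumerate(zip(mol.elements, mol.coords)):
            if el not in data:
                raise ValueError(f"basis {name!r} has no data for element {el!r}")
            for l, exps, coefs in data[el]:
                if l > MAX_L:
                    raise ValueError("angular momenta beyond d are not supported")
                norms = np.array([primitive_norm(a, l) for a in exps])
                shells.append(Shell(l, np.asarray(xyz, float), exps.copy(),
                                    coefs * norms, ia))
        self._init_from_shells(shells, name.lower())

    @classmethod
    def merge(cls, b1: "BasisSet", b2: "BasisSet",
              atom_offset: int | None = None) -> "BasisSet":
        """Union basis over two (disjoint) molecules, b1's shells first."""
        if atom_offset is None:
            atom_offset = 1 + max(sh.atom_index for sh in b1.shells)
        shells = list(b1.shells) + [
            Shell(sh.l, sh.center, sh.exponents, sh.coefficients,
                  sh.atom_index + atom_offset)
            for sh in b2.shells
        ]
        obj = cls.__new__(cls)
        obj._init_from_shells(shells, f"{b1.name}+{b2.name}")
        return obj

    def _init_from_shells(self, shells: list[Shell], name: str):
        self.name = name
        self.shells = shells
        self.ao_offsets = np.zeros(len(shells) + 1, dtype=int)
        self.cart_offsets = np.zeros(len(shells) + 1, dtype=int)
        for i, sh in enumerate(shells):
            self.ao_offsets[i + 1] = self.ao_offsets[i] + sh.n_func
            self.cart_offsets[i + 1] = self.cart_offsets[i] + sh.n_cart
        self.n_ao = int(self.ao_offsets[-1])
        self.n_cart = int(self.cart_offsets[-1])
        # per-AO normalization scales, fixed after one self-overlap build
        self._scales = np.ones(self.n_ao)
        from ._engine import overlap_cart
        s_cart = overlap_cart(self, self)
        s = self.cart_to_sph(self.cart_to_sph(s_cart, axis=0), axis=1)
        self._scales = 1.0 / np.sqrt(np.diag(s))

    @property
    def scales(self) -> np.ndarray:
        return self._scales

    def cart_to_sph(self, array: np.ndarray, axis: int) -> np.ndarray:
        """Apply the per-shell Cartesian->spherical transform along ``axis``
        (no normalization scaling)."""
        arr = np.moveaxis(array, axis, 0)
        out = np.empty((self.n_ao,) + arr.shape[1:], dtype=arr.dtype)
        for i, sh in enumerate(self.shells):
            c0, c1 = self.cart_offsets[i], self.cart_offsets[i + 1]
            a0, a1 = self.ao_offsets[i], self.ao_offsets[i + 1]
            t = shell_transform(sh.l)
            out[a0:a1] = np.tensordot(t, arr[c0:c1], axes=(1, 0))
        return np.moveaxis(out, 0, axis)

    def finalize(self, cart_array: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
        """Cartesian->spherical transform plus normalization along ``axes``."""
        out = cart_array
        for ax in axes:
            out = self.cart_to_sph(out, ax)
        for ax in axes:
            shape = [1] * out.ndim
            shape[ax] = self.n_ao
            out = out * self._scales.reshape(shape)
        return out
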