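"""Atom records, molecular frames and element-symbol normalization.

A :class:`MolecularFrame` is one conformation: an ordered list of atoms with
Cartesian coordinates in Å. Trajectories are plain sequences of frames. No
bond perception is ever performed — atoms are points with element identities,
nothing more.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FileFormat",
    "RawAtomRecord",
    "MolecularFrame",
    "UnknownElementError",
    "normalize_element",
]

#: All IUPAC element symbols (Z = 1..118).
ELEMENT_SYMBOLS: frozenset[str] = frozenset(
    """
    H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni
    Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I
    Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt
    Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr
    Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og
    """.split()
)

_STRIP_RE = re.compile(r"[^A-Za-z]+")


class UnknownElementError(ValueError):
    """Raised when an atom label cannot be resolved to an element symbol."""


class FileFormat(enum.Enum):
    MOL2 = "mol2"
    PDB = "pdb"
    SDF = "sdf"
    XYZ = "xyz"


def normalize_element(label: str) -> str:
    """Resolve an atom label to a canonical element symbol.

    Digits and punctuation are stripped, then a two-letter symbol is tried
    before a one-letter symbol (``"CL1"`` → ``"Cl"``, ``"HB2"`` → ``"H"``).
    Unknown labels raise :class:`UnknownElementError` rather than being
    skipped: a missing element would silently corrupt every descriptor
    downstream via its missing radius.
    """
    stripped = _STRIP_RE.sub("", label)
    if not stripped:
        raise UnknownElementError(f"atom label {label!r} contains no element symbol")
    two = stripped[:2].capitalize()
    if len(stripped) >= 2 and two in ELEMENT_SYMBOLS:
        return two
    one = stripped[0].upper()
    if one in ELEMENT_SYMBOLS:
        return one
    raise UnknownElementError(f"cannot resolve element from atom label {label!r}")


@dataclass(frozen=True)
class RawAtomRecord:
    """One atom as read from a structure file: label, element, position (Å)."""

    label: str
    element: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.element not in ELEMENT_SYMBOLS:
            raise UnknownElementError(f"unrecognized element {self.element!r}")
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError(f"non-finite coordinate in atom {self.label!r}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class MolecularFrame:
    """One conformation: ordered atoms plus provenance metadata."""

    atoms: list[RawAtomRecord]
    frame_index: int = 0
    source_format: FileFormat | None = None
    source_name: str = ""
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a MolecularFrame must contain at least one atom")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterable[RawAtomRecord]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Atom positions as an (n, 3) float array, file order preserved."""
        if self._coords is None:
            self._coords = np.array(
                [[a.x, a.y, a.z] for a in self.atoms], dtype=float
            )
        return self._coords

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def translated(self, shift: Sequence[float]) -> "MolecularFrame":
        """Return a copy rigidly translated by ``shift`` (Å)."""
        dx, dy, dz = (float(s) for s in shift)
        atoms = [
            RawAtomRecord(a.label, a.element, a.x + dx, a.y + dy, a.z + dz)
            for a in self.atoms
        ]
        return MolecularFrame(atoms, self.frame_index, self.source_format, self.source_name)

    @classmethod
    def from_arrays(
        cls,
        elements: Sequence[str],
        coords: np.ndarray,
        frame_index: int = 0,
        source_format: FileFormat | None = None,
    ) -> "MolecularFrame":
        coords = np.asarray(coords, dtype=float)
        atoms = [
            RawAtomRecord(el, normalize_element(el), *xyz)
            for el, xyz in zip(elements, coords, strict=True)
        ]
        return cls(atoms, frame_index, source_format)
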