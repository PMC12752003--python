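"""Van der Waals radius tables and polar-atom classification.

Radii follow the Bondi consensus set (with the common extensions for
elements Bondi did not tabulate). The molecular surface they define stands
in for an electron iso-density surface; three calibrations are exposed,
named after the iso-density thresholds they emulate:

* ``iso_0001`` — 0.001 a.u., the gas-phase convention; the Bondi radii as-is.
* ``iso_0016`` — 0.0016 a.u. (thermodynamically effective surfaces).
* ``iso_0002`` — 0.002 a.u., the condensed-phase convention.

Higher thresholds sit deeper in the electron density, so the alternative
calibrations shrink every radius by a uniform declared factor (0.97 and
0.95 respectively); any published per-element set can be swapped in from a
plain-text file instead.

Solvent-accessible surfaces are obtained by adding a probe radius
(typically 1.4 Å for water) uniformly to every atomic radius.

Polar-surface-area classification marks N and O (optionally S) and the
hydrogens bonded to them. Because no bond perception is done anywhere in
the pipeline, an N/O-bound hydrogen is recognized geometrically: its
nearest N or O lies within ``polar_h_cutoff`` (default 1.2 Å, comfortably
above N–H/O–H bond lengths of ~0.96–1.02 Å and below nonbonded contacts).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import IO, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .frames import MolecularFrame, normalize_element

__all__ = [
    "ThresholdMode",
    "RadiiTable",
    "PolarityOptions",
    "MissingRadiusError",
    "BONDI_RADII",
    "THRESHOLD_SCALE",
    "default_radii",
    "load_radius_table",
    "get_radius",
    "mark_polar_atoms",
]


class ThresholdMode(enum.Enum):
    """Iso-density-threshold calibration selecting a radius table."""

    iso_0001 = "0.001"
    iso_0016 = "0.0016"
    iso_0002 = "0.002"


#: Bondi-style consensus vdW radii, Å.
BONDI_RADII: Mapping[str, float] = {
    "H": 1.20, "He": 1.40,
    "Li": 1.82, "Be": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Ga": 1.87, "Ge": 2.11, "As": 1.85, "Se": 1.90,
    "Br": 1.85, "Kr": 2.02,
    "Rb": 3.03, "Sr": 2.49, "In": 1.93, "Sn": 2.17, "Sb": 2.06, "Te": 2.06,
    "I": 1.98, "Xe": 2.16,
    "Cs": 3.43, "Ba": 2.68, "Tl": 1.96, "Pb": 2.02, "Bi": 2.07,
    "Zn": 1.39, "Cu": 1.40, "Ni": 1.63, "Pd": 1.63, "Pt": 1.75,
    "Ag": 1.72, "Au": 1.66, "Cd": 1.58, "Hg": 1.55, "Fe": 2.00, "Mn": 2.00,
    "Co": 2.00, "Cr": 2.00, "V": 2.00, "Ti": 2.00, "Sc": 2.10,
    "Mo": 2.00, "W": 2.00, "U": 1.86,
}

#: Uniform shrink factors applied to the 0.001 a.u. table (declared defaults).
THRESHOLD_SCALE: Mapping[ThresholdMode, float] = {
    ThresholdMode.iso_0001: 1.00,
    ThresholdMode.iso_0016: 0.97,
    ThresholdMode.iso_0002: 0.95,
}

_RADIUS_RANGE = (0.2, 5.0)


class MissingRadiusError(KeyError):
    """An element present in the structure has no radius entry."""

    def __str__(self) -> str:  # KeyError quotes its payload by default
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class RadiiTable:
    """Per-element vdW radii plus an optional solvent-probe augmentation."""

    entries: Mapping[str, float]
    mode: ThresholdMode = ThresholdMode.iso_0001
    probe_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        for el, r in self.entries.items():
            if not (_RADIUS_RANGE[0] < r < _RADIUS_RANGE[1]):
                raise ValueError(
                    f"radius {r} Å for {el} outside plausible range {_RADIUS_RANGE}"
                )

    def radius(self, element: str) -> float:
        """Augmented radius (vdW + probe) for ``element``, Å."""
        try:
            return self.entries[element] + self.probe_radius
        except KeyError:
            raise MissingRadiusError(
                f"no van der Waals radius for element {element!r} in mode "
                f"{self.mode.name}; supply one via a custom radius table"
            ) from None

    def radii_for(self, frame: MolecularFrame) -> np.ndarray:
        """Augmented radii for every atom of ``frame``, in atom order."""
        return np.array([self.radius(el) for el in frame.elements], dtype=float)

    def max_radius(self) -> float:
        return max(self.entries.values()) + self.probe_radius

    def with_probe(self, probe_radius: float) -> "RadiiTable":
        return replace(self, probe_radius=float(probe_radius))


def default_radii(
    mode: ThresholdMode = ThresholdMode.iso_0001, probe_radius: float = 0.0
) -> RadiiTable:
    """Built-in table for an iso-density calibration, optionally probed."""
    scale = THRESHOLD_SCALE[mode]
    entries = {el: r * scale for el, r in BONDI_RADII.items()}
    return RadiiTable(entries=entries, mode=mode, probe_radius=probe_radius)


def load_radius_table(
    stream: str | IO[str],
    mode: ThresholdMode = ThresholdMode.iso_0001,
    probe_radius: float = 0.0,
) -> RadiiTable:
    """Load a radius table from ``ELEMENT radius_Å`` lines (# comments)."""
    text = stream if isinstance(stream, str) else stream.read()
    entries: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"radius table line {lineno}: expected 'ELEMENT radius'")
        el = normalize_element(parts[0])
        entries[el] = float(parts[1])
    if not entries:
        raise ValueError("radius table contains no entries")
    return RadiiTable(entries=entries, mode=mode, probe_radius=probe_radius)


def get_radius(element: str, table: RadiiTable) -> float:
    """Augmented radius of ``element`` under ``table`` (vdW + probe), Å."""
    return table.radius(element)


#: Extra H-donor reach for sulfur: S–H bonds (~1.34 Å) are longer than the
#: N–H/O–H bonds (~0.96–1.02 Å) the base cutoff is sized for.
SULFUR_H_EXTRA: float = 0.25


@dataclass(frozen=True)
class PolarityOptions:
    """Which atoms count toward polar surface area."""

    include_sulfur: bool = False
    polar_h_cutoff: float = 1.2  # Å, max H—(N/O) distance for a polar H

    def __post_init__(self) -> None:
        if not (0.5 < self.polar_h_cutoff < 2.0):
            raise ValueError("polar_h_cutoff must lie in (0.5, 2.0) Å")


def mark_polar_atoms(
    frame: MolecularFrame, options: PolarityOptions | None = None
) -> np.ndarray:
    """Boolean polar flag per atom, in atom order.

    N and O atoms are polar; a hydrogen is polar iff its nearest N or O
    lies within ``polar_h_cutoff``. With ``include_sulfur``, S atoms are
    polar too and sulfur reaches hydrogens out to ``polar_h_cutoff +
    SULFUR_H_EXTRA`` to cover the longer S–H bond. Flags depend only on
    interatomic distances, so they are invariant under rigid motions of
    the frame.
    """
    if options is None:
        options = PolarityOptions()
    elements = np.array(frame.elements)
    flags = np.isin(elements, ["N", "O"])
    if options.include_sulfur:
        flags |= elements == "S"
    h_idx = np.flatnonzero(elements == "H")
    if h_idx.size:
        no_idx = np.flatnonzero(np.isin(elements, ["N", "O"]))
        donor_groups = [(no_idx, options.polar_h_cutoff)]
        if options.include_sulfur:
            s_idx = np.flatnonzero(elements == "S")
            donor_groups.append((s_idx, options.polar_h_cutoff + SULFUR_H_EXTRA))
        for donors, cutoff in donor_groups:
            if donors.size:
                tree = cKDTree(frame.coords[donors])
                dist, _ = tree.query(frame.coords[h_idx], k=1)
                flags[h_idx[dist <= cutoff]] = True
    return flags
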