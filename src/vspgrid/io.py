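"""Structure-file readers (MOL2 / PDB / SDF / XYZ) and the surface-point writer.

The readers extract only what the descriptors need — element symbols and
Cartesian coordinates — frame by frame, in file order. They deliberately do
no bond perception, no sanitization and no molecule splitting. Formats:

* MOL2: atoms between ``@<TRIPOS>ATOM`` and the next section marker; element
  from the SYBYL atom type (``"N.3"`` → ``N``), falling back to the atom name.
* PDB: fixed columns of ``ATOM``/``HETATM`` records; ``MODEL``/``ENDMDL``
  delimit frames. (The non-standard keyword ``HETAMM`` seen in some
  descriptions is read as the standard ``HETATM``.)
* SDF/MOL (V2000): atom count from the counts line; ``$$$$`` delimits records.
* XYZ: the universal count / comment / atom-lines layout, repeated per frame.
"""

from __future__ import annotations

import io as _stdio
import os
from typing import IO, Iterable, Sequence

import numpy as np

from .frames import (
    FileFormat,
    MolecularFrame,
    RawAtomRecord,
    normalize_element,
)

__all__ = [
    "ParseError",
    "UnsupportedFormatError",
    "TruncatedFileError",
    "detect_format",
    "parse_mol2",
    "parse_pdb",
    "parse_sdf",
    "parse_xyz",
    "parse_file",
    "write_surface_xyz",
    "SURFACE_POINT_SYMBOL",
]

#: Placeholder element written for exported surface grid points. Helium is
#: chemically inert and keeps the file a valid, re-parseable XYZ.
SURFACE_POINT_SYMBOL = "He"


class ParseError(ValueError):
    """Malformed structure file."""


class TruncatedFileError(ParseError):
    """A block declares more atoms than the file contains."""


class UnsupportedFormatError(ValueError):
    """File extension outside the supported set."""


_EXTENSIONS = {
    ".mol2": FileFormat.MOL2,
    ".pdb": FileFormat.PDB,
    ".ent": FileFormat.PDB,
    ".sdf": FileFormat.SDF,
    ".mol": FileFormat.SDF,
    ".xyz": FileFormat.XYZ,
}


def detect_format(path_or_name: str | os.PathLike) -> FileFormat:
    """Identify the file format from the extension, case-insensitively."""
    ext = os.path.splitext(os.fspath(path_or_name))[1].lower()
    try:
        return _EXTENSIONS[ext]
    except KeyError:
        raise UnsupportedFormatError(
            f"unsupported structure-file extension {ext!r} "
            f"(expected one of {sorted({e for e in _EXTENSIONS})})"
        ) from None


def _as_lines(stream: str | IO[str]) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream.read().splitlines()


def _float(token: str, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: non-numeric {what} {token!r}") from None


# ---------------------------------------------------------------------------
# MOL2


def parse_mol2(stream: str | IO[str]) -> list[MolecularFrame]:
    lines = _as_lines(stream)
    frames: list[MolecularFrame] = []
    atoms: list[RawAtomRecord] = []
    in_atoms = False
    seen_atom_block = False

    def flush() -> None:
        nonlocal atoms
        if atoms:
            frames.append(
                MolecularFrame(atoms, len(frames), FileFormat.MOL2)
            )
            atoms = []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.upper().startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            if section == "ATOM":
                in_atoms = True
                seen_atom_block = True
            else:
                in_atoms = False
                if section == "MOLECULE":
                    flush()
            continue
        if not in_atoms or not line:
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ParseError(f"line {lineno}: MOL2 atom line has too few columns")
        name = parts[1]
        x = _float(parts[2], lineno, "x coordinate")
        y = _float(parts[3], lineno, "y coordinate")
        z = _float(parts[4], lineno, "z coordinate")
        if len(parts) >= 6:
            # SYBYL type like "C.ar" or "N.3"; the element precedes the dot.
            element = normalize_element(parts[5].split(".")[0])
        else:
            element = normalize_element(name)
        atoms.append(RawAtomRecord(name, element, x, y, z))

    flush()
    if not seen_atom_block:
        raise ParseError("no @<TRIPOS>ATOM block found")
    if not frames:
        raise ParseError("@<TRIPOS>ATOM block contains no atoms")
    return frames


# ---------------------------------------------------------------------------
# PDB


def _pdb_element(line: str, lineno: int) -> str:
    field = line[76:78].strip() if len(line) >= 77 else ""
    if field:
        return normalize_element(field)
    # Fallback: the element part of the atom name occupies columns 13-14,
    # right-justified ("  CA" = C-alpha carbon, "CA  " = calcium).
    name_el = line[12:14].strip()
    if not name_el:
        raise ParseError(f"line {lineno}: cannot determine element")
    return normalize_element(name_el)


def parse_pdb(stream: str | IO[str]) -> list[MolecularFrame]:
    lines = _as_lines(stream)
    frames: list[MolecularFrame] = []
    atoms: list[RawAtomRecord] = []
    saw_model = False

    def flush() -> None:
        nonlocal atoms
        if atoms:
            frames.append(MolecularFrame(atoms, len(frames), FileFormat.PDB))
            atoms = []

    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip().upper()
        if rec == "MODEL":
            saw_model = True
            flush()
        elif rec == "ENDMDL":
            flush()
        elif rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"line {lineno}: truncated coordinate record")
            x = _float(line[30:38].strip(), lineno, "x coordinate")
            y = _float(line[38:46].strip(), lineno, "y coordinate")
            z = _float(line[46:54].strip(), lineno, "z coordinate")
            name = line[12:16].strip()
            atoms.append(RawAtomRecord(name, _pdb_element(line, lineno), x, y, z))
    flush()
    if not frames:
        raise ParseError("no parseable ATOM/HETATM records found")
    if saw_model and len(frames) > 1:
        for i, f in enumerate(frames):
            f.frame_index = i
    return frames


# ---------------------------------------------------------------------------
# SDF / MOL (V2000)


def _counts_line_natoms(line: str) -> int | None:
    """Return the atom count if ``line`` looks like a V2000 counts line."""
    parts = line.split()
    if len(parts) < 2:
        return None
    try:
        natoms = int(parts[0])
        int(parts[1])
    except ValueError:
        # strict fixed-width fallback: aaabbb...
        try:
            natoms = int(line[0:3])
            int(line[3:6])
        except (ValueError, IndexError):
            return None
    return natoms if natoms >= 0 else None


def _parse_sdf_record(lines: list[str], index: int) -> MolecularFrame | None:
    if not any(s.strip() for s in lines):
        return None
    # V2000 puts the counts line on physical line 4 (after three header
    # lines); be lenient and also accept it one line earlier.
    natoms = None
    counts_at = None
    for cand in (3, 2):
        if cand < len(lines):
            natoms = _counts_line_natoms(lines[cand])
            if natoms is not None:
                counts_at = cand
                break
    if natoms is None or counts_at is None:
        raise ParseError(f"record {index + 1}: malformed or missing V2000 counts line")
    atom_lines = lines[counts_at + 1 : counts_at + 1 + natoms]
    if len(atom_lines) < natoms:
        raise TruncatedFileError(
            f"record {index + 1}: counts line declares {natoms} atoms but only "
            f"{len(atom_lines)} atom lines are present"
        )
    atoms: list[RawAtomRecord] = []
    for off, line in enumerate(atom_lines):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"record {index + 1}: malformed atom line {off + 1}")
        x = _float(parts[0], off + 1, "x coordinate")
        y = _float(parts[1], off + 1, "y coordinate")
        z = _float(parts[2], off + 1, "z coordinate")
        atoms.append(RawAtomRecord(parts[3], normalize_element(parts[3]), x, y, z))
    if not atoms:
        return None
    return MolecularFrame(atoms, index, FileFormat.SDF)


def parse_sdf(stream: str | IO[str]) -> list[MolecularFrame]:
    lines = _as_lines(stream)
    records: list[list[str]] = [[]]
    for line in lines:
        if line.strip() == "$$$$":
            records.append([])
        else:
            records[-1].append(line)
    frames = []
    for rec in records:
        frame = _parse_sdf_record(rec, len(frames))
        if frame is not None:
            frames.append(frame)
    if not frames:
        raise ParseError("no parseable V2000 records found")
    return frames


# ---------------------------------------------------------------------------
# XYZ


def parse_xyz(stream: str | IO[str]) -> list[MolecularFrame]:
    lines = _as_lines(stream)
    frames: list[MolecularFrame] = []
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        count_token = lines[i].strip()
        try:
            natoms = int(count_token)
        except ValueError:
            raise ParseError(
                f"line {i + 1}: expected an atom count, got {count_token!r}"
            ) from None
        if natoms < 0:
            raise ParseError(f"line {i + 1}: negative atom count")
        if i + 1 >= n and natoms > 0:
            raise TruncatedFileError(f"line {i + 1}: missing comment line")
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise TruncatedFileError(
                f"block at line {i + 1} declares {natoms} atoms but only "
                f"{len(atom_lines)} atom lines follow"
            )
        atoms: list[RawAtomRecord] = []
        for off, line in enumerate(atom_lines):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + off}: malformed XYZ atom line")
            el = normalize_element(parts[0])
            x = _float(parts[1], i + 3 + off, "x coordinate")
            y = _float(parts[2], i + 3 + off, "y coordinate")
            z = _float(parts[3], i + 3 + off, "z coordinate")
            atoms.append(RawAtomRecord(parts[0], el, x, y, z))
        if atoms:
            frames.append(MolecularFrame(atoms, len(frames), FileFormat.XYZ))
        i += 2 + natoms
    if not frames:
        raise ParseError("no XYZ blocks with atoms found")
    return frames


# ---------------------------------------------------------------------------

_PARSERS = {
    FileFormat.MOL2: parse_mol2,
    FileFormat.PDB: parse_pdb,
    FileFormat.SDF: parse_sdf,
    FileFormat.XYZ: parse_xyz,
}


def parse_file(
    path: str | os.PathLike, fmt: FileFormat | None = None
) -> list[MolecularFrame]:
    """Parse a structure file, detecting the format from the extension."""
    if fmt is None:
        fmt = detect_format(path)
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        frames = _PARSERS[fmt](fh)
    for f in frames:
        f.source_name = os.fspath(path)
    return frames


def write_surface_xyz(
    points: Sequence[Sequence[float]] | np.ndarray,
    label: str = "surface grid points",
    symbol: str = SURFACE_POINT_SYMBOL,
) -> str:
    """Format surface grid points as a standard XYZ block.

    The output round-trips through :func:`parse_xyz`, preserving coordinates
    to the printed precision (6 decimal places). An empty point set produces
    a valid zero-count block.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.size and not np.all(np.isfinite(pts)):
        raise ValueError("surface points must have finite coordinates")
    out = _stdio.StringIO()
    out.write(f"{len(pts)}\n")
    out.write(f"{label}\n")
    for x, y, z in pts:
        out.write(f"{symbol} {x:.6f} {y:.6f} {z:.6f}\n")
    return out.getvalue()
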