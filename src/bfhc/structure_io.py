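"""Read and write molecular structures (plain XYZ and Gaussian-input Cartesian blocks).

Two on-disk dialects are supported:

* plain XYZ: atom count on line 1, a free-text comment on line 2, then one
  ``symbol x y z`` line per atom (coordinates in Angstrom);
* Gaussian input: optional ``%`` link0 lines, a route section (lines starting
  with ``#``), a blank line, a title block, a blank line, a charge/multiplicity
  line, then the Cartesian block terminated by a blank line or EOF.

:func:`read_structure` auto-detects the dialect: if the first non-blank token
of the file is an integer the file is treated as plain XYZ.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

import numpy as np

from .errors import StructureFormatError

__all__ = [
    "Molecule",
    "read_xyz",
    "read_gaussian_input",
    "read_structure",
    "write_xyz",
]

# Element symbols recognized by the parsers.  Parsing accepts any element;
# downstream graph construction restricts molecules to C/H.
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn".split()
)

PathLike = Union[str, Path]
Source = Union[PathLike, TextIO]


def _normalize_symbol(token: str) -> str:
    symbol = token.strip().capitalize()
    if symbol not in _ELEMENTS:
        raise StructureFormatError(f"unknown element symbol: {token!r}")
    return symbol


@dataclass
class Molecule:
    """An ordered list of atoms with Cartesian coordinates in Angstrom."""

    symbols: tuple
    coordinates: np.ndarray
    title: str = ""

    def __post_init__(self) -> None:
        self.symbols = tuple(_normalize_symbol(s) for s in self.symbols)
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise StructureFormatError(
                f"coordinates must be an (n, 3) array, got shape {coords.shape}"
            )
        if len(self.symbols) != coords.shape[0]:
            raise StructureFormatError(
                f"{len(self.symbols)} symbols but {coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise StructureFormatError("coordinates contain non-finite values")
        self.coordinates = coords

    @property
    def atom_count(self) -> int:
        return len(self.symbols)

    def element_counts(self) -> dict:
        """Counts per element symbol, e.g. ``{"C": 14, "H": 10}``."""
        counts: dict = {}
        for s in self.symbols:
            counts[s] = counts.get(s, 0) + 1
        return counts

    def formula(self) -> str:
        """Hill-order molecular formula (C first, H second, rest alphabetic)."""
        counts = self.element_counts()
        parts = []
        for sym in ["C", "H"] + sorted(set(counts) - {"C", "H"}):
            n = counts.get(sym, 0)
            if n:
                parts.append(f"{sym}{n if n > 1 else ''}")
        return "".join(parts)


def _as_lines(source: Source) -> list:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        raise TypeError(f"unsupported source type: {type(source)!r}")
    # normalize CRLF / lone CR line endings
    return text.replace("\r\n", "\n").replace("\r", "\n").split("\n")


def _parse_atom_line(line: str, lineno: int):
    tokens = line.split()
    if len(tokens) < 4:
        raise StructureFormatError(
            f"line {lineno}: expected 'symbol x y z', got {line.strip()!r}"
        )
    symbol = _normalize_symbol(tokens[0])
    try:
        xyz = [float(t) for t in tokens[1:4]]
    except ValueError as exc:
        raise StructureFormatError(
            f"line {lineno}: unparseable coordinate in {line.strip()!r}"
        ) from exc
    return symbol, xyz


def read_xyz(source: Source) -> Molecule:
    """Parse a plain XYZ file or stream into a :class:`Molecule`."""
    lines = _as_lines(source)
    idx = 0
    while idx < len(lines) and not lines[idx].strip():
        idx += 1
    if idx >= len(lines):
        raise StructureFormatError("empty XYZ input")
    count_line = lines[idx].strip()
    try:
        declared = int(count_line.split()[0])
    except (ValueError, IndexError) as exc:
        raise StructureFormatError(
            f"malformed atom-count line: {count_line!r}"
        ) from exc
    if declared < 1:
        raise StructureFormatError(f"declared atom count must be >= 1, got {declared}")
    title = lines[idx + 1] if idx + 1 < len(lines) else ""
    symbols, coords = [], []
    for lineno, line in enumerate(lines[idx + 2 :], start=idx + 3):
        if not line.strip():
            continue
        symbol, xyz = _parse_atom_line(line, lineno)
        symbols.append(symbol)
        coords.append(xyz)
    if len(symbols) != declared:
        raise StructureFormatError(
            f"declared {declared} atoms but parsed {len(symbols)} atom lines"
        )
    return Molecule(tuple(symbols), np.array(coords), title.strip())


def read_gaussian_input(source: Source) -> Molecule:
    """Extract the Cartesian block of a Gaussian input file as a :class:`Molecule`.

    Route/link0 lines and the charge/multiplicity line are discarded; the
    title block becomes the molecule title.
    """
    lines = _as_lines(source)
    idx = 0
    # skip blanks and link0 (%mem= etc.)
    while idx < len(lines) and (not lines[idx].strip() or lines[idx].lstrip().startswith("%")):
        idx += 1
    # route section: consecutive lines starting with '#'
    saw_route = False
    while idx < len(lines) and lines[idx].lstrip().startswith("#"):
        saw_route = True
        idx += 1
    if saw_route:
        while idx < len(lines) and not lines[idx].strip():
            idx += 1
        # title block
        title_lines = []
        while idx < len(lines) and lines[idx].strip():
            title_lines.append(lines[idx].strip())
            idx += 1
        title = " ".join(title_lines)
        while idx < len(lines) and not lines[idx].strip():
            idx += 1
    else:
        title = ""
    # charge/multiplicity line: exactly two integer tokens
    if idx < len(lines):
        tokens = lines[idx].split()
        if len(tokens) == 2:
            try:
                int(tokens[0]), int(tokens[1])
                idx += 1
            except ValueError:
                pass
    symbols, coords = [], []
    for lineno, line in enumerate(lines[idx:], start=idx + 1):
        if not line.strip():
            break
        symbol, xyz = _parse_atom_line(line, lineno)
        symbols.append(symbol)
        coords.append(xyz)
    if not symbols:
        raise StructureFormatError("no Cartesian block found in Gaussian input")
    return Molecule(tuple(symbols), np.array(coords), title)


def read_structure(source: Source) -> Molecule:
    """Auto-detect the dialect and parse.

    Plain XYZ if the first non-blank token is an integer, Gaussian input
    otherwise.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    stripped = text.strip()
    if not stripped:
        raise StructureFormatError("no Cartesian block found: empty input")
    first_token = stripped.split()[0]
    try:
        int(first_token)
        is_xyz = True
    except ValueError:
        is_xyz = False
    buffer = io.StringIO(text)
    return read_xyz(buffer) if is_xyz else read_gaussian_input(buffer)


def write_xyz(molecule: Molecule, destination: Source) -> None:
    """Write a molecule in plain XYZ format (8 decimal places)."""
    if molecule.atom_count == 0:
        raise StructureFormatError("refusing to write an empty molecule")
    lines = [str(molecule.atom_count), molecule.title or molecule.formula()]
    for symbol, (x, y, z) in zip(molecule.symbols, molecule.coordinates):
        lines.append(f"{symbol:<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    elif hasattr(destination, "write"):
        destination.write(text)
    else:
        raise TypeError(f"unsupported destination type: {type(destination)!r}")
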