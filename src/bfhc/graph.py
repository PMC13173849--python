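"""Distance-based bond perception and degree-based atom typing for C/H molecules.

Bonds are perceived from the pairwise distance matrix: atoms *i* and *j* are
bonded iff ``0 < d(i, j) <= r(i) + r(j) + tolerance`` where *r* are covalent
radii.  H-H bonds are never formed regardless of distance, which protects
crowded in-pocket hydrogens of nonplanar helicenes from being mis-bonded.

Atom types follow carbon degree: 2 -> sp, 3 -> sp2 (sp2-H when a hydrogen is
attached), 4 -> sp3.  Hydrogens must have degree exactly 1 with a carbon
neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import BondPerceptionError
from .structure_io import Molecule

__all__ = [
    "DEFAULT_RADII",
    "DEFAULT_BOND_TOLERANCE",
    "TypedGraph",
    "compute_distance_matrix",
    "perceive_bonds",
    "assign_atom_types",
    "build_typed_graph",
]

#: Default single-bond covalent radii in Angstrom.  Accepts aromatic C-C
#: (~1.40 A) and C-H (~1.09 A) with wide margin while rejecting non-bonded
#: contacts (> 2.4 A).
DEFAULT_RADII: Mapping[str, float] = {"C": 0.76, "H": 0.31}

#: Default bond tolerance in Angstrom added on top of the radii sum.
DEFAULT_BOND_TOLERANCE: float = 0.40


def compute_distance_matrix(molecule: Molecule) -> np.ndarray:
    """Symmetric Euclidean distance matrix (Angstrom) with a zero diagonal."""
    if molecule.atom_count < 2:
        raise BondPerceptionError("need at least 2 atoms for a distance matrix")
    return squareform(pdist(molecule.coordinates))


@dataclass
class TypedGraph:
    """Molecular connectivity plus per-atom hybridization labels.

    Attributes
    ----------
    molecule : Molecule
        The parsed structure this graph was derived from.
    distance_matrix : ndarray
        Pairwise distances in Angstrom.
    adjacency : ndarray of bool
        Symmetric bond matrix with an all-false diagonal.
    degree : ndarray of int
        Row sums of the adjacency matrix.
    atom_type : list of str
        One of ``H``, ``sp``, ``sp2``, ``sp2-H``, ``sp3`` per atom
        (empty until :func:`assign_atom_types` runs).
    has_hydrogen : ndarray of bool
        Per-atom flag, true for carbons with at least one H neighbor.
    """

    molecule: Molecule
    distance_matrix: np.ndarray
    adjacency: np.ndarray
    degree: np.ndarray = field(init=False)
    atom_type: list = field(default_factory=list)
    has_hydrogen: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.degree = self.adjacency.sum(axis=1).astype(int)
        n = self.molecule.atom_count
        is_h = np.array([s == "H" for s in self.molecule.symbols])
        self.has_hydrogen = np.array(
            [bool(self.adjacency[i, is_h].any()) for i in range(n)]
        )

    @property
    def n_bonds(self) -> int:
        return int(self.degree.sum()) // 2

    def bonds(self):
        """Iterate bonds as sorted (i, j) index pairs."""
        idx = np.argwhere(np.triu(self.adjacency, k=1))
        return [tuple(pair) for pair in idx]

    def carbon_indices(self) -> list:
        return [i for i, s in enumerate(self.molecule.symbols) if s == "C"]

    def carbon_graph(self) -> nx.Graph:
        """The carbon skeleton as a networkx graph (atom indices as nodes)."""
        g = nx.Graph()
        carbons = set(self.carbon_indices())
        g.add_nodes_from(carbons)
        for i, j in self.bonds():
            if i in carbons and j in carbons:
                g.add_edge(int(i), int(j))
        return g


def perceive_bonds(
    molecule: Molecule,
    radii: Optional[Mapping[str, float]] = None,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
    allow_fragments: bool = False,
) -> TypedGraph:
    """Build the bonded adjacency matrix from covalent-radii thresholds.

    Raises
    ------
    BondPerceptionError
        For non-C/H elements, missing radii, hydrogens of degree != 1,
        carbons of degree outside {2, 3, 4}, or (unless *allow_fragments*)
        a disconnected carbon skeleton.
    """
    radii = dict(DEFAULT_RADII if radii is None else radii)
    bad = sorted(set(molecule.symbols) - {"C", "H"})
    if bad:
        raise BondPerceptionError(
            f"only C/H molecules are supported, found: {', '.join(bad)}"
        )
    for symbol in set(molecule.symbols):
        if symbol not in radii:
            raise BondPerceptionError(f"no covalent radius configured for {symbol}")

    dist = compute_distance_matrix(molecule)
    r = np.array([radii[s] for s in molecule.symbols])
    threshold = r[:, None] + r[None, :] + tolerance
    adjacency = (dist > 0) & (dist <= threshold)
    np.fill_diagonal(adjacency, False)

    # chemistry guard: never bond two hydrogens
    is_h = np.array([s == "H" for s in molecule.symbols])
    adjacency[np.ix_(is_h, is_h)] = False

    graph = TypedGraph(molecule, dist, adjacency)
    _validate_degrees(graph)
    if not allow_fragments:
        skeleton = graph.carbon_graph()
        if skeleton.number_of_nodes() and not nx.is_connected(skeleton):
            n_parts = nx.number_connected_components(skeleton)
            raise BondPerceptionError(
                f"carbon skeleton has {n_parts} disconnected fragments "
                "(pass allow_fragments=True to process anyway)"
            )
    return graph


def _validate_degrees(graph: TypedGraph) -> None:
    symbols = graph.molecule.symbols
    for i, (symbol, deg) in enumerate(zip(symbols, graph.degree)):
        if symbol == "H":
            if deg != 1:
                raise BondPerceptionError(
                    f"atom {i} (H) has degree {deg}, expected exactly 1"
                )
            neighbor = int(np.flatnonzero(graph.adjacency[i])[0])
            if symbols[neighbor] != "C":
                raise BondPerceptionError(
                    f"atom {i} (H) is bonded to {symbols[neighbor]}, expected C"
                )
        elif symbol == "C":
            if deg not in (2, 3, 4):
                raise BondPerceptionError(
                    f"atom {i} (C) has degree {deg}, expected 2, 3 or 4"
                )


def assign_atom_types(graph: TypedGraph) -> TypedGraph:
    """Populate ``atom_type`` from degrees (mutates and returns *graph*)."""
    types = []
    for i, symbol in enumerate(graph.molecule.symbols):
        deg = graph.degree[i]
        if symbol == "H":
            types.append("H")
        elif deg == 2:
            types.append("sp")
        elif deg == 3:
            types.append("sp2-H" if graph.has_hydrogen[i] else "sp2")
        elif deg == 4:
            types.append("sp3")
        else:  # pragma: no cover - caught by _validate_degrees
            raise BondPerceptionError(f"atom {i} (C) has invalid degree {deg}")
    graph.atom_type = types
    return graph


def build_typed_graph(
    molecule: Molecule,
    radii: Optional[Mapping[str, float]] = None,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
    allow_fragments: bool = False,
) -> TypedGraph:
    """Convenience: perceive bonds then assign atom types."""
    return assign_atom_types(
        perceive_bonds(molecule, radii=radii, tolerance=tolerance,
                       allow_fragments=allow_fragments)
    )
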