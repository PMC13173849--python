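"""Idealized benzenoid geometry generator for fixtures and property tests.

Hexagonal cells live on an axial lattice (coordinates ``(q, r)``); each cell
is a regular hexagon of side ``cc_bond`` centered at
``(sqrt(3) * (q + r/2), 1.5 * r) * cc_bond``.  Vertices shared by cells joined
by a fusion edge are merged into one carbon; hydrogens are added along the
external bisector to every carbon with fewer than three carbon neighbors.

Helicenes need the ``spiral`` z-policy: each cell *i* is lifted to
``z = i * rise`` (merged vertices average their cells' heights) so that
lattice-coincident but non-fused terminal rings do not collide.

Ground-truth connectivity comes from the lattice combinatorics, never from
distances, so fixtures can test bond perception instead of assuming it.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import BuilderError
from .structure_io import Molecule

__all__ = [
    "HexSpec",
    "BuiltMolecule",
    "build_benzenoid",
    "canonical",
    "canonical_names",
    "random_polyhex",
    "attach_methyl",
    "DEFAULT_SPIRAL_RISE",
]

#: Default helical rise per cell (Angstrom): large enough that hexahelicene's
#: overlapping terminal rings stay beyond the bonding threshold, small enough
#: that intra-ring bonds remain within it.
DEFAULT_SPIRAL_RISE = 0.8

#: Axial-lattice neighbor offsets, counterclockwise starting east.
AXIAL_NEIGHBORS: Tuple[Tuple[int, int], ...] = (
    (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1),
)

Cell = Tuple[int, int]


def _lattice_adjacent(a: Cell, b: Cell) -> bool:
    return (b[0] - a[0], b[1] - a[1]) in AXIAL_NEIGHBORS


@dataclass(frozen=True)
class HexSpec:
    """A polyhex: hexagon cells plus which lattice-adjacent pairs are fused.

    ``fusion_edges=None`` fuses every lattice-adjacent cell pair (the usual
    planar benzenoid).  ``z_policy`` is ``"planar"`` or ``"spiral"``;
    ``spiral_rise`` is the per-cell z increment under the spiral policy.
    """

    cells: Tuple[Cell, ...]
    fusion_edges: Optional[Tuple[FrozenSet[Cell], ...]] = None
    z_policy: str = "planar"
    spiral_rise: float = DEFAULT_SPIRAL_RISE
    name: str = ""

    def resolved_fusion_edges(self) -> Set[FrozenSet[Cell]]:
        cells = set(self.cells)
        if len(cells) != len(self.cells):
            raise BuilderError("duplicate cells in spec")
        all_adjacent = {
            frozenset((a, b))
            for i, a in enumerate(self.cells)
            for b in self.cells[i + 1 :]
            if _lattice_adjacent(a, b)
        }
        if self.fusion_edges is None:
            return all_adjacent
        edges = {frozenset(e) for e in self.fusion_edges}
        extra = edges - all_adjacent
        if extra:
            raise BuilderError(
                f"fusion edges between non-adjacent cells: {sorted(map(sorted, extra))}"
            )
        return edges


@dataclass
class BuiltMolecule:
    """A generated structure together with its intended connectivity."""

    molecule: Molecule
    adjacency: Set[FrozenSet[int]]
    spec: Optional[HexSpec] = None

    def adjacency_matrix(self) -> np.ndarray:
        n = self.molecule.atom_count
        mat = np.zeros((n, n), dtype=bool)
        for edge in self.adjacency:
            i, j = sorted(edge)
            mat[i, j] = mat[j, i] = True
        return mat


def _cell_center(cell: Cell, cc_bond: float) -> np.ndarray:
    q, r = cell
    return np.array([math.sqrt(3.0) * (q + r / 2.0), 1.5 * r]) * cc_bond


def _vertex_xy(cell: Cell, k: int, cc_bond: float) -> np.ndarray:
    theta = math.radians(30.0 + 60.0 * k)
    return _cell_center(cell, cc_bond) + cc_bond * np.array(
        [math.cos(theta), math.sin(theta)]
    )


def build_benzenoid(
    spec: HexSpec, cc_bond: float = 1.40, ch_bond: float = 1.09
) -> BuiltMolecule:
    """Realize a :class:`HexSpec` as carbon + hydrogen coordinates.

    Raises :class:`BuilderError` for a disconnected fusion graph or when the
    planar policy is requested for a self-overlapping spec (non-fused cells
    sharing vertex positions).
    """
    fusion = spec.resolved_fusion_edges()
    cells = list(spec.cells)
    if not cells:
        raise BuilderError("spec has no cells")

    # connectivity of the fusion graph
    reached = {cells[0]}
    frontier = [cells[0]]
    while frontier:
        cur = frontier.pop()
        for other in cells:
            if other not in reached and frozenset((cur, other)) in fusion:
                reached.add(other)
                frontier.append(other)
    if len(reached) != len(cells):
        raise BuilderError("fusion graph over cells is disconnected")

    if spec.z_policy == "spiral":
        cell_z = {cell: i * spec.spiral_rise for i, cell in enumerate(cells)}
    elif spec.z_policy == "planar":
        cell_z = {cell: 0.0 for cell in cells}
    else:
        raise BuilderError(f"unknown z_policy: {spec.z_policy!r}")

    # group lattice-coincident vertices, then merge only across fused cells
    groups: Dict[Tuple[int, int], List[Tuple[Cell, int]]] = {}
    for cell in cells:
        for k in range(6):
            xy = _vertex_xy(cell, k, cc_bond)
            key = (round(xy[0] * 1e6), round(xy[1] * 1e6))
            groups.setdefault(key, []).append((cell, k))

    carbon_of: Dict[Tuple[Cell, int], int] = {}
    positions: List[np.ndarray] = []
    for key, members in sorted(groups.items()):
        parts: List[List[Tuple[Cell, int]]] = []
        for member in members:
            merged = False
            for part in parts:
                if any(frozenset((member[0], m[0])) in fusion for m in part):
                    part.append(member)
                    merged = True
                    break
            if not merged:
                parts.append([member])
        if len(parts) > 1 and spec.z_policy == "planar":
            raise BuilderError(
                "planar policy requested for a self-overlapping spec "
                f"(coincident non-fused cells at vertex {key}); use z_policy='spiral'"
            )
        for part in parts:
            xy = _vertex_xy(part[0][0], part[0][1], cc_bond)
            z = float(np.mean([cell_z[m[0]] for m in part]))
            idx = len(positions)
            positions.append(np.array([xy[0], xy[1], z]))
            for member in part:
                carbon_of[member] = idx

    # carbon-carbon bonds from hexagon edges
    cc_edges: Set[FrozenSet[int]] = set()
    for cell in cells:
        for k in range(6):
            a = carbon_of[(cell, k)]
            b = carbon_of[(cell, (k + 1) % 6)]
            cc_edges.add(frozenset((a, b)))

    neighbor_map: Dict[int, Set[int]] = {i: set() for i in range(len(positions))}
    for edge in cc_edges:
        i, j = tuple(edge)
        neighbor_map[i].add(j)
        neighbor_map[j].add(i)

    symbols = ["C"] * len(positions)
    coords = list(positions)
    adjacency = set(cc_edges)
    for i in range(len(positions)):
        if len(neighbor_map[i]) >= 3:
            continue
        center = positions[i]
        away = center - np.mean([positions[j] for j in neighbor_map[i]], axis=0)
        norm = np.linalg.norm(away)
        if norm < 1e-9:  # pragma: no cover - cannot happen on a hex lattice
            raise BuilderError(f"degenerate hydrogen direction at carbon {i}")
        h_index = len(coords)
        coords.append(center + ch_bond * away / norm)
        symbols.append("H")
        adjacency.add(frozenset((i, h_index)))

    molecule = Molecule(tuple(symbols), np.array(coords), spec.name or "benzenoid")
    return BuiltMolecule(molecule, adjacency, spec)


def attach_methyl(
    built: BuiltMolecule, carbon_index: int, cc_bond: float = 1.50, ch_bond: float = 1.09
) -> BuiltMolecule:
    """Replace the hydrogen on *carbon_index* with a methyl group.

    The sp3 carbon sits along the former C-H direction; its three hydrogens
    complete a staggered tetrahedral cap.  Used to exercise the
    substituent-bearing endpoint policy.
    """
    mol = built.molecule
    if mol.symbols[carbon_index] != "C":
        raise BuilderError(f"atom {carbon_index} is not a carbon")
    h_neighbors = [
        j for edge in built.adjacency if carbon_index in edge
        for j in edge - {carbon_index}
        if mol.symbols[j] == "H"
    ]
    if not h_neighbors:
        raise BuilderError(f"carbon {carbon_index} has no hydrogen to replace")
    h_index = h_neighbors[0]

    anchor = mol.coordinates[carbon_index]
    u = mol.coordinates[h_index] - anchor
    u = u / np.linalg.norm(u)
    # orthonormal frame around u
    seed = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, seed)
    v = v / np.linalg.norm(v)
    w = np.cross(u, v)

    methyl_c = anchor + cc_bond * u
    sin_t, cos_t = math.sqrt(8.0) / 3.0, 1.0 / 3.0  # tetrahedral 109.47 deg
    h_positions = [
        methyl_c + ch_bond * (
            cos_t * u + sin_t * (math.cos(phi) * v + math.sin(phi) * w)
        )
        for phi in (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)
    ]

    keep = [i for i in range(mol.atom_count) if i != h_index]
    remap = {old: new for new, old in enumerate(keep)}
    symbols = [mol.symbols[i] for i in keep] + ["C", "H", "H", "H"]
    coords = [mol.coordinates[i] for i in keep] + [methyl_c] + h_positions
    adjacency = {
        frozenset(remap[a] for a in edge)
        for edge in built.adjacency
        if h_index not in edge
    }
    mc = len(keep)
    adjacency.add(frozenset((remap[carbon_index], mc)))
    for offset in (1, 2, 3):
        adjacency.add(frozenset((mc, mc + offset)))
    new_mol = Molecule(tuple(symbols), np.array(coords), mol.title + "+CH3")
    return BuiltMolecule(new_mol, adjacency, built.spec)


# ring of cells around the origin, used for helicene-like circuits
_RING_POSITIONS: Tuple[Cell, ...] = AXIAL_NEIGHBORS


def _helicene_spec(n_cells: int, name: str) -> HexSpec:
    cells = tuple(_RING_POSITIONS[i % 6] for i in range(n_cells))
    if len(set(cells)) != len(cells):
        raise BuilderError(f"helicene of {n_cells} cells overlaps itself on the lattice")
    edges = tuple(frozenset((cells[i], cells[i + 1])) for i in range(n_cells - 1))
    return HexSpec(cells, fusion_edges=edges, z_policy="spiral", name=name)


def _linear_spec(n_cells: int, name: str) -> HexSpec:
    return HexSpec(tuple((i, 0) for i in range(n_cells)), name=name)


_CANONICAL_SPECS: Dict[str, HexSpec] = {
    "benzene": _linear_spec(1, "benzene"),
    "naphthalene": _linear_spec(2, "naphthalene"),
    "anthracene": _linear_spec(3, "anthracene"),
    "tetracene": _linear_spec(4, "tetracene"),
    "pentacene": _linear_spec(5, "pentacene"),
    "phenanthrene": HexSpec(((0, 0), (1, 0), (1, 1)), name="phenanthrene"),
    "chrysene": HexSpec(((0, 0), (1, 0), (1, 1), (2, 1)), name="chrysene"),
    "benzo[c]phenanthrene": _helicene_spec(4, "benzo[c]phenanthrene"),
    "triphenylene": HexSpec(((0, 0), (1, 0), (-1, 1), (0, -1)), name="triphenylene"),
    "pyrene": HexSpec(((0, 0), (1, 0), (0, 1), (1, 1)), name="pyrene"),
    "benzo[a]pyrene": HexSpec(
        ((0, 0), (1, 0), (0, 1), (1, 1), (-1, 0)), name="benzo[a]pyrene"
    ),
    "perylene": HexSpec(
        ((0, 0), (1, 0), (0, 1), (-1, 0), (0, -1)), name="perylene"
    ),
    "coronene": HexSpec(((0, 0),) + _RING_POSITIONS, name="coronene"),
    "pentahelicene": _helicene_spec(5, "pentahelicene"),
    "hexahelicene": _helicene_spec(6, "hexahelicene"),
}


def canonical_names() -> List[str]:
    """Names available to :func:`canonical`, sorted."""
    return sorted(_CANONICAL_SPECS)


def canonical(name: str, cc_bond: float = 1.40, ch_bond: float = 1.09) -> BuiltMolecule:
    """Deterministic built-in fixture by compound name."""
    key = name.strip().lower()
    if key not in _CANONICAL_SPECS:
        raise BuilderError(
            f"unknown compound {name!r}; available: {', '.join(canonical_names())}"
        )
    return build_benzenoid(_CANONICAL_SPECS[key], cc_bond=cc_bond, ch_bond=ch_bond)


def _is_crowded(cells: Sequence[Cell], cc_bond: float = 1.40) -> bool:
    """True when any intended-non-bonded carbon pair falls within bond range.

    Almost-closed shapes (e.g. a C-shaped wrap around an empty cell) place
    unmerged rim atoms ~1 bond length apart, which distance-based perception
    would spuriously bond; such planar specs are rejected during growth.
    """
    built = build_benzenoid(HexSpec(tuple(cells)), cc_bond=cc_bond)
    coords = built.molecule.coordinates
    carbons = [i for i, s in enumerate(built.molecule.symbols) if s == "C"]
    pts = coords[carbons]
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    bonded = np.zeros_like(dist, dtype=bool)
    index_of = {atom: k for k, atom in enumerate(carbons)}
    for edge in built.adjacency:
        i, j = tuple(edge)
        if i in index_of and j in index_of:
            bonded[index_of[i], index_of[j]] = bonded[index_of[j], index_of[i]] = True
    np.fill_diagonal(bonded, True)
    return bool((dist[~bonded] < 2.0).any())


def random_polyhex(n_cells: int, seed: int) -> HexSpec:
    """Grow a connected random polyhex by repeated uniform cell addition.

    Candidate cells whose planar geometry would crowd non-bonded atoms into
    bonding range (see :func:`_is_crowded`) are rejected and redrawn, so the
    emitted spec always survives distance-based bond perception intact.
    """
    if not 1 <= n_cells <= 10:
        raise BuilderError(f"n_cells must be in [1, 10], got {n_cells}")
    rng = random.Random(seed)
    cells: List[Cell] = [(0, 0)]
    occupied = {(0, 0)}
    while len(cells) < n_cells:
        frontier = sorted(
            {
                (c[0] + dq, c[1] + dr)
                for c in cells
                for dq, dr in AXIAL_NEIGHBORS
            }
            - occupied
        )
        rng.shuffle(frontier)
        for pick in frontier:
            if not _is_crowded(cells + [pick]):
                cells.append(pick)
                occupied.add(pick)
                break
        else:  # pragma: no cover - outward growth is always possible
            raise BuilderError("no viable growth cell found")
    return HexSpec(tuple(cells), name=f"polyhex-n{n_cells}-s{seed}")
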