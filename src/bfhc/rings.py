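"""Ring perception, perimeter walks and fused-ring topology classification.

Rings are a minimum cycle basis of the carbon skeleton (the smallest-set-of-
smallest-rings equivalent); for planar fused benzenoids this coincides with
the hexagonal faces.  The inner dual graph has one node per ring and an edge
between rings sharing at least two atoms (a fused bond).  The perimeter of a
fused component is the closed walk along edges belonging to exactly one ring.

Topology labels:

* ``peri-condensed`` -- some carbon belongs to >= 3 rings of the component;
* ``linear`` -- cata-condensed, the dual is a simple path and each internal
  ring's two fused neighbors subtend >= ``linear_angle_threshold`` degrees at
  its centroid (single-ring systems are linear by convention);
* ``angular`` -- any other cata-condensed arrangement (bent or branched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .errors import BoundaryError, RingPerceptionError
from .graph import TypedGraph
from .structure_io import Molecule

__all__ = [
    "DEFAULT_MAX_RING_SIZE",
    "DEFAULT_LINEAR_ANGLE_THRESHOLD",
    "RingSystem",
    "BoundaryWalk",
    "find_rings",
    "boundary_walk",
    "classify_topology",
    "TOPOLOGY_LABELS",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_RING_SIZE = 7
DEFAULT_LINEAR_ANGLE_THRESHOLD = 170.0

TOPOLOGY_LABELS = ("linear", "angular", "peri-condensed")


def _order_cycle(skeleton: nx.Graph, nodes: Sequence[int]) -> Tuple[int, ...]:
    """Order a basis-cycle node set into a closed walk along skeleton edges."""
    node_set = set(nodes)
    sub = skeleton.subgraph(node_set)
    start = min(node_set)

    def extend(path: list) -> Optional[list]:
        if len(path) == len(node_set):
            return path if sub.has_edge(path[-1], start) else None
        for nxt in sorted(sub.neighbors(path[-1])):
            if nxt not in path:
                result = extend(path + [nxt])
                if result is not None:
                    return result
        return None

    ordered = extend([start])
    if ordered is None:
        raise RingPerceptionError(
            f"basis cycle {sorted(node_set)} cannot be ordered into a closed walk"
        )
    return tuple(ordered)


@dataclass
class RingSystem:
    """Rings of a carbon skeleton plus derived structure.

    Attributes
    ----------
    rings : list of tuple
        Each ring is an ordered closed walk of carbon atom indices.
    membership : dict
        Atom index -> number of rings containing it (0 for ring-free atoms).
    dual : networkx.Graph
        One node per ring index; edges join rings sharing >= 2 atoms.
    skeleton : networkx.Graph
        The carbon skeleton the rings were perceived on.
    """

    rings: List[Tuple[int, ...]]
    membership: dict
    dual: nx.Graph
    skeleton: nx.Graph

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    def ring_sizes(self) -> List[int]:
        return [len(r) for r in self.rings]

    def has_non_hexagonal_rings(self) -> bool:
        return any(len(r) != 6 for r in self.rings)

    def fused_components(self) -> List[List[int]]:
        """Connected components of the dual, largest first (ring indices)."""
        comps = [sorted(c) for c in nx.connected_components(self.dual)]
        comps.sort(key=lambda c: (-len(c), c))
        return comps

    def boundary_edge_counts(self, ring_indices: Optional[Sequence[int]] = None) -> dict:
        """Map frozenset{i, j} bond -> number of rings (of the subset) using it."""
        if ring_indices is None:
            ring_indices = range(self.n_rings)
        counts: dict = {}
        for ri in ring_indices:
            ring = self.rings[ri]
            for a, b in zip(ring, ring[1:] + ring[:1]):
                key = frozenset((a, b))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def component_membership(self, ring_indices: Sequence[int]) -> dict:
        counts: dict = {}
        for ri in ring_indices:
            for atom in self.rings[ri]:
                counts[atom] = counts.get(atom, 0) + 1
        return counts


def find_rings(graph: TypedGraph, max_ring_size: int = DEFAULT_MAX_RING_SIZE) -> RingSystem:
    """Perceive a minimum cycle basis of the carbon skeleton.

    Raises :class:`RingPerceptionError` if any basis cycle exceeds
    *max_ring_size* (macrocycles are out of scope).  An acyclic skeleton
    yields a ring-free :class:`RingSystem`.
    """
    skeleton = graph.carbon_graph()
    basis = nx.minimum_cycle_basis(skeleton) if skeleton.number_of_nodes() else []
    rings = []
    for cycle in basis:
        if len(cycle) > max_ring_size:
            raise RingPerceptionError(
                f"ring of size {len(cycle)} exceeds max_ring_size={max_ring_size}"
            )
        rings.append(_order_cycle(skeleton, cycle))
    rings.sort(key=lambda r: (len(r), r))

    expected = (
        skeleton.number_of_edges() - skeleton.number_of_nodes()
        + nx.number_connected_components(skeleton)
    )
    if len(rings) != expected:  # pragma: no cover - networkx guarantees this
        raise RingPerceptionError(
            f"cycle basis size {len(rings)} != cyclomatic number {expected}"
        )

    membership = {node: 0 for node in skeleton.nodes}
    for ring in rings:
        for atom in ring:
            membership[atom] += 1

    dual = nx.Graph()
    dual.add_nodes_from(range(len(rings)))
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if len(set(rings[i]) & set(rings[j])) >= 2:
                dual.add_edge(i, j)
    return RingSystem(rings, membership, dual, skeleton)


@dataclass
class BoundaryWalk:
    """Ordered cyclic perimeter walk of one fused component.

    ``flags[k]`` is True when ``atoms[k]`` is a junction carbon (ring
    membership >= 2 within the component).  ``substituents`` maps a walk atom
    to non-ring heavy-atom neighbors hanging off it (e.g. methyl carbons).
    """

    atoms: List[int]
    flags: List[bool]
    ring_indices: List[int]
    substituents: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_junctions(self) -> int:
        return sum(self.flags)


def boundary_walk(
    ring_system: RingSystem,
    graph: TypedGraph,
    ring_indices: Optional[Sequence[int]] = None,
) -> BoundaryWalk:
    """Trace the perimeter of a fused component (default: largest component).

    The perimeter consists of the edges belonging to exactly one ring of the
    component.  Substituent branches (sp3 carbons etc.) are excluded from the
    walk and recorded as decorations on their anchor carbon.
    """
    if ring_system.n_rings == 0:
        raise BoundaryError("boundary walk requires at least one ring")
    if ring_indices is None:
        ring_indices = ring_system.fused_components()[0]
    ring_indices = list(ring_indices)

    edge_counts = ring_system.boundary_edge_counts(ring_indices)
    boundary_edges = [tuple(sorted(e)) for e, c in edge_counts.items() if c == 1]
    perimeter = nx.Graph(boundary_edges)
    if perimeter.number_of_nodes() == 0:
        raise BoundaryError("component has no boundary edges")
    bad = [n for n in perimeter.nodes if perimeter.degree(n) != 2]
    if bad or not nx.is_connected(perimeter):
        raise BoundaryError(
            "boundary is not a single closed walk (found "
            f"{nx.number_connected_components(perimeter)} pieces; "
            f"atoms with degree != 2: {sorted(bad)})"
        )

    # deterministic orientation: start at the smallest atom, step to its
    # smaller-index perimeter neighbor
    start = min(perimeter.nodes)
    walk = [start, min(perimeter.neighbors(start))]
    while True:
        prev, cur = walk[-2], walk[-1]
        nxt = next(n for n in perimeter.neighbors(cur) if n != prev)
        if nxt == start:
            break
        walk.append(nxt)

    membership = ring_system.component_membership(ring_indices)
    flags = [membership.get(a, 0) >= 2 for a in walk]

    ring_atoms = set().union(*(set(ring_system.rings[ri]) for ri in ring_indices))
    carbons = set(graph.carbon_indices())
    substituents: dict = {}
    skeleton = ring_system.skeleton
    for atom in walk:
        branches = [
            n for n in skeleton.neighbors(atom)
            if n in carbons and n not in ring_atoms
        ]
        if branches:
            substituents[atom] = sorted(branches)
    return BoundaryWalk(walk, flags, ring_indices, substituents)


def _ring_centroid(ring: Sequence[int], molecule: Molecule) -> np.ndarray:
    return molecule.coordinates[list(ring)].mean(axis=0)


def _is_simple_path(dual_sub: nx.Graph) -> bool:
    if dual_sub.number_of_nodes() == 1:
        return True
    degrees = [d for _, d in dual_sub.degree()]
    return (
        nx.is_connected(dual_sub)
        and max(degrees) <= 2
        and degrees.count(1) == 2
        and dual_sub.number_of_edges() == dual_sub.number_of_nodes() - 1
    )


def classify_topology(
    ring_system: RingSystem,
    molecule: Molecule,
    linear_angle_threshold: float = DEFAULT_LINEAR_ANGLE_THRESHOLD,
) -> str:
    """Classify the fused-ring arrangement as linear / angular / peri-condensed.

    Molecules with several disjoint fused components are labeled from the
    largest component (a warning lists all components).
    """
    if ring_system.n_rings == 0:
        raise RingPerceptionError("topology classification requires at least one ring")
    components = ring_system.fused_components()
    if len(components) > 1:
        logger.warning(
            "molecule has %d fused components (sizes %s); classifying the largest",
            len(components), [len(c) for c in components],
        )
    component = components[0]

    membership = ring_system.component_membership(component)
    if any(count >= 3 for count in membership.values()):
        return "peri-condensed"
    if len(component) == 1:
        return "linear"

    dual_sub = ring_system.dual.subgraph(component)
    if not _is_simple_path(dual_sub):
        return "angular"

    centroids = {ri: _ring_centroid(ring_system.rings[ri], molecule) for ri in component}
    for ri in component:
        neighbors = list(dual_sub.neighbors(ri))
        if len(neighbors) != 2:
            continue
        u = centroids[neighbors[0]] - centroids[ri]
        v = centroids[neighbors[1]] - centroids[ri]
        cosine = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        angle = np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0)))
        if angle < linear_angle_threshold:
            return "angular"
    return "linear"
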