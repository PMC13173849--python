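"""Detection of concave perimeter regions: bay, fjord, harbor and canyon.

A maximal run of *k* consecutive junction carbons (ring membership >= 2) on
the perimeter walk, flanked on both sides by rim carbons of membership 1,
defines one region:

====  =================  ==========
k     kind               path atoms
====  =================  ==========
1     fissure            3
2     bay                4
3     fjord              5
4     harbor             6
5     canyon             7
>= 6  extended           > 7
====  =================  ==========

The motif path is ``[left flank, run atoms..., right flank]``.  Fissures and
extended runs are tallied for completeness but are not BFHC indices.

Detection is purely topological; geometry acts only as a validity filter
(endpoints must be non-bonded, and within ``geometry_max_distance`` when the
filter is on).  Motifs failing geometry are retained with
``passed_geometry=False`` and excluded from the counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import BoundaryError
from .graph import TypedGraph
from .rings import BoundaryWalk, RingSystem, boundary_walk

__all__ = [
    "DEFAULT_GEOMETRY_MAX_DISTANCE",
    "KIND_BY_RUN_LENGTH",
    "Motif",
    "MotifReport",
    "detect_motifs",
    "brute_force_motifs",
    "report_motifs",
]

logger = logging.getLogger(__name__)

#: Default through-space cap (Angstrom) on the X...Y endpoint distance.
DEFAULT_GEOMETRY_MAX_DISTANCE = 4.5

KIND_BY_RUN_LENGTH = {1: "fissure", 2: "bay", 3: "fjord", 4: "harbor", 5: "canyon"}
BFHC_KINDS = ("bay", "fjord", "harbor", "canyon")


def _kind_for_run(k: int) -> str:
    return KIND_BY_RUN_LENGTH.get(k, "extended")


@dataclass(frozen=True)
class Motif:
    """One concave region: its kind, atom path and geometric validity."""

    kind: str
    path: Tuple[int, ...]
    endpoint_types: Tuple[str, str]
    endpoint_distance: float
    passed_geometry: bool
    passed_policy: bool = True

    @property
    def run_length(self) -> int:
        return len(self.path) - 2

    @property
    def counted(self) -> bool:
        return self.passed_geometry and self.passed_policy

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "path": list(self.path),
            "endpoint_types": list(self.endpoint_types),
            "endpoint_distance": self.endpoint_distance,
            "passed_geometry": self.passed_geometry,
            "passed_policy": self.passed_policy,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Motif":
        return cls(
            kind=data["kind"],
            path=tuple(data["path"]),
            endpoint_types=tuple(data["endpoint_types"]),
            endpoint_distance=float(data["endpoint_distance"]),
            passed_geometry=bool(data["passed_geometry"]),
            passed_policy=bool(data.get("passed_policy", True)),
        )


@dataclass
class MotifReport:
    """All detected regions of one molecule plus per-kind counts.

    Counts include only motifs passing the geometry filter and endpoint
    policy; the ``motifs`` list retains everything.
    """

    motifs: List[Motif] = field(default_factory=list)
    boundary_junction_total: int = 0

    def _count(self, kind: str) -> int:
        return sum(1 for m in self.motifs if m.kind == kind and m.counted)

    @property
    def bay_count(self) -> int:
        return self._count("bay")

    @property
    def fjord_count(self) -> int:
        return self._count("fjord")

    @property
    def harbor_count(self) -> int:
        return self._count("harbor")

    @property
    def canyon_count(self) -> int:
        return self._count("canyon")

    @property
    def fissure_count(self) -> int:
        return self._count("fissure")

    @property
    def extended_count(self) -> int:
        return self._count("extended")

    def bfhc(self) -> Tuple[int, int, int, int]:
        return (self.bay_count, self.fjord_count, self.harbor_count, self.canyon_count)

    def counts(self) -> dict:
        return {
            "bay": self.bay_count,
            "fjord": self.fjord_count,
            "harbor": self.harbor_count,
            "canyon": self.canyon_count,
            "fissure": self.fissure_count,
            "extended": self.extended_count,
        }

    def run_length_total(self) -> int:
        """Sum of run lengths over all detected motifs (filters ignored)."""
        return sum(m.run_length for m in self.motifs)

    def canonical_motifs(self) -> list:
        """Motifs sorted by a path-canonical key, for order-free comparison."""
        return sorted(
            self.motifs,
            key=lambda m: (m.kind, min(m.path, m.path[::-1])),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifReport):
            return NotImplemented
        mine = [(m.kind, min(m.path, m.path[::-1])) for m in self.canonical_motifs()]
        theirs = [(m.kind, min(m.path, m.path[::-1])) for m in other.canonical_motifs()]
        return mine == theirs

    def to_dict(self) -> dict:
        return {
            "counts": self.counts(),
            "boundary_junction_total": self.boundary_junction_total,
            "motifs": [m.to_dict() for m in self.canonical_motifs()],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MotifReport":
        return cls(
            motifs=[Motif.from_dict(m) for m in data["motifs"]],
            boundary_junction_total=int(data["boundary_junction_total"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "MotifReport":
        return cls.from_dict(json.loads(text))


def _maximal_cyclic_runs(flags: Sequence[bool]) -> List[List[int]]:
    """Indices of maximal runs of True in a cyclic boolean sequence."""
    n = len(flags)
    if all(flags):
        raise BoundaryError("entire boundary is junction carbons; no rim flanks")
    if not any(flags):
        return []
    # rotate so position 0 is False, then scan linearly
    offset = next(i for i in range(n) if not flags[i])
    runs, current = [], []
    for step in range(n):
        pos = (offset + step) % n
        if flags[pos]:
            current.append(pos)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def _make_motif(
    path: List[int],
    graph: TypedGraph,
    geometry_filter: bool,
    geometry_max_distance: float,
    endpoint_policy: str,
) -> Motif:
    x, y = path[0], path[-1]
    dist = float(graph.distance_matrix[x, y])
    nonbonded = not bool(graph.adjacency[x, y])
    passed_geometry = nonbonded and (
        not geometry_filter or dist <= geometry_max_distance
    )
    if endpoint_policy == "hydrogen-only":
        passed_policy = bool(graph.has_hydrogen[x] and graph.has_hydrogen[y])
    elif endpoint_policy == "any":
        passed_policy = True
    else:
        raise ValueError(f"unknown endpoint_policy: {endpoint_policy!r}")
    types = graph.atom_type if graph.atom_type else ["?"] * graph.molecule.atom_count
    return Motif(
        kind=_kind_for_run(len(path) - 2),
        path=tuple(path),
        endpoint_types=(types[x], types[y]),
        endpoint_distance=dist,
        passed_geometry=passed_geometry,
        passed_policy=passed_policy,
    )


def detect_motifs(
    ring_system: RingSystem,
    graph: TypedGraph,
    geometry_filter: bool = True,
    geometry_max_distance: float = DEFAULT_GEOMETRY_MAX_DISTANCE,
    endpoint_policy: str = "any",
) -> MotifReport:
    """Scan the perimeter of every fused component for concave regions."""
    motifs: List[Motif] = []
    junction_total = 0
    for component in ring_system.fused_components():
        walk = boundary_walk(ring_system, graph, component)
        junction_total += walk.n_junctions
        n = len(walk)
        for run in _maximal_cyclic_runs(walk.flags):
            left = walk.atoms[(run[0] - 1) % n]
            right = walk.atoms[(run[-1] + 1) % n]
            path = [left] + [walk.atoms[p] for p in run] + [right]
            motif = _make_motif(
                path, graph, geometry_filter, geometry_max_distance, endpoint_policy
            )
            if motif.kind == "extended":
                logger.warning(
                    "extended junction run of length %d at atoms %s",
                    motif.run_length, motif.path,
                )
            motifs.append(motif)
    return MotifReport(motifs=motifs, boundary_junction_total=junction_total)


def brute_force_motifs(
    graph: TypedGraph,
    ring_system: RingSystem,
    geometry_filter: bool = False,
    geometry_max_distance: float = DEFAULT_GEOMETRY_MAX_DISTANCE,
    endpoint_policy: str = "any",
) -> MotifReport:
    """Independent oracle: enumerate concave regions by exhaustive path search.

    Enumerates every simple path over perimeter edges (edges in exactly one
    ring) whose endpoints are membership-1 rim carbons, whose interior atoms
    are all junction carbons, and whose endpoints are not bonded.  Path
    reversals are deduplicated.  With the geometry filter off this must agree
    exactly with :func:`detect_motifs`.
    """
    motifs: List[Motif] = []
    junction_total = 0
    skeleton = ring_system.skeleton
    for component in ring_system.fused_components():
        edge_counts = ring_system.boundary_edge_counts(component)
        membership = ring_system.component_membership(component)
        perimeter_edges = [tuple(e) for e, c in edge_counts.items() if c == 1]
        boundary_atoms = set()
        for a, b in perimeter_edges:
            boundary_atoms.update((a, b))
        perimeter_adj: dict = {a: set() for a in boundary_atoms}
        for a, b in perimeter_edges:
            perimeter_adj[a].add(b)
            perimeter_adj[b].add(a)

        junctions = {a for a in boundary_atoms if membership.get(a, 0) >= 2}
        rims = {a for a in boundary_atoms if membership.get(a, 0) == 1}
        junction_total += len(junctions)

        seen = set()
        for start in sorted(rims):
            stack = [[start]]
            while stack:
                path = stack.pop()
                tail = path[-1]
                for nxt in sorted(perimeter_adj[tail]):
                    if nxt in path:
                        continue
                    if nxt in junctions:
                        stack.append(path + [nxt])
                    elif nxt in rims and len(path) >= 2:
                        full = path + [nxt]
                        if skeleton.has_edge(full[0], full[-1]):
                            continue  # endpoints bonded: not a concave region
                        key = min(tuple(full), tuple(reversed(full)))
                        if key in seen:
                            continue
                        seen.add(key)
                        motifs.append(
                            _make_motif(
                                list(full), graph, geometry_filter,
                                geometry_max_distance, endpoint_policy,
                            )
                        )
    return MotifReport(motifs=motifs, boundary_junction_total=junction_total)


def report_motifs(report: MotifReport, format: str = "table") -> str:
    """Serialize a report deterministically as a text table or JSON."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if format != "table":
        raise ValueError(f"unknown format: {format!r}")
    header = f"{'kind':<10s} {'path_indices':<40s} {'endpoint_distance':>18s} {'passed_geometry':>16s}"
    lines = [header, "-" * len(header)]
    for m in report.canonical_motifs():
        path_text = "-".join(str(i) for i in m.path)
        lines.append(
            f"{m.kind:<10s} {path_text:<40s} {m.endpoint_distance:>18.3f} "
            f"{str(m.passed_geometry):>16s}"
        )
    return "\n".join(lines)
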