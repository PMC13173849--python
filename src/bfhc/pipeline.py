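"""End-to-end convenience: coordinates in, BFHC counts and topology out."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .graph import DEFAULT_BOND_TOLERANCE, TypedGraph, build_typed_graph
from .motifs import DEFAULT_GEOMETRY_MAX_DISTANCE, MotifReport, detect_motifs
from .rings import (
    DEFAULT_LINEAR_ANGLE_THRESHOLD,
    DEFAULT_MAX_RING_SIZE,
    RingSystem,
    classify_topology,
    find_rings,
)
from .structure_io import Molecule

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs for the whole pipeline (all defaults documented upstream)."""

    radii: Optional[Mapping[str, float]] = None
    bond_tolerance_angstrom: float = DEFAULT_BOND_TOLERANCE
    allow_fragments: bool = False
    max_ring_size: int = DEFAULT_MAX_RING_SIZE
    linear_angle_threshold_degrees: float = DEFAULT_LINEAR_ANGLE_THRESHOLD
    geometry_filter: bool = True
    geometry_max_distance_angstrom: float = DEFAULT_GEOMETRY_MAX_DISTANCE
    endpoint_policy: str = "any"


@dataclass
class AnalysisResult:
    molecule: Molecule
    graph: TypedGraph
    ring_system: RingSystem
    topology: str
    motifs: MotifReport

    @property
    def n_carbon(self) -> int:
        return self.molecule.element_counts().get("C", 0)

    @property
    def n_hydrogen(self) -> int:
        return self.molecule.element_counts().get("H", 0)

    def bfhc(self):
        return self.motifs.bfhc()


def analyze(molecule: Molecule, config: AnalysisConfig = AnalysisConfig()) -> AnalysisResult:
    """Perceive bonds, find rings, classify topology and detect motifs."""
    graph = build_typed_graph(
        molecule,
        radii=config.radii,
        tolerance=config.bond_tolerance_angstrom,
        allow_fragments=config.allow_fragments,
    )
    ring_system = find_rings(graph, max_ring_size=config.max_ring_size)
    topology = classify_topology(
        ring_system, molecule,
        linear_angle_threshold=config.linear_angle_threshold_degrees,
    )
    motifs = detect_motifs(
        ring_system, graph,
        geometry_filter=config.geometry_filter,
        geometry_max_distance=config.geometry_max_distance_angstrom,
        endpoint_policy=config.endpoint_policy,
    )
    return AnalysisResult(molecule, graph, ring_system, topology, motifs)
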