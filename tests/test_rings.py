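import numpy as np
import pytest

import bfhc
from bfhc.errors import BoundaryError, RingPerceptionError
from bfhc.graph import build_typed_graph
from bfhc.rings import boundary_walk, classify_topology, find_rings
from bfhc.structure_io import Molecule

from conftest import CANONICAL_NAMES, PLANAR_FIXTURES, analyzed, built, transformed


def ring_system_of(name):
    return analyzed(name).ring_system


class TestFindRings:
    @pytest.mark.parametrize(
        "name, n_rings",
        [("naphthalene", 2), ("pyrene", 4), ("coronene", 7), ("benzene", 1)],
    )
    def test_ring_counts(self, name, n_rings):
        rs = ring_system_of(name)
        assert rs.n_rings == n_rings
        assert rs.ring_sizes() == [6] * n_rings

    def test_naphthalene_membership(self):
        rs = ring_system_of("naphthalene")
        assert sum(1 for v in rs.membership.values() if v == 2) == 2

    def test_pyrene_membership_three(self):
        rs = ring_system_of("pyrene")
        assert sum(1 for v in rs.membership.values() if v == 3) == 2

    @pytest.mark.parametrize("name", CANONICAL_NAMES)
    def test_cyclomatic_number(self, name):
        rs = ring_system_of(name)
        skeleton = rs.skeleton
        assert rs.n_rings == skeleton.number_of_edges() - skeleton.number_of_nodes() + 1

    def test_macrocycle_rejected(self):
        # a bare 8-ring of sp carbons exceeds the default size cap
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        radius = 1.4 / (2 * np.sin(np.pi / 8))
        coords = np.c_[radius * np.cos(theta), radius * np.sin(theta), np.zeros(8)]
        mol = Molecule(("C",) * 8, coords)
        graph = build_typed_graph(mol)
        with pytest.raises(RingPerceptionError, match="max_ring_size"):
            find_rings(graph)
        assert find_rings(graph, max_ring_size=8).n_rings == 1

    def test_acyclic_skeleton_yields_no_rings(self):
        # ethane: staggered-ish tetrahedral caps on a 1.54 A C-C bond
        u = np.array([
            [-1 / 3, 2 * np.sqrt(2) / 3, 0.0],
            [-1 / 3, -np.sqrt(2) / 3, np.sqrt(6) / 3],
            [-1 / 3, -np.sqrt(2) / 3, -np.sqrt(6) / 3],
        ])
        c1, c2 = np.zeros(3), np.array([1.54, 0.0, 0.0])
        coords = np.vstack([c1, c2, c1 + 1.09 * u, c2 - 1.09 * u])
        mol = Molecule(("C", "C") + ("H",) * 6, coords, "ethane")
        graph = build_typed_graph(mol)
        assert graph.atom_type[:2] == ["sp3", "sp3"]
        rs = find_rings(graph)
        assert rs.n_rings == 0
        with pytest.raises(RingPerceptionError):
            classify_topology(rs, mol)


class TestBoundaryWalk:
    def test_benzene_boundary(self):
        walk = boundary_walk(ring_system_of("benzene"), analyzed("benzene").graph)
        assert len(walk) == 6
        assert walk.n_junctions == 0

    def test_naphthalene_boundary(self):
        walk = boundary_walk(ring_system_of("naphthalene"), analyzed("naphthalene").graph)
        assert len(walk) == 10
        assert walk.n_junctions == 2
        positions = [i for i, f in enumerate(walk.flags) if f]
        gap = (positions[1] - positions[0]) % len(walk)
        assert gap not in (1, len(walk) - 1)  # junctions not adjacent in the walk

    def test_phenanthrene_single_junction_pair(self):
        walk = boundary_walk(ring_system_of("phenanthrene"), analyzed("phenanthrene").graph)
        assert len(walk) == 14
        runs = []
        flags = walk.flags
        n = len(flags)
        start = next(i for i in range(n) if not flags[i])
        current = 0
        for step in range(1, n + 1):
            if flags[(start + step) % n]:
                current += 1
            elif current:
                runs.append(current)
                current = 0
        assert sorted(runs) == [1, 1, 2]

    def test_no_rings_raises(self):
        rs = ring_system_of("benzene")
        empty = bfhc.RingSystem([], {}, rs.dual.subgraph([]), rs.skeleton)
        with pytest.raises(BoundaryError):
            boundary_walk(empty, analyzed("benzene").graph)

    @pytest.mark.parametrize("name", PLANAR_FIXTURES)
    def test_boundary_theorem(self, name):
        # unsubstituted simply connected fused systems: b2 - b3 = 6
        rs = ring_system_of(name)
        walk = boundary_walk(rs, analyzed(name).graph)
        b2 = sum(1 for f in walk.flags if not f)
        b3 = sum(1 for f in walk.flags if f)
        assert b2 - b3 == 6

    def test_substituent_excluded_but_recorded(self):
        fixture = bfhc.attach_methyl(built("benzene"), 0)
        graph = build_typed_graph(fixture.molecule)
        rs = find_rings(graph)
        walk = boundary_walk(rs, graph)
        assert len(walk) == 6
        assert len(walk.substituents) == 1
        (anchor, branches), = walk.substituents.items()
        assert graph.atom_type[branches[0]] == "sp3"


class TestClassifyTopology:
    @pytest.mark.parametrize("name", ["naphthalene", "anthracene", "tetracene", "pentacene"])
    def test_acenes_linear(self, name):
        assert analyzed(name).topology == "linear"

    def test_single_ring_linear_by_convention(self):
        assert analyzed("benzene").topology == "linear"

    @pytest.mark.parametrize("name", ["phenanthrene", "chrysene", "triphenylene",
                                      "benzo[c]phenanthrene", "pentahelicene", "hexahelicene"])
    def test_angular(self, name):
        assert analyzed(name).topology == "angular"

    @pytest.mark.parametrize("name", ["pyrene", "perylene", "benzo[a]pyrene", "coronene"])
    def test_peri_condensed(self, name):
        assert analyzed(name).topology == "peri-condensed"

    @pytest.mark.parametrize("name", ["anthracene", "phenanthrene", "pyrene"])
    def test_invariance_under_motion_and_permutation(self, name):
        reference = analyzed(name).topology
        rng = np.random.default_rng(3)
        for k in range(6):
            moved = transformed(built(name).molecule, rng, reflect=bool(k % 2))
            assert bfhc.analyze(moved).topology == reference

    def test_angle_threshold_configurable(self):
        mol = built("phenanthrene").molecule
        graph = build_typed_graph(mol)
        rs = find_rings(graph)
        # with an absurdly low threshold the 120-degree kink counts as straight
        assert classify_topology(rs, mol, linear_angle_threshold=100.0) == "linear"
        assert classify_topology(rs, mol) == "angular"

    def test_biphenyl_like_classified_from_largest_component(self, caplog):
        # naphthalene and benzene joined by a long non-fused C-C bond
        naph = built("naphthalene")
        benz = built("benzene")
        mol_n, mol_b = naph.molecule, benz.molecule
        # weld: drop one H from each part and bond the exposed carbons
        import numpy as np
        h_n = next(i for i, s in enumerate(mol_n.symbols) if s == "H")
        anchor_n = int(np.flatnonzero(
            build_typed_graph(mol_n).adjacency[h_n])[0])
        shift = mol_n.coordinates[h_n] - mol_n.coordinates[anchor_n]
        shift = shift / np.linalg.norm(shift)
        g_b = build_typed_graph(mol_b)
        h_b = next(i for i, s in enumerate(mol_b.symbols) if s == "H")
        anchor_b = int(np.flatnonzero(g_b.adjacency[h_b])[0])
        # place benzene so its anchor carbon sits 1.48 A from naphthalene's
        target = mol_n.coordinates[anchor_n] + 1.48 * shift
        u = mol_b.coordinates[h_b] - mol_b.coordinates[anchor_b]
        u = u / np.linalg.norm(u)
        # rotate benzene so its anchor->H axis points back along -shift
        v = -shift
        axis = np.cross(u, v)
        s, c = np.linalg.norm(axis), float(np.dot(u, v))
        if s < 1e-12:
            rot = np.eye(3) if c > 0 else -np.eye(3)
        else:
            k = axis / s
            K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            rot = np.eye(3) + np.sin(np.arctan2(s, c)) * K + (1 - c) * K @ K
        coords_b = (mol_b.coordinates - mol_b.coordinates[anchor_b]) @ rot.T + target
        keep_n = [i for i in range(mol_n.atom_count) if i != h_n]
        keep_b = [i for i in range(mol_b.atom_count) if i != h_b]
        symbols = tuple(mol_n.symbols[i] for i in keep_n) + tuple(
            mol_b.symbols[i] for i in keep_b)
        coords = np.vstack([mol_n.coordinates[keep_n], coords_b[keep_b]])
        welded = Molecule(symbols, coords, "2-phenylnaphthalene")
        graph = build_typed_graph(welded)
        rs = find_rings(graph)
        assert rs.n_rings == 3
        assert len(rs.fused_components()) == 2
        import logging
        with caplog.at_level(logging.WARNING, logger="bfhc.rings"):
            label = classify_topology(rs, welded)
        assert label == "linear"  # naphthalene component wins
        assert any("fused components" in r.message for r in caplog.records)
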