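"""Shared fixtures: cached canonical structures and transform helpers."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import bfhc

CANONICAL_NAMES = tuple(bfhc.canonical_names())

CATA_PLANAR = (
    "benzene", "naphthalene", "anthracene", "tetracene", "pentacene",
    "phenanthrene", "chrysene", "triphenylene",
)
PLANAR_FIXTURES = CATA_PLANAR + ("pyrene", "benzo[a]pyrene", "perylene", "coronene")


@lru_cache(maxsize=None)
def built(name: str) -> bfhc.BuiltMolecule:
    return bfhc.canonical(name)


@lru_cache(maxsize=None)
def analyzed(name: str) -> bfhc.AnalysisResult:
    return bfhc.analyze(built(name).molecule)


@pytest.fixture
def get_built():
    return built


@pytest.fixture
def get_analyzed():
    return analyzed


def transformed(molecule: bfhc.Molecule, rng: np.random.Generator,
                reflect: bool = False) -> bfhc.Molecule:
    """Random rigid motion (optionally improper) plus atom permutation."""
    rot = Rotation.random(random_state=rng).as_matrix()
    if reflect:
        rot = rot @ np.diag([1.0, 1.0, -1.0])
    shift = rng.uniform(-10.0, 10.0, size=3)
    coords = molecule.coordinates @ rot.T + shift
    perm = rng.permutation(molecule.atom_count)
    return bfhc.Molecule(
        tuple(molecule.symbols[i] for i in perm), coords[perm], molecule.title
    )
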