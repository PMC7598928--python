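import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from capsidatlas import (AtlasParams, InterfaceAssemblySystem, PlantedSystemSpec,
                         build_atlas, basin_decomposition,
                         build_capsid_polyhedron, make_planted_interface_system)
from capsidatlas.atlas import Atlas, AtlasRegion
from capsidatlas.energy import DiscretizedWell, EnergyModel
from capsidatlas.geometry import Atom, Pose, RigidUnit


def _atom(i: int, prefix: str, xyz) -> Atom:
    return Atom(f"{prefix}{i}", i, prefix, np.array(xyz, dtype=float))


@pytest.fixture(scope="session")
def small_system() -> InterfaceAssemblySystem:
    """Planted 6-atom / 6-well system shared by the atlas-level tests."""
    return make_planted_interface_system(
        PlantedSystemSpec(atoms_per_unit=6, n_wells=6, seed=5)
    )


@pytest.fixture(scope="session")
def small_params() -> AtlasParams:
    return AtlasParams(seed=5, max_samples_per_region=150)


@pytest.fixture(scope="session")
def small_atlas(small_system, small_params) -> Atlas:
    return build_atlas(small_system, small_params)


@pytest.fixture(scope="session")
def small_basins(small_atlas, small_system):
    return basin_decomposition(small_atlas, small_system.true_pose)


@pytest.fixture(scope="session")
def t1_graph():
    return build_capsid_polyhedron(1)


@pytest.fixture(scope="session")
def t3_graph():
    return build_capsid_polyhedron(3)


@pytest.fixture(scope="session")
def micro_system() -> InterfaceAssemblySystem:
    """Two atoms per unit, two wells: small enough for the exhaustive pose
    oracle."""
    fixed = RigidUnit((_atom(0, "F", [-1.2, 0, 0]), _atom(1, "F", [1.2, 0, 0])), "F")
    mobile = RigidUnit((_atom(0, "M", [-1.2, 0, 0]), _atom(1, "M", [1.2, 0, 0])), "M")
    wells = (DiscretizedWell("F0", "M0", 2.5, 3.1, "wa"),
             DiscretizedWell("F1", "M1", 2.5, 3.1, "wb"))
    return InterfaceAssemblySystem(
        fixed, mobile, EnergyModel(wells=wells),
        Pose(np.eye(3), np.array([0.0, 2.8, 0.0])), "micro",
    )


@pytest.fixture()
def sphere_pair_system() -> InterfaceAssemblySystem:
    fixed = RigidUnit((_atom(0, "F", [0, 0, 0]),), "F")
    mobile = RigidUnit((_atom(0, "M", [0, 0, 0]),), "M")
    wells = (DiscretizedWell("F0", "M0", 2.5, 3.1, "ws"),)
    return InterfaceAssemblySystem(
        fixed, mobile, EnergyModel(wells=wells),
        Pose(np.eye(3), np.array([0.0, 2.8, 0.0])), "sphere-pair",
    )


def _shift_cfg(system: InterfaceAssemblySystem, offset) -> "object":
    return system.configuration(Pose(np.eye(3), np.array(offset, dtype=float)))


@pytest.fixture()
def handmade_atlas():
    """A tiny atlas built by hand (no sampling): two symmetric bottoms
    {a, b} and {c, d}, each with one 1-edge ancestor, for exact-arithmetic
    cruciality tests.

    The true pose sits on the {a, b} bottom's configuration.
    """
    fixed = RigidUnit((_atom(0, "F", [-1.2, 0, 0]), _atom(1, "F", [1.2, 0, 0])), "F")
    mobile = RigidUnit((_atom(0, "M", [-1.2, 0, 0]), _atom(1, "M", [1.2, 0, 0])), "M")
    wells = (
        DiscretizedWell("F0", "M0", 2.4, 3.4, "a", residue_pair=(10, 20)),
        DiscretizedWell("F1", "M1", 2.4, 3.4, "b", residue_pair=(11, 21)),
        DiscretizedWell("F0", "M1", 2.4, 3.4, "c", residue_pair=(12, 22)),
        DiscretizedWell("F1", "M0", 2.4, 3.4, "d", residue_pair=(13, 23)),
    )
    system = InterfaceAssemblySystem(
        fixed, mobile, EnergyModel(wells=wells),
        Pose(np.eye(3), np.array([0.0, 2.9, 0.0])), "handmade",
    )
    atlas = Atlas(system=system, params=AtlasParams(seed=0))

    def put(edges, dim, offsets):
        region = AtlasRegion(edges=frozenset(edges), dim=dim)
        for off in offsets:
            region.configurations.append(_shift_cfg(system, off))
        atlas.regions[region.label] = region
        return region

    put({"a", "b"}, 0, [[0.0, 2.9, 0.0]])          # true bottom
    put({"c", "d"}, 0, [[0.0, -2.9, 0.0]])         # mirror bottom
    put({"a"}, 5, [[0.0, 3.6, 0.0], [0.0, 4.4, 0.0]])
    put({"c"}, 5, [[0.0, -3.6, 0.0], [0.0, -4.4, 0.0]])
    return atlas
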