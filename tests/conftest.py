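"""Shared fixtures: the toy library, small phantoms, and analytic test rigs."""

from __future__ import annotations

import numpy as np
import pytest

from voxdose.lattice import Phantom, VoxelLattice, make_phantom
from voxdose.nuclear_data import (
    EnergyGrid,
    Library,
    Material,
    NuclideData,
    VACUUM,
    make_synthetic_library,
)
from voxdose.source import EnergyGroups, Monodirectional, PointSpatial, SourceSpec, head_neck_beam


@pytest.fixture(scope="session")
def toy_library() -> Library:
    return make_synthetic_library()


@pytest.fixture(scope="session")
def cube_phantom() -> Phantom:
    return make_phantom("cube-with-tumor", scale=0.5)


@pytest.fixture(scope="session")
def cube_beam(cube_phantom) -> SourceSpec:
    side = cube_phantom.lattice.dims[0] * cube_phantom.lattice.spacing[0]
    return head_neck_beam(center=(-1.0, side / 2, side / 2),
                          direction=(1.0, 0.0, 0.0), radius=side / 3)


def make_absorber_slab(sigma_cm: float = 2.0, n_voxels: int = 10, dx_cm: float = 0.25,
                       heating_mev: float = 1.0):
    """A 1-d pure-absorber slab with an axial monoenergetic pencil beam.

    The track-length flux in voxel i and the leakage fraction have closed
    forms: (e^{-S x_i} - e^{-S x_{i+1}})/(S V) and e^{-S L}.
    """
    nodes = np.array([1e-5, 2e7])
    absorber = NuclideData(
        "ABS", "neutron", 10.0, EnergyGrid(nodes),
        sigma_total=np.array([sigma_cm, sigma_cm]),
        partials={"capture": np.array([sigma_cm, sigma_cm])},
        heating_H=np.array([heating_mev, heating_mev]),
    )
    library = Library([absorber])
    material = Material(1, "absorber", (("ABS", 1.0),), 1.0)
    lattice = VoxelLattice((0.0, 0.0, 0.0), (dx_cm, 10.0, 10.0),
                           np.ones((n_voxels, 1, 1), dtype=np.int32))
    phantom = Phantom("absorber-slab", lattice, {0: VACUUM, 1: material},
                      {"all": np.ones(lattice.dims, dtype=bool)})
    source = SourceSpec(
        particle_mix=(("neutron", 1.0),),
        spatial=PointSpatial((-0.5, 5.0, 5.0)),
        angular=Monodirectional((1.0, 0.0, 0.0)),
        energy={"neutron": EnergyGroups(((0.9, 1.1, 1.0),))},
    )
    return phantom, library, source
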