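"""Shared fixtures: reference phantoms, engines and compartment dose maps.

Everything heavy is session-scoped; all inputs are generated in-process
(no fixture files).
"""

import numpy as np
import pytest

from pedidose.dosimetry import compartment_dose_maps
from pedidose.materials import material_from_table
from pedidose.phantom import OrganSpec, Phantom, build_reference_phantom
from pedidose.transport import TransportEngine


@pytest.fixture(scope="session")
def male_phantom():
    return build_reference_phantom("male", 2.0)


@pytest.fixture(scope="session")
def female_phantom():
    return build_reference_phantom("female", 2.0)


@pytest.fixture(scope="session")
def male_engine(male_phantom):
    return TransportEngine(male_phantom)


@pytest.fixture(scope="session")
def female_engine(female_phantom):
    return TransportEngine(female_phantom)


@pytest.fixture(scope="session")
def male_maps(male_phantom, male_engine):
    """Per-compartment dose-rate maps at acceptance-grade statistics."""
    return compartment_dose_maps(male_phantom, histories_per_source=400_000,
                                 seed=1, engine=male_engine)


@pytest.fixture(scope="session")
def female_maps(female_phantom, female_engine):
    return compartment_dose_maps(female_phantom, histories_per_source=400_000,
                                 seed=1, engine=female_engine)


def uniform_box(n=40, voxel_cm=0.5, material="soft_tissue", density=None,
                central_source=False):
    """Homogeneous cube phantom for transport oracles.

    With ``central_source`` a small same-material region at the centre is
    labelled separately so sources can be kept away from the surface.
    """
    mat = material_from_table(material)
    if density is not None:
        mat = type(mat)(mat.name, dict(mat.mass_fractions), density)
    labels = np.ones((n, n, n), dtype=np.uint16)
    side = n * voxel_cm
    organs = {1: OrganSpec("box", "none", side ** 3, mat, ())}
    if central_source:
        c = n // 2
        labels[c - 1:c + 1, c - 1:c + 1, c - 1:c + 1] = 2
        organs[2] = OrganSpec("source", "none", (2 * voxel_cm) ** 3, mat, ())
    return Phantom(labels, voxel_cm, (0.0, 0.0, 0.0), organs, "male")
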