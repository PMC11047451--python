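"""Shared fixtures: the spherical study geometry every suite runs against.

Session-scoped because the 19-sensor / 500-source lead fields are the
expensive common substrate of the QC, inverse-solver and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from meegsi.forward import (
    SourceSpace,
    apply_orientation_constraint,
    homogeneous_leadfield_eeg,
    three_shell_sphere_leadfield_eeg,
)
from meegsi.synth import (
    make_1020_layout,
    make_icosphere,
    make_nested_head,
    make_source_cap,
)

SHELL_RADII = (0.082, 0.088, 0.092)
CONDUCTIVITIES = (0.33, 0.0042, 0.33)


@pytest.fixture(scope="session")
def head():
    return make_nested_head(subdivisions=4)


@pytest.fixture(scope="session")
def source_cap(head):
    """(positions, normals, decimated mesh, kept indices) for 500 sources."""
    return make_source_cap(head.cortex, 500)


@pytest.fixture(scope="session")
def sensors(head):
    return make_1020_layout(head.scalp)


@pytest.fixture(scope="session")
def source_space(source_cap):
    pos, normals, _, _ = source_cap
    return SourceSpace(pos, orientations=normals, mode="constrained")


@pytest.fixture(scope="session")
def leadfield_sphere(source_cap, sensors):
    """Constrained three-shell lead field of the 500-source fixture."""
    pos, normals, _, _ = source_cap
    free = three_shell_sphere_leadfield_eeg(
        SourceSpace(pos), sensors, radii=SHELL_RADII, sigmas=CONDUCTIVITIES
    )
    return apply_orientation_constraint(free, normals)


@pytest.fixture(scope="session")
def leadfield_homogeneous(source_cap, sensors):
    pos, normals, _, _ = source_cap
    free = homogeneous_leadfield_eeg(SourceSpace(pos), sensors, sigma=CONDUCTIVITIES[0])
    return apply_orientation_constraint(free, normals)


@pytest.fixture(scope="session")
def one_ring(source_cap):
    """Vertex -> {itself + neighbors} on the source cap."""
    _, _, dec, kept = source_cap
    index_of = {int(v): i for i, v in enumerate(kept)}
    nbr = {i: {i} for i in range(len(kept))}
    for a, b in dec.edges():
        ia, ib = index_of.get(int(a)), index_of.get(int(b))
        if ia is not None and ib is not None:
            nbr[ia].add(ib)
            nbr[ib].add(ia)
    return nbr


@pytest.fixture(scope="session")
def icosphere3():
    return make_icosphere(3)
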