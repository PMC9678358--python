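"""Shared fixtures.

The finite-element solves and the calibrated arbor set are expensive
relative to everything else, so they are computed once per session and
shared by the field, activation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from nocimech import fields as fl
from nocimech import synthetic as syn
from nocimech.contact import ElasticMedium, ProbeSpec
from nocimech.morphology import Arbor


@pytest.fixture(scope="session")
def probe60() -> ProbeSpec:
    return ProbeSpec(diameter=60.0)


@pytest.fixture(scope="session")
def homog_profile(probe60) -> fl.RadialProfile:
    """Homogeneous-material solve with the parabolic indenter (Hertz regime)."""
    medium = ElasticMedium(2.6, 0.45)
    stack = fl.LayerStack.homogeneous(medium)
    return fl.solve_indentation(stack, probe60, 20.0, indenter="parabolic")


@pytest.fixture(scope="session")
def layered_profile(probe60) -> fl.RadialProfile:
    """Production solve: default cuticle-on-PDMS stack, 60 μm probe, d = 20 μm."""
    return fl.solve_indentation(fl.LayerStack.default(), probe60, 20.0)


@pytest.fixture(scope="session")
def layered_map(layered_profile) -> fl.FieldMap:
    return fl.radial_to_map(layered_profile, pixel_size=1.0, extent=150.0)


@pytest.fixture(scope="session")
def wt_arbors() -> list[Arbor]:
    """Five calibrated wild-type arbors (the n = 5 cells of the study design)."""
    return [syn.generate_arbor(syn.ArborGenParams(), seed=k) for k in range(5)]


@pytest.fixture()
def cross_arbor() -> Arbor:
    """Four straight 300 μm arms along the axes — every metric is analytic."""
    nodes = np.array(
        [[0.0, 0.0], [300.0, 0.0], [-300.0, 0.0], [0.0, 300.0], [0.0, -300.0]]
    )
    parents = np.array([-1, 0, 0, 0, 0])
    return Arbor(nodes=nodes, parents=parents, class_label="custom")
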