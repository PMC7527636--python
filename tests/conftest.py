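"""Shared fixtures: toy morphologies and cached synthetic suites.

Expensive simulation products (protocol suites, extraction reports) are
session-scoped so independent tests reuse them instead of regenerating.
"""

import numpy as np
import pytest

from olmcell.morphology import Morphology, REGION_DEND, REGION_SOMA, Section
from olmcell.simulator import PassiveParams
from olmcell.synthetic_data import NoiseModel, make_cell, run_suite


@pytest.fixture()
def ball_and_stick() -> Morphology:
    """Soma cylinder (d = L = 20 um) plus one 200 um, 2 um dendrite."""
    soma = Section(
        region=REGION_SOMA,
        points=np.array([[0.0, 0.0, 0.0, 20.0], [20.0, 0.0, 0.0, 20.0]]),
    )
    dend = Section(
        region=REGION_DEND,
        points=np.array([[20.0, 0.0, 0.0, 2.0], [220.0, 0.0, 0.0, 2.0]]),
        parent=0,
    )
    return Morphology([soma, dend])


@pytest.fixture()
def iso_cell():
    """Single-compartment soma with realistic OLM-like passive load."""
    d = np.sqrt(25000.0 / np.pi)
    soma = Section(
        region=REGION_SOMA,
        points=np.array([[0.0, 0.0, -d / 2, d], [0.0, 0.0, d / 2, d]]),
    )
    from olmcell.morphology import discretize

    geom = discretize(Morphology([soma]), 0.1, 100.0, 150.0, 1.0)
    passive = PassiveParams(Ra=150.0, Cm=1.0, Gpas=1.0e-5, Epas=-65.0)
    return geom, passive


@pytest.fixture(scope="session")
def point_cell():
    return make_cell("point", seed=3)


@pytest.fixture(scope="session")
def point_suite(point_cell):
    """Noise-free protocol suite of the single-compartment ground-truth cell."""
    return run_suite(point_cell, NoiseModel.none(), seed=3)


@pytest.fixture(scope="session")
def cell1():
    return make_cell("cell1", seed=11)


@pytest.fixture(scope="session")
def cell1_suite(cell1):
    """Noise-free suite of the dendritic cell (dt matched to refit runs)."""
    return run_suite(cell1, NoiseModel.none(), seed=11, dt=0.2)
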