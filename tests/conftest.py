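"""Shared fixtures.

The mini-nucleosome and its derived scenarios are expensive to build
(wrap calibration plus the translocase pulling protocol), so they are
session-scoped; the builders themselves cache per process.
"""

import numpy as np
import pytest

from chaperone_cg import scenarios, synthetic_fixtures as fx
from chaperone_cg.energy import ForceFieldParams


@pytest.fixture()
def toy_helix():
    return fx.make_toy_helix(n_beads=20, seed=0)


@pytest.fixture()
def forcefield():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def mini_system():
    return fx.make_mini_nucleosome()


@pytest.fixture(scope="session")
def unwrapped_system():
    spec = scenarios.ScenarioSpec("partial_unwrapped", seed=3)
    return scenarios.build_scenario(spec)


@pytest.fixture(scope="session")
def nap1_system():
    spec = scenarios.ScenarioSpec("partial_unwrapped_nap1",
                                  chaperone_distance=18.0, seed=3)
    return scenarios.build_scenario(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, n=12, chain="A"):
    """Self-avoiding-ish random chain for oracle tests."""
    from chaperone_cg.cg_model import AMINO_ACID, BeadRecord, CGStructure
    names = ["ALA", "GLU", "LYS", "GLY", "SER", "ASP"]
    pos = np.cumsum(rng.normal(scale=2.2, size=(n, 3))
                    + np.array([3.0, 0.0, 0.0]), axis=0)
    s = CGStructure()
    for i in range(n):
        s.beads.append(BeadRecord(chain, i + 1, AMINO_ACID,
                                  names[i % len(names)], pos[i]))
    s.validate()
    return s
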