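"""Shared fixtures: small synthetic cells, settled states, fixture SWC text."""

import numpy as np
import pytest

from axosoma.builder import RegionMembraneSpec, build_cell
from axosoma.morphology import Morphology, Section, resegment
from axosoma.solver import init_steady_state
from axosoma.synth import SynthMorphParams, generate, generate_pool

# morphometric targets at the small end of the imported-cell pool; small
# trees keep the compartment counts (and hence runtimes) modest while
# staying inside the observed ranges
POOL_BASE = SynthMorphParams(
    seed=11,
    soma_diameter=58.0,
    n_primary=10,
    target_dendrite_surface=155_000.0,
    mean_terminal_distance=520.0,
)

MINI = SynthMorphParams(
    seed=5,
    soma_diameter=50.0,
    n_primary=4,
    target_dendrite_surface=40_000.0,
    mean_terminal_distance=300.0,
)


@pytest.fixture(scope="session")
def mini_morph():
    return resegment(generate(MINI))


@pytest.fixture(scope="session")
def mini_cell(mini_morph):
    return build_cell(mini_morph)


@pytest.fixture(scope="session")
def mini_state(mini_cell):
    return init_steady_state(mini_cell)


@pytest.fixture(scope="session")
def pool_morphs():
    return [resegment(m) for m in generate_pool(5, POOL_BASE,
                                                variability=0.08, seed=23)]


@pytest.fixture(scope="session")
def pool_cells(pool_morphs):
    return [build_cell(m) for m in pool_morphs]


@pytest.fixture(scope="session")
def pool_states(pool_cells):
    return [init_steady_state(c) for c in pool_cells]


def passive_membrane(leak=0.25):
    """A membrane spec with leak only, for analytic cable checks."""
    return RegionMembraneSpec(channels={
        "soma_gradients": {"leak": (leak, leak)},
        "g_h": 0.0, "mid_dendrite": {},
        "hillock_soma_end": {"leak": 4.4}, "hillock_ais_end": {"leak": 4.4},
        "ais": {"leak": 4.4}, "node": {"leak": 1.0},
        "MYSA": {"leak": 1.0}, "FLUT": {"leak": 0.1}, "STIN": {"leak": 0.1}})


def cable_morphology(length=1000.0, diam=2.0, nseg=101):
    """Tiny soma stub + one uniform dendritic cylinder."""
    soma = Section(points=np.array([[0, -0.5, 0, 1.0], [0, 0, 0, 1.0],
                                    [0, 0.5, 0, 1.0]]),
                   parent=None, region="soma", nseg=2)
    dend = Section(points=np.array([[0, 0, 0, diam], [0, length, 0, diam]]),
                   parent=0, parent_pos=0.5, region="dendrite", nseg=nseg)
    return Morphology(sections=[soma, dend], soma_sections=[0])


THREE_POINT_SWC = """\
# soma sample plus an unbranched two-point dendrite
1 1 0 0 0 25 -1
2 3 50 0 0 2 1
3 3 150 0 0 2 2
"""

BRANCHED_SWC = """\
1 1 0 0 0 30 -1
2 3 40 0 0 4 1
3 3 80 0 0 3 2
4 3 120 30 0 2 3
5 3 120 -30 0 2 3
6 3 160 60 0 1 4
"""
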