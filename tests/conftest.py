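"""Shared fixtures: small example networks and random-network helpers.
Everything is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import boolmaa as bm
from boolmaa.ensembles import _toggles_to_network


@pytest.fixture
def example1():
    """Mutual activation: two point attractors, a synchronous-only
    oscillation, no asynchronous MAA."""
    return bm.parse_bnet("A, B\nB, A\n")


@pytest.fixture
def star2():
    """The unique 2-variable network with an asynchronous MAA (both
    functions XNOR)."""
    return bm.star_network(2)


@pytest.fixture
def star3():
    return bm.star_network(3)


@pytest.fixture
def star4():
    return bm.star_network(4)


@pytest.fixture
def chain3(star2):
    """The 2-variable MAA network hidden behind one linear node: the
    extension of the B->A edge.  Deleting the delay node recreates the MAA
    (reduction of a linear node can create motif avoidance)."""
    return bm.linear_extend(star2, [("B", "A")])


@pytest.fixture
def six_cycle():
    """A 3-variable network whose MAA is a 6-state cycle of single-variable
    transitions (000->010->110->100->101->001->000), with trap state 111
    reached only from 011.  No state pair oscillates back and forth, so the
    2-variable pattern does not embed."""
    toggles = np.zeros((8, 3), dtype=np.uint8)
    cycle = [0, 2, 3, 1, 5, 4]
    for a, b in zip(cycle, cycle[1:] + cycle[:1]):
        toggles[a, (a ^ b).bit_length() - 1] = 1
    toggles[6, 0] = 1  # 011 -> 111
    return _toggles_to_network(toggles, 3)


def random_net(rng, n_max=8, k_max=4):
    """One random critical N-K network with N, K drawn uniformly."""
    n = int(rng.integers(2, n_max + 1))
    k = int(rng.integers(1, min(n, k_max) + 1))
    return bm.generate_critical_rbn(bm.EnsembleConfig(N=n, K=k), rng)


@pytest.fixture(scope="session")
def survey3():
    """The exhaustive 3-variable template survey (computed once)."""
    return bm.prototype_survey_3var()
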