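"""Shared fixtures: small hand-built solutes and toy solvated systems.

All fixtures are generated programmatically; the 6/8 A switching window
(with boxes of ~16.5 A) keeps the periodic systems desk-sized while
preserving the structure of the production 10/12 A setup.
"""

import numpy as np
import pytest

from saisolv import (AtomRecord, NonbondedSettings, SoluteTopology,
                     make_solvated_system, make_toy_solute, vacuum_system)


def _atom(i, element, q=0.0, r_min=3.8, eps=0.1):
    if element == "H":
        r_min, eps = 2.2, 0.03
    return AtomRecord(index=i, element=element, charge=q, r_min=r_min,
                      epsilon=eps)


@pytest.fixture
def methanol_like():
    """CH3OH-like: 2 heavy atoms, 4 hydrogens, neutral."""
    atoms = (
        _atom(0, "C", -0.1), _atom(1, "O", -0.5),
        _atom(2, "H", 0.1), _atom(3, "H", 0.1), _atom(4, "H", 0.1),
        _atom(5, "H", 0.3),
    )
    bonds = ((0, 1), (0, 2), (0, 3), (0, 4), (1, 5))
    return SoluteTopology(name="methanol-like", atoms=atoms, bonds=bonds)


@pytest.fixture
def chain3():
    """Three heavy atoms in a chain (C1-C2-C3), no hydrogens."""
    atoms = tuple(_atom(i, "C", q) for i, q in enumerate((0.2, -0.4, 0.2)))
    return SoluteTopology(name="chain3", atoms=atoms, bonds=((0, 1), (1, 2)))


@pytest.fixture
def benzene_like():
    """Six heavy atoms in a ring, no hydrogens."""
    atoms = tuple(_atom(i, "C", 0.0) for i in range(6))
    bonds = tuple((i, (i + 1) % 6) for i in range(6))
    return SoluteTopology(name="ring6", atoms=atoms, bonds=bonds)


@pytest.fixture
def toluene_like():
    """Seven heavy atoms (six-ring + methyl) with eight hydrogens."""
    return make_toy_solute(7, 8, "ring", seed=3)


@pytest.fixture
def small_settings():
    """Desk-scale switching window (6-8 A) at the production temperature."""
    return NonbondedSettings(r_on=6.0, r_off=8.0)


@pytest.fixture
def tiny_aq_system():
    """2-heavy-atom toy solute in 16 waters, 16.5 A box."""
    solute = make_toy_solute(2, 3, "chain", seed=9)
    return make_solvated_system(solute, n_waters=16, box_edge=16.5, seed=9)


@pytest.fixture
def tiny_vac_system(tiny_aq_system):
    return vacuum_system(tiny_aq_system.solute,
                         coords=tiny_aq_system.solute_coords.copy())
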