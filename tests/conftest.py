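"""Shared fixtures: hand-built pedigrees and small simulated herds."""

import numpy as np
import pandas as pd
import pytest

from dgvcal import simdata
from dgvcal.pedigree import Pedigree


def make_pedigree(rows):
    """rows: (animal, sire, dam, birth_year) tuples; 0 = unknown parent."""
    return Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year"]))


@pytest.fixture
def trio():
    """Two unrelated founders and their offspring."""
    return make_pedigree([(1, 0, 0, 2000), (2, 0, 0, 2000), (3, 1, 2, 2001)])


@pytest.fixture
def sib_pedigree():
    """Founders 1,2,3; full sibs 4,5 (1x2); half sib 6 (1x3)."""
    return make_pedigree(
        [
            (1, 0, 0, 2000),
            (2, 0, 0, 2000),
            (3, 0, 0, 2000),
            (4, 1, 2, 2001),
            (5, 1, 2, 2001),
            (6, 1, 3, 2001),
        ]
    )


@pytest.fixture
def fullsib_mating():
    """Offspring of a full-sib mating: inbreeding coefficient 0.25."""
    return make_pedigree(
        [
            (1, 0, 0, 2000),
            (2, 0, 0, 2000),
            (3, 1, 2, 2001),
            (4, 1, 2, 2001),
            (5, 3, 4, 2002),
        ]
    )


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimulationConfig(
        n_founders=60, n_generations=4, n_markers=250, n_qtl=25, seed=11
    )


@pytest.fixture(scope="session")
def small_herd(small_config):
    return simdata.simulate_herd(small_config)
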