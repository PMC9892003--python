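"""Shared fixtures: small particle tables and a default synthetic scene."""

import numpy as np
import pandas as pd
import pytest

from polyneigh.particle_io import ParticleTable
from polyneigh.synthetic_scenes import SceneConfig, generate_scene

COLUMNS = [
    "tomogram_id", "particle_id", "x", "y", "z",
    "rot", "tilt", "psi", "state_label", "population_label",
]


def make_table(rows, pixel_size=1.0):
    """Build a ParticleTable from (tid, pid, x, y, z, rot, tilt, psi[, state, pop])."""
    full = []
    for r in rows:
        r = list(r)
        if len(r) == 8:
            r += ["unassigned", "unidentified"]
        full.append(r)
    return ParticleTable(pd.DataFrame(full, columns=COLUMNS), pixel_size=pixel_size)


@pytest.fixture(scope="session")
def default_scene():
    """The default 20-tomogram synthetic scene (fixed seed) with ground truth."""
    return generate_scene(SceneConfig(n_tomograms=20, seed=11))


@pytest.fixture(scope="session")
def small_scene():
    """A faster 6-tomogram scene for mid-weight geometry tests."""
    return generate_scene(SceneConfig(n_tomograms=6, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
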