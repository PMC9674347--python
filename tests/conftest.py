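"""Shared fixtures: small synthetic complexes and derived models.

Everything is generated at test time from fixed seeds; no data files.
"""

import numpy as np
import pytest

import xlweaver as xw


@pytest.fixture(scope="session")
def truth4():
    """4-subunit ground truth (~400 residues, 6 rigid bodies)."""
    return xw.generate_complex(
        n_subunits=4, sizes=[100] * 4, n_rigid_per_subunit=[2, 2, 1, 1], seed=3
    )


@pytest.fixture(scope="session")
def model4(truth4):
    segments = {}
    for st in truth4.structures:
        segments.update(xw.segment_rigid_bodies(st))
    return xw.build_coarse_model(truth4.structures, segments)


@pytest.fixture(scope="session")
def links4(truth4):
    xl, _ = xw.simulate_crosslinks(truth4, n_links=40, fp_rate=0.0, seed=5)
    return xl


@pytest.fixture(scope="session")
def truth_coords4(truth4, model4):
    return truth4.coords_for_model(model4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
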