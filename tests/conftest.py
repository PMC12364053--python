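import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import replanrl as rl

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")
from replanrl.environment import PlanningEnv


@pytest.fixture(scope="session")
def geom():
    """Default desk-scale phantom (64x64 slice, 3 CTVs + 12 OARs)."""
    return rl.generate_phantom(rl.PhantomConfig.default(), seed=7)


@pytest.fixture(scope="session")
def geom_small():
    return rl.generate_phantom(rl.PhantomConfig.small(), seed=0)


@pytest.fixture(scope="session")
def dinf(geom):
    return rl.compute_dose_influence(geom, rl.BeamConfig())


@pytest.fixture(scope="session")
def dinf_small(geom_small):
    return rl.compute_dose_influence(geom_small, rl.BeamConfig.small())


@pytest.fixture(scope="session")
def env_small(geom_small, dinf_small):
    """Shared planning environment; tests must reset() before stepping."""
    return PlanningEnv(geom_small, dinf_small)


def make_tiny_dinf(matrix, ctv_rows, oar_rows=None):
    """DoseInfluence from a dense matrix with explicit structure rows."""
    from scipy import sparse

    from replanrl.dose import DoseInfluence

    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    rows = {"CTV1": np.asarray(ctv_rows, dtype=int)}
    if oar_rows is not None:
        rows["OAR1"] = np.asarray(oar_rows, dtype=int)
    return DoseInfluence(
        matrix=sparse.csr_matrix(matrix),
        structure_rows=rows,
        grid_shape=(matrix.shape[0],),
    )


@pytest.fixture
def tiny_dinf_factory():
    return make_tiny_dinf
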