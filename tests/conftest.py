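"""Shared fixtures: optimised toy crystals, reused across the suite."""

import numpy as np
import pytest

from polyphonon.fixtures import chain_1d, exp6_fcc, rigid_diatomic_crystal
from polyphonon.optimizer import optimize


@pytest.fixture(scope="session")
def chain():
    return chain_1d()


@pytest.fixture(scope="session")
def fcc():
    return exp6_fcc()


@pytest.fixture(scope="session")
def fcc_min(fcc):
    """exp6_fcc relaxed to its static minimum."""
    res = optimize(fcc.crystal, fcc.ff, tol=1e-6)
    assert res.converged
    return res.crystal


@pytest.fixture(scope="session")
def diatomic_alpha():
    fx = rigid_diatomic_crystal(packing="alpha")
    res = optimize(fx.crystal, fx.ff, tol=1e-4)
    assert res.converged
    return fx, res.crystal


@pytest.fixture(scope="session")
def diatomic_beta():
    fx = rigid_diatomic_crystal(packing="beta")
    res = optimize(fx.crystal, fx.ff, tol=1e-4)
    assert res.converged
    return fx, res.crystal


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
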