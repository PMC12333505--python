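"""Shared fixtures: small deterministic RNGs and one session-scoped
Wright-Fisher run reused by the extinction-time tests."""

from __future__ import annotations

import numpy as np
import pytest

from ecoresist import UniformEffect, WFParams, run


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240603)


@pytest.fixture(scope="session")
def wf_tau_run():
    """Moderate lineage-tracking run used by several extinction-time tests.

    N=2000, fc=0 (DFE uniform on [0,1]), DEE uniform on [0,1], mu=5e-4 so
    roughly one lineage emerges per generation; ~6e4 lineages total.
    """
    params = WFParams(
        N=2000,
        mu=5e-4,
        generations=60_000,
        fc=0.0,
        dee=UniformEffect(0.0, 1.0),
        seed=11,
    )
    return run(params)
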