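"""Shared fixtures: worked parameter sets, reference communities, RNG helpers."""

from __future__ import annotations

import numpy as np
import pytest

from traitweb import (
    AttackKernel,
    CRParams,
    HandlingKernel,
    Prey,
    PreyCommunity,
    TraitDistribution,
)
from traitweb.synthetic import make_mismatch_community


@pytest.fixture
def worked_params() -> CRParams:
    """Consumer-resource parameter set with hand-computable equilibrium:
    R* = 2, C* = 0.8, eigenvalues −0.1 ± i√0.79."""
    return CRParams(r=1.0, K=10.0, a=1.0, e=0.5, m=1.0)


@pytest.fixture
def reference_fixture():
    """Mismatch-graded 10-prey community with shared kernels (even mismatch
    spacing on [0, 25], equal densities)."""
    return make_mismatch_community(10, 25.0)


@pytest.fixture
def single_prey():
    """One prey sitting exactly at the predator optimum; unit parameters."""
    comm = PreyCommunity(
        prey=(Prey(id="p0", density=1.0, optimum=0.0),), consumer_density=1.0
    )
    kernels = [
        (
            AttackKernel(alpha_max=1.0, width=1.0, optimum=0.0),
            HandlingKernel(eta_min=1.0, width=1.0, optimum=0.0),
        )
    ]
    return comm, kernels


def random_community(rng: np.random.Generator, n_prey: int = 5):
    """Random community + kernels for oracle comparisons (seeded by caller)."""
    prey = tuple(
        Prey(
            id=f"p{i}",
            density=float(rng.uniform(0.2, 3.0)),
            optimum=float(rng.uniform(-3.0, 3.0)),
        )
        for i in range(n_prey)
    )
    comm = PreyCommunity(prey=prey, consumer_density=float(rng.uniform(0.5, 2.0)))
    kernels = [
        (
            AttackKernel(
                alpha_max=float(rng.uniform(0.5, 2.0)),
                width=float(rng.uniform(0.5, 2.0)),
                optimum=p.optimum,
            ),
            HandlingKernel(
                eta_min=float(rng.uniform(0.5, 2.0)),
                width=float(rng.uniform(0.5, 2.0)),
                optimum=p.optimum,
            ),
        )
        for p in prey
    ]
    dist = TraitDistribution(mean=float(rng.uniform(-1.0, 1.0)), variance=float(rng.uniform(0.1, 5.0)))
    return comm, kernels, dist
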