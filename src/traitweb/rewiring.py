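"""Rewiring metrics: link counts, strength summaries and turnover.

"Rewiring" is the reconfiguration of the number and/or strength of
trophic links.  An intake profile becomes a set of realised links by
thresholding: prey with intake above ε count as interaction partners.
Sweeping the predator's trait variance σ² then quantifies the
more-but-weaker / fewer-but-stronger trade-off: concentrated phenotypes
feed hard on well-matched prey, variable phenotypes spread weak feeding
across many prey.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import IncompatibleProfilesError, InvalidThresholdError
from .trait_intake import (
    AttackKernel,
    HandlingKernel,
    IntakeProfile,
    PreyCommunity,
    TraitDistribution,
    intake_profile,
)

__all__ = [
    "RewiringSummary",
    "RewiringComparison",
    "count_links",
    "link_set",
    "summarize_profile",
    "compare_profiles",
    "variance_sweep",
    "default_epsilon",
]


@dataclass(frozen=True)
class RewiringSummary:
    """Link statistics of one intake profile at one threshold.

    Strength fields are ``None`` when no link clears the threshold.
    """

    sigma2: float
    link_threshold: float
    n_links: int
    max_strength: float | None
    mean_strength: float | None
    total_intake: float


@dataclass(frozen=True)
class RewiringComparison:
    """Set-level difference between two link sets over the same prey pool."""

    links_gained: frozenset[str]
    links_lost: frozenset[str]
    links_retained: frozenset[str]
    jaccard_turnover: float
    strength_deltas: dict[str, float]


def _check_threshold(epsilon: float) -> None:
    if epsilon < 0:
        raise InvalidThresholdError(f"link threshold must be >= 0, got {epsilon}")


def count_links(profile: IntakeProfile, epsilon: float) -> int:
    """Number of prey with intake strictly above ``epsilon``."""
    _check_threshold(epsilon)
    return int(sum(1 for f in profile.intakes if f > epsilon))


def link_set(profile: IntakeProfile, epsilon: float) -> frozenset[str]:
    """Ids of prey whose intake exceeds ``epsilon``."""
    _check_threshold(epsilon)
    return frozenset(
        pid for pid, f in zip(profile.prey_ids, profile.intakes) if f > epsilon
    )


def summarize_profile(profile: IntakeProfile, epsilon: float) -> RewiringSummary:
    """Summary statistics over the links clearing ``epsilon``."""
    _check_threshold(epsilon)
    strengths = [f for f in profile.intakes if f > epsilon]
    return RewiringSummary(
        sigma2=profile.sigma2,
        link_threshold=epsilon,
        n_links=len(strengths),
        max_strength=max(strengths) if strengths else None,
        mean_strength=float(np.mean(strengths)) if strengths else None,
        total_intake=profile.total_intake,
    )


def compare_profiles(
    a: IntakeProfile, b: IntakeProfile, epsilon: float
) -> RewiringComparison:
    """Link turnover from profile ``a`` to profile ``b``.

    Both profiles must cover the same prey id set (the same community
    evaluated under two scenarios).  Jaccard turnover is
    1 − |retained| / |union|, i.e. 0 for identical link sets and 1 for
    disjoint ones; an empty union (no links in either scenario) yields 0.
    """
    if set(a.prey_ids) != set(b.prey_ids):
        raise IncompatibleProfilesError(
            f"profiles cover different prey: {sorted(set(a.prey_ids) ^ set(b.prey_ids))}"
        )
    la, lb = link_set(a, epsilon), link_set(b, epsilon)
    union = la | lb
    retained = la & lb
    turnover = 1.0 - len(retained) / len(union) if union else 0.0
    fa, fb = a.as_dict(), b.as_dict()
    return RewiringComparison(
        links_gained=frozenset(lb - la),
        links_lost=frozenset(la - lb),
        links_retained=retained,
        jaccard_turnover=turnover,
        strength_deltas={pid: fb[pid] - fa[pid] for pid in sorted(union)},
    )


def default_epsilon(profile: IntakeProfile, fraction: float = 1e-3) -> float:
    """Relative link threshold: ``fraction`` of the profile's strongest intake.

    In a variance sweep the reference profile is the one at the smallest
    σ², where intake is most concentrated; the cutoff is then scale-free
    with respect to densities and kernel amplitudes.
    """
    return fraction * max(profile.intakes)


def variance_sweep(
    comm: PreyCommunity,
    kernels: Sequence[tuple[AttackKernel, HandlingKernel]],
    sigma2_grid: Sequence[float],
    *,
    predator_mean: float,
    epsilon: float | None = None,
    n_nodes: int = 64,
) -> pd.DataFrame:
    """One rewiring summary per σ² in the grid.

    Returns a DataFrame with columns sigma2, epsilon, n_links,
    max_strength, mean_strength, total_intake (NaN strengths when no
    links clear the threshold).  When ``epsilon`` is None it defaults to
    10⁻³ × the maximum intake at the smallest σ² in the grid.
    """
    grid = list(sigma2_grid)
    if not grid:
        raise ValueError("sigma2 grid must be nonempty")
    if any(s < 0 for s in grid):
        raise ValueError(f"sigma2 grid must be nonnegative, got {grid}")

    profiles = {
        s: intake_profile(
            comm, TraitDistribution(mean=predator_mean, variance=s), kernels,
            n_nodes=n_nodes,
        )
        for s in grid
    }
    if epsilon is None:
        epsilon = default_epsilon(profiles[min(grid)])

    rows = []
    for s in grid:
        summ = summarize_profile(profiles[s], epsilon)
        rows.append(
            {
                "sigma2": s,
                "epsilon": epsilon,
                "n_links": summ.n_links,
                "max_strength": np.nan if summ.max_strength is None else summ.max_strength,
                "mean_strength": np.nan if summ.mean_strength is None else summ.mean_strength,
                "total_intake": summ.total_intake,
            }
        )
    return pd.DataFrame(rows)
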