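"""Synthetic fixtures: mismatch-graded prey communities and genotype panels.

Everything here is seeded through :class:`numpy.random.Generator`
(PCG64), so a fixture spec plus a seed reproduces the identical objects
on any platform.  Panels plant known G / E / G×E structure and return
the analytically computed variance components for recovery tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ecoevo import (
    CRParams,
    Genotype,
    GxEDecomposition,
    PARAMETER_FLOOR,
    ReactionNorm,
    T_REF,
)
from .errors import DegenerateRangeError, ParameterFloorWarning
from .trait_intake import (
    AttackKernel,
    HandlingKernel,
    Prey,
    PreyCommunity,
    shared_kernels,
)

__all__ = [
    "FixtureSpec",
    "NormSpec",
    "make_mismatch_community",
    "make_genotype_panel",
    "random_feasible_params",
    "DEFAULT_PARAM_RANGES",
]


@dataclass(frozen=True)
class NormSpec:
    """Planted reaction-norm structure for one parameter across a panel.

    ``intercept`` is the panel-mean value at T_ref; ``intercept_sd``
    plants G (0 ⇒ all genotypes identical at T_ref).  ``mean_slope``
    plants E; ``slope_sd`` plants G×E (0 ⇒ parallel norms).
    """

    intercept: float
    intercept_sd: float = 0.0
    mean_slope: float = 0.0
    slope_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.intercept_sd < 0 or self.slope_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


@dataclass(frozen=True)
class FixtureSpec:
    """Full recipe for a genotype panel with planted variance components."""

    seed: int
    n_genotypes: int = 2
    a: NormSpec = field(default_factory=lambda: NormSpec(intercept=1.0, mean_slope=0.02, slope_sd=0.01))
    m: NormSpec = field(default_factory=lambda: NormSpec(intercept=0.6, mean_slope=0.02, slope_sd=0.005))
    e: NormSpec = field(default_factory=lambda: NormSpec(intercept=0.5))
    T_ref: float = T_REF

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError(f"need n_genotypes >= 2, got {self.n_genotypes}")


def make_mismatch_community(
    n_prey: int = 10,
    mismatch_max: float = 25.0,
    *,
    density: float = 1.0,
    consumer_density: float = 1.0,
    predator_mean: float = 0.0,
    alpha_max: float = 1.0,
    tau_alpha: float = 1.0,
    eta_min: float = 1.0,
    tau_eta: float = 1.0,
    seed: int | None = None,
    density_cv: float = 0.0,
) -> tuple[PreyCommunity, list[tuple[AttackKernel, HandlingKernel]]]:
    """Reference community with evenly spaced phenotypic mismatch.

    Prey optima are placed so that mismatch_i = (x̄ − X_opt,i)² is evenly
    spaced on [0, mismatch_max]; the first prey sits exactly at the
    predator's mean trait.  Densities are equal by default; a positive
    ``density_cv`` draws lognormal densities with that coefficient of
    variation (seeded).  Returns the community and one shared-parameter
    kernel pair per prey, each centred on its prey's optimum.
    """
    if n_prey < 1:
        raise ValueError(f"need n_prey >= 1, got {n_prey}")
    if mismatch_max < 0:
        raise ValueError(f"mismatch_max must be >= 0, got {mismatch_max}")

    if n_prey == 1:
        mismatches = np.array([0.0])
    else:
        mismatches = np.linspace(0.0, mismatch_max, n_prey)

    if density_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + density_cv**2))
        densities = density * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_prey)
    else:
        densities = np.full(n_prey, density)

    prey = tuple(
        Prey(
            id=f"prey_{i:02d}",
            density=float(densities[i]),
            optimum=predator_mean + math.sqrt(mismatches[i]),
        )
        for i in range(n_prey)
    )
    comm = PreyCommunity(prey=prey, consumer_density=consumer_density)
    kernels = shared_kernels(
        comm, alpha_max=alpha_max, tau_alpha=tau_alpha, eta_min=eta_min, tau_eta=tau_eta
    )
    return comm, kernels


def _planted_components(
    intercepts: np.ndarray, slopes: np.ndarray, T_grid: np.ndarray, T_ref: float
) -> GxEDecomposition:
    """Closed-form two-way components for linear norms v = i_g + s_g (T − T_ref).

    With d_t = T_t − T_ref:  genotype means are i_g + s_g d̄, temperature
    means are ī + s̄ d_t, and interaction residuals factor as
    (s_g − s̄)(d_t − d̄), so V_GxE = Var(s) · Var(d) exactly.
    """
    d = T_grid - T_ref
    d_bar = d.mean()
    var_d = float(np.mean((d - d_bar) ** 2))
    g_means = intercepts + slopes * d_bar
    V_G = float(np.mean((g_means - g_means.mean()) ** 2))
    V_E = float(slopes.mean() ** 2 * var_d)
    var_s = float(np.mean((slopes - slopes.mean()) ** 2))
    V_GxE = var_s * var_d
    return GxEDecomposition(
        parameter="", V_G=V_G, V_E=V_E, V_GxE=V_GxE, V_total=V_G + V_E + V_GxE
    )


def make_genotype_panel(
    spec: FixtureSpec,
    T_grid: list[float] | np.ndarray | None = None,
) -> tuple[list[Genotype], dict[str, GxEDecomposition]]:
    """Genotype panel with planted G / E / G×E structure.

    Intercepts (values at T_ref) are drawn N(intercept, intercept_sd²)
    and slopes N(mean_slope, slope_sd²) per parameter; draws below the
    positivity floor are truncated there (logged via warning).  Genotype
    ids are A, B, C, ... in draw order.

    Returns the panel and, for each parameter, the planted variance
    components computed analytically on ``T_grid`` (default 5-35 °C in
    5 °C steps) — the bookkeeping that recovery tests compare against
    :func:`traitweb.ecoevo.decompose_variance`.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(
        T_grid if T_grid is not None else np.arange(5.0, 36.0, 5.0), dtype=float
    )
    names = [chr(ord("A") + k) if k < 26 else f"G{k}" for k in range(spec.n_genotypes)]

    norms: dict[str, list[ReactionNorm]] = {}
    planted: dict[str, GxEDecomposition] = {}
    for pname, ns in (("a", spec.a), ("m", spec.m), ("e", spec.e)):
        intercepts = ns.intercept + ns.intercept_sd * rng.standard_normal(spec.n_genotypes)
        if ns.intercept_sd == 0.0:
            intercepts = np.full(spec.n_genotypes, ns.intercept)
        low = intercepts < PARAMETER_FLOOR
        if low.any():
            warnings.warn(
                f"{low.sum()} {pname}-intercept draw(s) truncated at the parameter floor",
                ParameterFloorWarning,
                stacklevel=2,
            )
            intercepts = np.where(low, PARAMETER_FLOOR, intercepts)
        slopes = ns.mean_slope + ns.slope_sd * rng.standard_normal(spec.n_genotypes)
        if ns.slope_sd == 0.0:
            slopes = np.full(spec.n_genotypes, ns.mean_slope)
        norms[pname] = [
            ReactionNorm(value_at_ref=float(iv), slope=float(sl), ref_temperature=spec.T_ref)
            for iv, sl in zip(intercepts, slopes)
        ]
        comp = _planted_components(intercepts, slopes, grid, spec.T_ref)
        planted[pname] = GxEDecomposition(
            parameter=pname, V_G=comp.V_G, V_E=comp.V_E, V_GxE=comp.V_GxE,
            V_total=comp.V_total,
        )

    panel = [
        Genotype(id=names[k], norm_a=norms["a"][k], norm_m=norms["m"][k], norm_e=norms["e"][k])
        for k in range(spec.n_genotypes)
    ]
    return panel, planted


#: Biologically plausible uniform sampling ranges (simulation units).
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "r": (0.5, 2.0),
    "K": (5.0, 20.0),
    "a": (0.5, 2.0),
    "e": (0.2, 0.8),
    "m": (0.1, 1.0),
}


def random_feasible_params(
    n_draws: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> list[CRParams]:
    """Rejection-sample parameter sets with a feasible coexistence equilibrium.

    Draws each of r, K, a, e, m uniformly from its range and keeps draws
    satisfying m/(e·a) < K.  Raises :class:`DegenerateRangeError` if more
    than 99% of attempts are rejected.
    """
    if n_draws < 1:
        raise ValueError(f"need n_draws >= 1, got {n_draws}")
    ranges = dict(DEFAULT_PARAM_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if lo <= 0 or hi < lo:
            raise ValueError(f"range for {name} must be positive with lo <= hi, got ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    out: list[CRParams] = []
    attempts = 0
    while len(out) < n_draws:
        batch = max(n_draws - len(out), 64)
        draws = {
            name: rng.uniform(lo, hi, size=batch) for name, (lo, hi) in ranges.items()
        }
        ok = draws["m"] / (draws["e"] * draws["a"]) < draws["K"]
        attempts += batch
        for k in np.flatnonzero(ok):
            if len(out) >= n_draws:
                break
            out.append(
                CRParams(
                    r=float(draws["r"][k]), K=float(draws["K"][k]), a=float(draws["a"][k]),
                    e=float(draws["e"][k]), m=float(draws["m"][k]),
                )
            )
        if attempts >= 1000 and len(out) < 0.01 * attempts:
            raise DegenerateRangeError(
                f"feasibility rejection rate above 99% "
                f"({len(out)}/{attempts} accepted); widen the ranges"
            )
    return out
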