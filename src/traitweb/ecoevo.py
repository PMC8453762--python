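"""Temperature-dependent consumer-resource model with G×E reaction norms.

The ecological core is the Rosenzweig-MacArthur-type per-capita system

    (1/R) dR/dt = r − (r/K) R − a C
    (1/C) dC/dt = e a R − m

with resource growth rate ``r``, carrying capacity ``K``, consumer
attack rate ``a``, conversion efficiency ``e`` and consumer mortality
``m``.  The feasible coexistence equilibrium is closed-form:

    R* = m / (e a),     C* = (r / a) (1 − R*/K),   feasible iff R* < K.

Each demographic parameter of the consumer is carried by a genotype as a
thermal reaction norm — a function of temperature anchored at a
reference of 15 °C.  Differences among genotypes at the reference
temperature are G; the mean slope across genotypes is E (plasticity);
slope differences among genotypes are G×E.  The resource responds to
temperature only plastically (E), with a humped growth rate by default.

Selection among a discrete genotype panel is resolved by adaptive
dynamics: a rare invader grows at rate s = e' a' R*_res − m' at the
resident's equilibrium, so the genotype depressing the resource to the
lowest R* = m/(e a) excludes all others (the R* rule).  Community
resilience is −Re(λmax) of the Jacobian at equilibrium: the asymptotic
return rate from small perturbations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import (
    InfeasibleEquilibriumError,
    InfeasibleResidentError,
    InsufficientDesignError,
    InvalidStateError,
    NoViableGenotypeError,
    NumericalFailureError,
    OutOfRangeError,
    ParameterFloorWarning,
)

__all__ = [
    "ReactionNorm",
    "Genotype",
    "ResourceEnvironment",
    "CRParams",
    "Equilibrium",
    "StabilityResult",
    "InvasionResult",
    "GxEDecomposition",
    "evaluate_norm",
    "params_at",
    "equilibrium",
    "rhs",
    "jacobian",
    "stability",
    "invasion_fitness",
    "favoured_genotype",
    "crossing_temperature",
    "temperature_sweep",
    "simulate_trajectory",
    "decompose_variance",
    "PARAMETER_FLOOR",
    "T_REF",
    "NEUTRALITY_TOL",
]

#: Reference temperature (°C) at which genotypes share their "initial" phenotype.
T_REF = 15.0
#: Positivity floor for evaluated demographic parameters.
PARAMETER_FLOOR = 1e-6
#: |ΔR*| below which two genotypes are treated as selectively neutral.
NEUTRALITY_TOL = 1e-9


@dataclass(frozen=True)
class ReactionNorm:
    """Thermal reaction norm of one demographic parameter.

    ``linear``:          v(T) = value_at_ref + slope · (T − T_ref)
    ``quadratic-peak``:  v(T) = value_at_ref + curvature · [(T − peak_temperature)²
                                                            − (T_ref − peak_temperature)²]

    The quadratic-peak form is anchored so that v(T_ref) = value_at_ref;
    with curvature < 0 it rises to a maximum at ``peak_temperature`` and
    falls beyond it — the canonical humped thermal-performance shape.
    A flat norm (linear, slope 0) returns value_at_ref everywhere.
    """

    value_at_ref: float
    slope: float = 0.0
    form: str = "linear"
    ref_temperature: float = T_REF
    peak_temperature: float | None = None
    curvature: float | None = None

    def __post_init__(self) -> None:
        if self.form not in ("linear", "quadratic-peak"):
            raise ValueError(f"unknown reaction-norm form {self.form!r}")
        if self.form == "quadratic-peak":
            if self.peak_temperature is None or self.curvature is None:
                raise ValueError("quadratic-peak norm needs peak_temperature and curvature")
            if self.curvature >= 0:
                raise ValueError(f"curvature must be < 0, got {self.curvature}")

    def raw(self, T: np.ndarray | float) -> np.ndarray | float:
        """Un-floored evaluation at temperature ``T`` (°C)."""
        T = np.asarray(T, dtype=float)
        if self.form == "linear":
            out = self.value_at_ref + self.slope * (T - self.ref_temperature)
        else:
            out = self.value_at_ref + self.curvature * (
                (T - self.peak_temperature) ** 2
                - (self.ref_temperature - self.peak_temperature) ** 2
            )
        return out if out.ndim else float(out)


def evaluate_norm(
    norm: ReactionNorm, T: float, *, floor: float = PARAMETER_FLOOR
) -> float:
    """Evaluate a reaction norm, flooring the result at ``floor``.

    Linear norms inevitably cross zero somewhere; rather than failing,
    the value is clamped to a small positive floor and a
    :class:`ParameterFloorWarning` is emitted, keeping temperature
    sweeps total while making biological invalidity visible.
    """
    if not np.isfinite(T):
        raise ValueError(f"temperature must be finite, got {T}")
    value = float(norm.raw(T))
    if value < floor:
        warnings.warn(
            f"reaction-norm value {value:.3g} at T={T} floored to {floor:.1g}",
            ParameterFloorWarning,
            stacklevel=2,
        )
        return floor
    return value


@dataclass(frozen=True)
class Genotype:
    """A consumer genotype: reaction norms for attack rate, mortality and
    conversion efficiency."""

    id: str
    norm_a: ReactionNorm
    norm_m: ReactionNorm
    norm_e: ReactionNorm

    def norms(self) -> dict[str, ReactionNorm]:
        return {"a": self.norm_a, "m": self.norm_m, "e": self.norm_e}


@dataclass(frozen=True)
class ResourceEnvironment:
    """Thermal response of the resource: growth rate r(T) and capacity K(T).

    Defaults give a humped r(T) peaking at 25 °C and a
    temperature-independent K, over a declared valid range of 0-40 °C.
    """

    # curvature chosen so r stays positive over the whole 0-40 °C range
    # (r(0) ≈ 0.21, r(25) = 1.15 at the peak, r(40) ≈ 0.81)
    norm_r: ReactionNorm = field(
        default_factory=lambda: ReactionNorm(
            value_at_ref=1.0, form="quadratic-peak", peak_temperature=25.0,
            curvature=-0.0015,
        )
    )
    norm_K: ReactionNorm = field(default_factory=lambda: ReactionNorm(value_at_ref=10.0))
    valid_range: tuple[float, float] = (0.0, 40.0)

    def check_temperature(self, T: float) -> None:
        lo, hi = self.valid_range
        if not (lo <= T <= hi):
            raise OutOfRangeError(
                f"temperature {T} outside the environment's valid range [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class CRParams:
    """Consumer-resource parameter set at one temperature for one genotype."""

    r: float
    K: float
    a: float
    e: float
    m: float
    temperature: float | None = None
    genotype_id: str | None = None
    floored: bool = False

    def __post_init__(self) -> None:
        for name in ("r", "K", "a", "e", "m"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class Equilibrium:
    """Coexistence equilibrium; feasible iff the consumer can persist (C* > 0)."""

    R_star: float
    C_star: float
    feasible: bool


@dataclass(frozen=True)
class StabilityResult:
    """Jacobian eigenvalues at equilibrium and the derived resilience."""

    eigenvalues: tuple[complex, complex]
    lambda_max_real: float
    resilience: float
    stable: bool


@dataclass(frozen=True)
class InvasionResult:
    """Pairwise invasibility outcome for a genotype panel at one temperature."""

    genotype_ids: tuple[str, ...]
    fitness_matrix: np.ndarray  # s[i, j] = growth of invader j in resident i's equilibrium
    favoured_genotype: str
    neutral: bool
    R_stars: dict[str, float]


@dataclass(frozen=True)
class GxEDecomposition:
    """Two-way variance decomposition of one parameter on a genotype × T grid."""

    parameter: str
    V_G: float
    V_E: float
    V_GxE: float
    V_total: float


def params_at(
    genotype: Genotype,
    env: ResourceEnvironment,
    T: float,
    *,
    floor: float = PARAMETER_FLOOR,
) -> CRParams:
    """Assemble the five model parameters at temperature ``T``."""
    env.check_temperature(T)
    floored = False
    values = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ParameterFloorWarning)
        for name, norm in genotype.norms().items():
            values[name] = evaluate_norm(norm, T, floor=floor)
        values["r"] = evaluate_norm(env.norm_r, T, floor=floor)
        values["K"] = evaluate_norm(env.norm_K, T, floor=floor)
        floored = any(issubclass(w.category, ParameterFloorWarning) for w in caught)
    if floored:
        warnings.warn(
            f"one or more parameters floored at T={T} for genotype {genotype.id!r}",
            ParameterFloorWarning,
            stacklevel=2,
        )
    return CRParams(
        r=values["r"], K=values["K"], a=values["a"], e=values["e"], m=values["m"],
        temperature=T, genotype_id=genotype.id, floored=floored,
    )


def equilibrium(p: CRParams) -> Equilibrium:
    """Closed-form coexistence equilibrium R* = m/(ea), C* = (r/a)(1 − R*/K)."""
    R_star = p.m / (p.e * p.a)
    C_star = (p.r / p.a) * (1.0 - R_star / p.K)
    return Equilibrium(R_star=R_star, C_star=C_star, feasible=R_star < p.K)


def rhs(state: Sequence[float], p: CRParams) -> tuple[float, float]:
    """Right-hand side (dR/dt, dC/dt) of the consumer-resource system."""
    R, C = float(state[0]), float(state[1])
    if R < 0 or C < 0:
        raise InvalidStateError(f"densities must be nonnegative, got R={R}, C={C}")
    dR = R * (p.r - (p.r / p.K) * R - p.a * C)
    dC = C * (p.e * p.a * R - p.m)
    return dR, dC


def jacobian(p: CRParams, eq: Equilibrium | None = None) -> np.ndarray:
    """Analytic Jacobian of the system at the feasible coexistence equilibrium.

        J = [[ −r R*/K,  −a R* ],
             [ e a C*,       0 ]]

    The zero bottom-right entry reflects the consumer's per-capita growth
    depending only on resource density.
    """
    if eq is None:
        eq = equilibrium(p)
    if not eq.feasible:
        raise InfeasibleEquilibriumError(
            f"no feasible coexistence equilibrium: R*={eq.R_star:.4g} >= K={p.K:.4g}"
        )
    return np.array(
        [
            [-p.r * eq.R_star / p.K, -p.a * eq.R_star],
            [p.e * p.a * eq.C_star, 0.0],
        ]
    )


def stability(p: CRParams) -> StabilityResult:
    """Eigenvalues of the Jacobian at equilibrium; resilience = −max Re(λ)."""
    J = jacobian(p)
    eigs = np.linalg.eigvals(J)
    lam_max = float(np.max(eigs.real))
    return StabilityResult(
        eigenvalues=(complex(eigs[0]), complex(eigs[1])),
        lambda_max_real=lam_max,
        resilience=-lam_max,
        stable=lam_max < 0,
    )


def _resident_R_star(genotype: Genotype, env: ResourceEnvironment, T: float) -> float:
    p = params_at(genotype, env, T)
    return equilibrium(p).R_star


def invasion_fitness(
    resident: Genotype,
    invader: Genotype,
    env: ResourceEnvironment,
    T: float,
) -> float:
    """Per-capita growth rate of a rare invader at the resident's equilibrium.

    s = e' a' R*_res − m'.  Positive s means the invader spreads; the sign
    equals sign(R*_res − R*_inv), so lower-R* genotypes always invade.
    """
    p_res = params_at(resident, env, T)
    eq_res = equilibrium(p_res)
    if not eq_res.feasible:
        raise InfeasibleResidentError(
            f"resident {resident.id!r} has no feasible equilibrium at T={T}"
        )
    p_inv = params_at(invader, env, T)
    return p_inv.e * p_inv.a * eq_res.R_star - p_inv.m


def favoured_genotype(
    panel: Sequence[Genotype],
    env: ResourceEnvironment,
    T: float,
    *,
    neutrality_tol: float = NEUTRALITY_TOL,
) -> InvasionResult:
    """The genotype favoured by selection at temperature ``T``.

    Builds the full pairwise invasibility matrix among feasible panel
    members; the winner is the genotype uninvadable by every other,
    equivalently the argmin of R* = m/(ea).  Ties within
    ``neutrality_tol`` on R* set the neutral flag and resolve to the
    lexicographically smallest id for reproducibility.
    """
    feasible = []
    for g in panel:
        p = params_at(g, env, T)
        eq = equilibrium(p)
        if eq.feasible:
            feasible.append((g, p, eq))
    if not feasible:
        raise NoViableGenotypeError(f"no genotype in the panel is viable at T={T}")

    ids = tuple(g.id for g, _, _ in feasible)
    n = len(feasible)
    s = np.zeros((n, n))
    for i, (_, _, eq_i) in enumerate(feasible):
        for j, (_, p_j, _) in enumerate(feasible):
            s[i, j] = p_j.e * p_j.a * eq_i.R_star - p_j.m

    r_stars = {g.id: eq.R_star for g, _, eq in feasible}
    best = min(feasible, key=lambda t: (t[2].R_star, t[0].id))
    sorted_rs = sorted(r_stars.values())
    neutral = len(sorted_rs) > 1 and (sorted_rs[1] - sorted_rs[0]) < neutrality_tol
    return InvasionResult(
        genotype_ids=ids,
        fitness_matrix=s,
        favoured_genotype=best[0].id,
        neutral=neutral,
        R_stars=r_stars,
    )


def crossing_temperature(
    gA: Genotype,
    gB: Genotype,
    env: ResourceEnvironment,
    T_range: tuple[float, float],
    *,
    n_scan: int = 256,
    degenerate_tol: float = 1e-12,
) -> list[float]:
    """Temperatures where the two genotypes' R* curves cross.

    Scans ΔR*(T) = R*_A(T) − R*_B(T) on a grid, then refines each
    sign-change bracket with Brent's method.  Returns all roots sorted;
    an empty list means no crossing (including the degenerate case of
    identical genotypes, where ΔR* ≈ 0 everywhere and selection is
    neutral at all temperatures).
    """
    lo, hi = T_range
    env.check_temperature(lo)
    env.check_temperature(hi)
    Ts = np.linspace(lo, hi, n_scan)
    diff = np.array(
        [_resident_R_star(gA, env, t) - _resident_R_star(gB, env, t) for t in Ts]
    )
    if np.max(np.abs(diff)) < degenerate_tol:
        return []

    roots: list[float] = []
    f = lambda t: _resident_R_star(gA, env, t) - _resident_R_star(gB, env, t)
    for k in range(len(Ts) - 1):
        d0, d1 = diff[k], diff[k + 1]
        if d0 == 0.0 and abs(d1) > degenerate_tol:
            roots.append(float(Ts[k]))
        elif d0 * d1 < 0:
            roots.append(float(brentq(f, Ts[k], Ts[k + 1], xtol=1e-12)))
    if abs(diff[-1]) == 0.0 and abs(diff[-2]) > degenerate_tol:
        roots.append(float(Ts[-1]))
    return sorted(set(roots))


def temperature_sweep(
    panel: Sequence[Genotype],
    env: ResourceEnvironment,
    T_grid: Sequence[float],
) -> pd.DataFrame:
    """Equilibria, resilience and the favoured genotype across a temperature grid.

    One row per (temperature, genotype) with the evaluated parameters,
    the genotype's own resident equilibrium and resilience (matching the
    solid-vs-open presentation: each genotype assessed as if resident),
    and a flag marking the genotype favoured by selection at that
    temperature.  Infeasible cells carry NaN equilibrium/resilience and
    are never flagged favoured.
    """
    grid = list(T_grid)
    if not grid:
        raise ValueError("temperature grid must be nonempty")
    rows = []
    for T in grid:
        try:
            inv = favoured_genotype(panel, env, T)
            winner = inv.favoured_genotype
        except NoViableGenotypeError:
            winner = None
        for g in panel:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ParameterFloorWarning)
                p = params_at(g, env, T)
            eq = equilibrium(p)
            if eq.feasible:
                st = stability(p)
                lam, res = st.lambda_max_real, st.resilience
                R_s, C_s = eq.R_star, eq.C_star
            else:
                lam = res = R_s = C_s = np.nan
            rows.append(
                {
                    "T": T,
                    "genotype_id": g.id,
                    "a": p.a, "m": p.m, "e": p.e, "r": p.r, "K": p.K,
                    "R_star": R_s,
                    "C_star": C_s,
                    "lambda_max_real": lam,
                    "resilience": res,
                    "favoured_flag": bool(winner == g.id and eq.feasible),
                    "floored_flag": p.floored,
                }
            )
    return pd.DataFrame(rows)


def simulate_trajectory(
    p: CRParams | Callable[[float], CRParams],
    initial_state: Sequence[float],
    horizon: float,
    *,
    n_points: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate the consumer-resource dynamics from ``initial_state``.

    ``p`` may be a fixed parameter set or a callable t → CRParams
    encoding a temperature schedule.  Uses an adaptive explicit
    Runge-Kutta stepper; densities are clipped at zero inside the
    vector field so roundoff cannot push them negative.  Returns a
    DataFrame with columns t, R, C.
    """
    R0, C0 = float(initial_state[0]), float(initial_state[1])
    if R0 < 0 or C0 < 0:
        raise InvalidStateError(f"initial densities must be nonnegative, got ({R0}, {C0})")
    get_params = p if callable(p) else (lambda t: p)

    def field(t: float, y: np.ndarray) -> list[float]:
        R, C = max(y[0], 0.0), max(y[1], 0.0)
        return list(rhs((R, C), get_params(t)))

    sol = solve_ivp(
        field,
        (0.0, horizon),
        [R0, C0],
        method="RK45",
        t_eval=np.linspace(0.0, horizon, n_points),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalFailureError(f"ODE integration failed: {sol.message}")
    return pd.DataFrame(
        {"t": sol.t, "R": np.maximum(sol.y[0], 0.0), "C": np.maximum(sol.y[1], 0.0)}
    )


def decompose_variance(
    panel: Sequence[Genotype],
    T_grid: Sequence[float],
    parameter: str,
) -> GxEDecomposition:
    """Two-way G / E / G×E variance decomposition of one parameter.

    Evaluates the named parameter's reaction norm (un-floored) for every
    genotype at every temperature and partitions the population variance
    of the complete grid:

        V_G   = Var over genotypes of the genotype means,
        V_E   = Var over temperatures of the temperature means,
        V_GxE = Var of interaction residuals
                (cell − genotype mean − temperature mean + grand mean).

    On a balanced grid these are orthogonal, so V_G + V_E + V_GxE equals
    the total population variance of the cells exactly.
    """
    if parameter not in ("a", "m", "e"):
        raise ValueError(f"parameter must be one of 'a', 'm', 'e'; got {parameter!r}")
    if len(panel) < 2 or len(T_grid) < 2:
        raise InsufficientDesignError(
            f"need >= 2 genotypes and >= 2 temperatures, "
            f"got {len(panel)} x {len(T_grid)}"
        )
    Ts = np.asarray(list(T_grid), dtype=float)
    cells = np.array([[float(g.norms()[parameter].raw(t)) for t in Ts] for g in panel])

    grand = cells.mean()
    g_means = cells.mean(axis=1)
    t_means = cells.mean(axis=0)
    resid = cells - g_means[:, None] - t_means[None, :] + grand

    V_G = float(np.mean((g_means - grand) ** 2))
    V_E = float(np.mean((t_means - grand) ** 2))
    V_GxE = float(np.mean(resid**2))
    V_total = float(np.mean((cells - grand) ** 2))
    return GxEDecomposition(
        parameter=parameter, V_G=V_G, V_E=V_E, V_GxE=V_GxE, V_total=V_total
    )
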