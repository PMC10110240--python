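"""Rate laws and closed-form steady-state theory of the simple allocation model.

The simple model partitions protein synthesis between ribosomal, metabolic
and "other" sectors with fixed allocation fractions. Under saturating
nutrients its steady state is fully analytic: the growth rate is the
positive root of a quadratic, and the stationary precursor abundance
follows from flux balance. Three regulatory scenarios are expressed on top
of this theory: fixed allocation (I), allocation holding the precursor
concentration - and hence the translation rate - constant (II), and
allocation maximizing the steady-state growth rate (III).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DomainError, InfeasibleSteadyStateError
from .params import AllocationTriple, SimpleKinetics, SteadyStateSolution

__all__ = [
    "translation_rate",
    "metabolic_rate_nutrient",
    "steady_state_growth_rate",
    "steady_state_precursor",
    "solve_steady_state",
    "scenario_II_allocation",
    "scenario_II_allocation_approx",
    "scenario_III_allocation",
    "optimal_allocation_bruteforce",
]

#: |1 - Km_cpc| below which the quadratic is treated as degenerate and the
#: analytic linear-limit root is used instead (the root is continuous there).
_KM_ONE_TOL = 1e-9


def translation_rate(c_pc: float, gamma_max: float, Km_cpc: float) -> float:
    """Translation rate ``gamma(c_pc)``, 1/hr.

    Michaelis-Menten in the precursor abundance: ribosomes translate at
    ``gamma_max * c_pc / (c_pc + Km_cpc)``, saturating at ``gamma_max``.
    """
    if c_pc < 0:
        raise DomainError(f"c_pc must be nonnegative, got {c_pc!r}")
    if gamma_max <= 0 or Km_cpc <= 0:
        raise DomainError("gamma_max and Km_cpc must be strictly positive")
    return gamma_max * c_pc / (c_pc + Km_cpc)


def metabolic_rate_nutrient(c_nt: float, nu_max: float, Km_cnt: float) -> float:
    """Metabolic rate ``nu(c_nt)``, 1/hr, Monod in the nutrient concentration."""
    if c_nt < 0:
        raise DomainError(f"c_nt must be nonnegative, got {c_nt!r}")
    if nu_max <= 0 or Km_cnt <= 0:
        raise DomainError("nu_max and Km_cnt must be strictly positive")
    return nu_max * c_nt / (c_nt + Km_cnt)


def steady_state_growth_rate(
    phi_Rb: float, phi_O: float, kinetics: SimpleKinetics
) -> float:
    """Steady-state growth rate (1/hr) at fixed allocation, saturating nutrients.

    With maximal metabolic output ``N = nu_max * (1 - phi_Rb - phi_O)`` and
    maximal translational output ``Gamma = gamma_max * phi_Rb``, the growth
    rate is the positive root of

        (1 - Km) lambda^2 - (N + Gamma) lambda + N Gamma = 0,

    i.e. ``lambda = (N + Gamma - sqrt((N + Gamma)^2 - 4 (1 - Km) N Gamma))
    / (2 (1 - Km))``.  At ``Km_cpc = 1`` the quadratic degenerates and the
    root continuously approaches the harmonic-mean form
    ``lambda = N Gamma / (N + Gamma)``.
    """
    if phi_Rb < 0 or phi_O < 0:
        raise DomainError("allocation fractions must be nonnegative")
    if phi_Rb + phi_O > 1 + 1e-12:
        raise DomainError(
            f"phi_Rb + phi_O must not exceed 1, got {phi_Rb + phi_O!r}"
        )
    N = kinetics.nu_max * max(1.0 - phi_Rb - phi_O, 0.0)
    Gamma = kinetics.gamma_max * phi_Rb
    if N <= 0.0 or Gamma <= 0.0:
        return 0.0
    one_minus_km = 1.0 - kinetics.Km_cpc
    if abs(one_minus_km) < _KM_ONE_TOL:
        return N * Gamma / (N + Gamma)
    disc = (N + Gamma) ** 2 - 4.0 * one_minus_km * N * Gamma
    return (N + Gamma - math.sqrt(disc)) / (2.0 * one_minus_km)


def steady_state_precursor(
    growth_rate: float, phi_Mb: float, nu_max: float
) -> float:
    """Stationary precursor abundance ``c_pc* = nu_max * phi_Mb / lambda - 1``.

    Raises
    ------
    DomainError
        If ``growth_rate <= 0``.
    InfeasibleSteadyStateError
        If the result is negative: the metabolic flux cannot sustain the
        dilution and consumption at this growth rate, so no self-consistent
        steady state exists.
    """
    if growth_rate <= 0:
        raise DomainError(f"growth_rate must be positive, got {growth_rate!r}")
    c_pc = nu_max * phi_Mb / growth_rate - 1.0
    if c_pc < 0:
        raise InfeasibleSteadyStateError(
            "no steady state: nu_max * phi_Mb "
            f"({nu_max * phi_Mb!r}) < growth rate ({growth_rate!r})"
        )
    return c_pc


def solve_steady_state(
    phi_Rb: float,
    phi_O: float,
    kinetics: SimpleKinetics,
    scenario: str = "I",
) -> SteadyStateSolution:
    """Full analytic steady state (growth rate, precursor, translation rate)."""
    lam = steady_state_growth_rate(phi_Rb, phi_O, kinetics)
    allocation = AllocationTriple.from_ribosomal(phi_Rb, phi_O)
    if lam == 0.0:
        return SteadyStateSolution(
            growth_rate=0.0,
            c_pc_star=0.0,
            gamma_value=0.0,
            realized_allocation=allocation,
            scenario=scenario,
        )
    c_pc = steady_state_precursor(lam, allocation.phi_Mb, kinetics.nu_max)
    gamma = lam / phi_Rb
    return SteadyStateSolution(
        growth_rate=lam,
        c_pc_star=c_pc,
        gamma_value=gamma,
        realized_allocation=allocation,
        scenario=scenario,
    )


def scenario_II_allocation(
    c_pc_star: float, phi_O: float, kinetics: SimpleKinetics
) -> float:
    """Ribosomal allocation holding the precursor pool at ``c_pc_star``.

    Exact form: ``phi_Rb = (1 - phi_O) * nu (c* + Km) /
    [nu (c* + Km) + gamma_max c* (c* + 1)]`` with ``nu = nu_max``. Keeping
    ``c*`` fixed across conditions keeps the translation rate fixed.
    """
    if c_pc_star <= 0:
        raise DomainError(f"c_pc_star must be positive, got {c_pc_star!r}")
    if not 0 <= phi_O <= 1:
        raise DomainError(f"phi_O must lie in [0, 1], got {phi_O!r}")
    nu, g, Km = kinetics.nu_max, kinetics.gamma_max, kinetics.Km_cpc
    num = nu * (c_pc_star + Km)
    den = num + g * c_pc_star * (c_pc_star + 1.0)
    return (1.0 - phi_O) * num / den


def scenario_II_allocation_approx(
    c_pc_star: float, phi_O: float, kinetics: SimpleKinetics
) -> float:
    """Large-``c*`` approximation of :func:`scenario_II_allocation`.

    Valid when ``c* >> Km_cpc``:
    ``phi_Rb ~ (1 - phi_O) nu_max / (gamma_max (c* + 1) + nu_max)``.
    """
    if c_pc_star <= 0:
        raise DomainError(f"c_pc_star must be positive, got {c_pc_star!r}")
    nu, g = kinetics.nu_max, kinetics.gamma_max
    return (1.0 - phi_O) * nu / (g * (c_pc_star + 1.0) + nu)


def scenario_III_allocation(phi_O: float, kinetics: SimpleKinetics) -> float:
    """Growth-rate-optimal ribosomal allocation (scenario III).

    Closed form (argmax of the steady-state quadratic root; the square root
    spans only ``Km * gamma_max * nu_max``):

        phi_Rb = (1 - phi_O) * [nu (gamma + nu - 2 Km gamma)
                  + (gamma - nu) sqrt(Km gamma nu)]
                 / [(gamma + nu)^2 - 4 Km gamma nu]

    The expression degenerates (0/0) only for ``gamma_max = nu_max`` with
    ``Km_cpc = 1``; there, and as a safety net whenever the closed form
    falls outside the feasible range, a bounded numerical maximization of
    :func:`steady_state_growth_rate` is used instead.
    """
    if phi_O < 0 or phi_O > 1:
        raise DomainError(f"phi_O must lie in [0, 1], got {phi_O!r}")
    if phi_O == 1.0:
        return 0.0
    g, nu, Km = kinetics.gamma_max, kinetics.nu_max, kinetics.Km_cpc
    den = (g + nu) ** 2 - 4.0 * Km * g * nu
    if den > 1e-12 * (g + nu) ** 2:
        num = nu * (g + nu - 2.0 * Km * g) + (g - nu) * math.sqrt(Km * g * nu)
        phi = (1.0 - phi_O) * num / den
        if 0.0 <= phi <= 1.0 - phi_O:
            return phi
    # Degenerate or out-of-range: maximize the growth-rate root directly.
    res = minimize_scalar(
        lambda p: -steady_state_growth_rate(p, phi_O, kinetics),
        bounds=(0.0, 1.0 - phi_O),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def optimal_allocation_bruteforce(
    phi_O: float, kinetics: SimpleKinetics, grid_size: int = 2000
) -> float:
    """Brute-force argmax of the steady-state growth rate over ``phi_Rb``.

    Dense grid scan over ``[0, 1 - phi_O]`` followed by a bounded local
    refinement inside the bracketing grid cells. Serves as the independent
    oracle for :func:`scenario_III_allocation`.
    """
    if grid_size < 1000:
        raise DomainError(f"grid_size must be >= 1000, got {grid_size!r}")
    upper = 1.0 - phi_O
    if upper <= 0:
        return 0.0
    grid = np.linspace(0.0, upper, grid_size + 1)
    lams = np.array(
        [steady_state_growth_rate(p, phi_O, kinetics) for p in grid]
    )
    i = int(np.argmax(lams))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size)]
    if hi <= lo:
        return float(grid[i])
    res = minimize_scalar(
        lambda p: -steady_state_growth_rate(p, phi_O, kinetics),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)
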