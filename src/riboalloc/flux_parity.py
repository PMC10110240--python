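"""The flux-parity regulatory circuit.

The refined model resolves the lumped precursor pool into charged and
uncharged tRNA. Metabolism converts uncharged to charged tRNA; translation
consumes charged tRNA and returns uncharged tRNA; transcription tops up the
uncharged pool; growth dilutes both. The ratio of the two pools - the
charging balance ``B = tRNA_c / tRNA_u`` - is the internal signal: the
ribosomal allocation and the tRNA transcription rate both follow saturating
functions of ``B`` with half-point ``tau``. Mechanistically this is the
ppGpp circuit read in reverse: the alarmone concentration is taken to be
inversely proportional to ``B`` (ratiometric ansatz) or proportional to the
probability of a ribosome binding an uncharged tRNA (binding ansatz), and
only concentrations *relative* to a reference condition are ever reported.

Steady states of this circuit self-organize at the allocation that mutually
maximizes the metabolic flux (uncharged -> charged tRNA) and the
translational flux (charged tRNA -> protein), reproducing the growth-rate
optimal allocation of the simple model without any explicit optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .dynamics import (
    ATOL,
    CONSERVATION_TOL,
    NEGATIVE_CLIP,
    RTOL,
    Trajectory,
    check_nonnegative,
)
from .errors import (
    ChargingSingularityError,
    ConvergenceError,
    DomainError,
    IntegrationError,
)
from .params import AllocationTriple, FluxParityKinetics, SteadyStateSolution

__all__ = [
    "ExtraAllocation",
    "FluxParityState",
    "FluxPair",
    "PpGppPrediction",
    "FP_TRAJECTORY_COLUMNS",
    "fp_allocation",
    "fp_transcription_rate",
    "fp_translation_rate",
    "fp_metabolic_rate",
    "fp_rhs",
    "fp_simulate",
    "fp_steady_state",
    "fp_fixed_allocation_steady_state",
    "compute_fluxes",
    "ppgpp_relative",
    "find_reference_state",
    "steady_state_scan",
]

logger = logging.getLogger(__name__)

#: Floor applied to the uncharged-tRNA pool inside the integrator only,
#: to keep the charging balance finite; a hit is logged as a warning.
TRNA_FLOOR = 1e-12

FP_TRAJECTORY_COLUMNS = [
    "time_hr",
    "M",
    "M_Rb",
    "M_Mb",
    "M_O",
    "M_X",
    "tRNA_c",
    "tRNA_u",
    "c_nt",
    "phi_Rb",
    "phi_Mb",
    "inst_growth_rate_hr",
]


@dataclass(frozen=True)
class ExtraAllocation:
    """Optional extra proteome sectors.

    ``phi_X`` is a deliberately expressed excess sector (synthetic protein
    burden); ``phi_useless`` models conditionally useless expression that
    shrinks upon a nutrient upshift. Both divert synthesis away from the
    regulated ribosomal/metabolic split.
    """

    phi_X: float = 0.0
    phi_useless: float = 0.0

    def __post_init__(self) -> None:
        if self.phi_X < 0 or self.phi_useless < 0:
            raise DomainError("extra allocation fractions must be nonnegative")

    @property
    def total(self) -> float:
        return self.phi_X + self.phi_useless


@dataclass(frozen=True)
class FluxParityState:
    """Instantaneous state of the flux-parity circuit.

    ``M_X`` lumps the mass of any extra sectors (excess plus useless).
    The tRNA pools are relative mass abundances (one amino-acid equivalent
    per tRNA).
    """

    M: float
    M_Rb: float
    M_Mb: float
    M_O: float
    tRNA_c: float
    tRNA_u: float
    c_nt: float = 0.0
    M_X: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.M,
                self.M_Rb,
                self.M_Mb,
                self.M_O,
                self.M_X,
                self.tRNA_c,
                self.tRNA_u,
                self.c_nt,
            ]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "FluxParityState":
        M, M_Rb, M_Mb, M_O, M_X, tc, tu, c_nt = map(float, y)
        return cls(
            M=M,
            M_Rb=M_Rb,
            M_Mb=M_Mb,
            M_O=M_O,
            tRNA_c=tc,
            tRNA_u=tu,
            c_nt=c_nt,
            M_X=M_X,
        )

    @property
    def charging_balance(self) -> float:
        if self.tRNA_u <= 0:
            raise ChargingSingularityError(
                "charging balance undefined: uncharged-tRNA pool is zero"
            )
        return self.tRNA_c / self.tRNA_u


@dataclass(frozen=True)
class FluxPair:
    """Metabolic and translational fluxes (per total biomass, 1/hr)."""

    J_Mb: float
    J_Tl: float

    def __post_init__(self) -> None:
        if self.J_Mb < 0 or self.J_Tl < 0:
            raise DomainError("fluxes must be nonnegative")


@dataclass(frozen=True)
class PpGppPrediction:
    """Relative alarmone concentration (query state over reference state)."""

    relative_concentration: float
    ansatz: str

    def __post_init__(self) -> None:
        if self.ansatz not in ("ratiometric", "binding"):
            raise DomainError(f"unknown ppGpp ansatz {self.ansatz!r}")
        if self.relative_concentration <= 0:
            raise DomainError("relative ppGpp concentration must be positive")


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def fp_allocation(
    charging_balance: float, phi_O: float, tau: float
) -> float:
    """Ribosomal allocation ``(1 - phi_O) B / (B + tau)``.

    Monotone increasing in the charging balance with supremum ``1 - phi_O``
    and half-maximum at ``B = tau``. Callers with extra sectors pass the
    total unregulated fraction (phi_O + phi_X + phi_useless) as ``phi_O``.
    """
    if charging_balance < 0:
        raise DomainError("charging balance must be nonnegative")
    if tau <= 0:
        raise DomainError("tau must be strictly positive")
    return (1.0 - phi_O) * charging_balance / (charging_balance + tau)


def fp_transcription_rate(
    charging_balance: float, kappa_max: float, tau: float
) -> float:
    """tRNA transcription rate ``kappa_max B / (B + tau)``, rel. abundance/hr."""
    if charging_balance < 0:
        raise DomainError("charging balance must be nonnegative")
    if kappa_max <= 0 or tau <= 0:
        raise DomainError("kappa_max and tau must be strictly positive")
    return kappa_max * charging_balance / (charging_balance + tau)


def fp_translation_rate(
    tRNA_c: float, gamma_max: float, Km_tRNAc: float
) -> float:
    """Translation rate as a Michaelis-Menten function of charged tRNA."""
    if tRNA_c < 0:
        raise DomainError("tRNA_c must be nonnegative")
    if gamma_max <= 0 or Km_tRNAc <= 0:
        raise DomainError("gamma_max and Km_tRNAc must be strictly positive")
    return gamma_max * tRNA_c / (tRNA_c + Km_tRNAc)


def fp_metabolic_rate(
    tRNA_u: float,
    nu_max: float,
    Km_tRNAu: float,
    c_nt: float | None = None,
    Km_cnt: float | None = None,
) -> float:
    """Metabolic rate as a function of uncharged tRNA (and optionally nutrients).

    With nutrient coupling enabled the two saturating factors multiply:
    ``nu_max * tRNA_u/(tRNA_u + Km) * c_nt/(c_nt + Km_cnt)``.
    """
    if tRNA_u < 0:
        raise DomainError("tRNA_u must be nonnegative")
    if nu_max <= 0 or Km_tRNAu <= 0:
        raise DomainError("nu_max and Km_tRNAu must be strictly positive")
    rate = nu_max * tRNA_u / (tRNA_u + Km_tRNAu)
    if c_nt is not None:
        if Km_cnt is None or Km_cnt <= 0:
            raise DomainError("Km_cnt must be strictly positive")
        if c_nt < 0:
            raise DomainError("c_nt must be nonnegative")
        rate *= c_nt / (c_nt + Km_cnt)
    return rate


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def fp_rhs(
    state: FluxParityState,
    kinetics: FluxParityKinetics,
    extra_allocation: ExtraAllocation | None = None,
    active_fraction: float = 1.0,
    nutrients_saturating: bool = True,
    fixed_phi_Rb: float | None = None,
    fixed_kappa: float | None = None,
) -> FluxParityState:
    """Time derivative of the flux-parity state.

    ``active_fraction`` scales every term in which translating ribosomes
    appear (antibiotic action). ``fixed_phi_Rb`` and ``fixed_kappa`` pin
    the ribosomal allocation and the tRNA transcription rate, decoupling
    them from the charging balance (stepwise-reallocation mode, where
    regulation reads only the environment, not the internal fluxes).
    """
    extra = extra_allocation or ExtraAllocation()
    if kinetics.phi_O + extra.total > 1 + 1e-12:
        raise DomainError("phi_O plus extra sectors exceeds 1")
    if state.M <= 0:
        raise DomainError("total biomass M must be positive")
    if state.tRNA_u <= 0:
        if state.tRNA_c > 0:
            raise ChargingSingularityError(
                "uncharged-tRNA pool is zero while charged pool is not"
            )
        B = 0.0
    else:
        B = max(state.tRNA_c, 0.0) / state.tRNA_u
    unregulated = kinetics.phi_O + extra.total
    if fixed_phi_Rb is None:
        phi_Rb = fp_allocation(B, unregulated, kinetics.tau)
    else:
        phi_Rb = fixed_phi_Rb
    phi_Mb = 1.0 - unregulated - phi_Rb
    if phi_Mb < -1e-12:
        raise DomainError("allocation fractions exceed 1")
    phi_Mb = max(phi_Mb, 0.0)
    gamma = fp_translation_rate(
        max(state.tRNA_c, 0.0), kinetics.gamma_max, kinetics.Km_tRNAc
    )
    if nutrients_saturating:
        nu = fp_metabolic_rate(
            max(state.tRNA_u, 0.0), kinetics.nu_max, kinetics.Km_tRNAu
        )
        dc_nt = 0.0
    else:
        nu = fp_metabolic_rate(
            max(state.tRNA_u, 0.0),
            kinetics.nu_max,
            kinetics.Km_tRNAu,
            c_nt=max(state.c_nt, 0.0),
            Km_cnt=kinetics.Km_cnt,
        )
        dc_nt = -nu * state.M_Mb / kinetics.Y
    if fixed_kappa is None:
        kappa = fp_transcription_rate(B, kinetics.kappa_max, kinetics.tau)
    else:
        kappa = fixed_kappa
    translating = active_fraction * gamma * state.M_Rb
    dM = translating
    per_mass = translating / state.M
    metab = nu * state.M_Mb / state.M
    d_tc = metab - per_mass - state.tRNA_c * per_mass
    d_tu = kappa + per_mass - metab - state.tRNA_u * per_mass
    return FluxParityState(
        M=dM,
        M_Rb=phi_Rb * dM,
        M_Mb=phi_Mb * dM,
        M_O=kinetics.phi_O * dM,
        tRNA_c=d_tc,
        tRNA_u=d_tu,
        c_nt=dc_nt,
        M_X=extra.total * dM,
    )


def _vector_rhs(
    kinetics,
    extra,
    active_fraction,
    nutrients_saturating,
    fixed_phi_Rb,
    fixed_kappa=None,
):
    floor_hit = [False]

    def rhs(t, y):
        y = np.maximum(y, NEGATIVE_CLIP)
        if y[6] < TRNA_FLOOR:
            if not floor_hit[0]:
                logger.warning(
                    "uncharged-tRNA pool hit the %.0e floor during "
                    "integration",
                    TRNA_FLOOR,
                )
                floor_hit[0] = True
            y = y.copy()
            y[6] = TRNA_FLOOR
        state = FluxParityState.from_array(y)
        d = fp_rhs(
            state,
            kinetics,
            extra_allocation=extra,
            active_fraction=active_fraction,
            nutrients_saturating=nutrients_saturating,
            fixed_phi_Rb=fixed_phi_Rb,
            fixed_kappa=fixed_kappa,
        )
        return d.as_array()

    return rhs


def default_initial_state(
    kinetics: FluxParityKinetics,
    extra_allocation: ExtraAllocation | None = None,
    c_nt0: float = 0.0,
) -> FluxParityState:
    """M(0)=1 with sectors at the allocations implied by a balanced
    charging ratio (B = tau) and tRNA pools at a physiological scale."""
    extra = extra_allocation or ExtraAllocation()
    unregulated = kinetics.phi_O + extra.total
    phi_Rb = fp_allocation(kinetics.tau, unregulated, kinetics.tau)
    phi_Mb = 1.0 - unregulated - phi_Rb
    pool = max(kinetics.kappa_max / 2.0, 10.0 * kinetics.Km_tRNAc)
    return FluxParityState(
        M=1.0,
        M_Rb=phi_Rb,
        M_Mb=phi_Mb,
        M_O=kinetics.phi_O,
        tRNA_c=pool,
        tRNA_u=pool,
        c_nt=c_nt0,
        M_X=extra.total,
    )


def fp_simulate(
    kinetics: FluxParityKinetics,
    t_grid: np.ndarray,
    state0: FluxParityState | None = None,
    extra_allocation: ExtraAllocation | None = None,
    active_fraction: float = 1.0,
    nutrients_saturating: bool = True,
    fixed_phi_Rb: float | None = None,
    fixed_kappa: float | None = None,
) -> Trajectory:
    """Integrate the flux-parity circuit over ``t_grid``."""
    extra = extra_allocation or ExtraAllocation()
    if state0 is None:
        state0 = default_initial_state(kinetics, extra)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be a strictly increasing 1-D grid")
    rhs = _vector_rhs(
        kinetics,
        extra,
        active_fraction,
        nutrients_saturating,
        fixed_phi_Rb,
        fixed_kappa,
    )
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        state0.as_array(),
        t_eval=t_grid,
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    check_nonnegative(sol.y)
    y = np.maximum(sol.y, 0.0)
    M, M_Rb, M_Mb, M_O, M_X, tc, tu, c_nt = y
    resid = np.abs(M_Rb + M_Mb + M_O + M_X - M) / M
    if np.max(resid) > CONSERVATION_TOL:
        raise IntegrationError(
            f"sector-mass conservation violated (max residual "
            f"{np.max(resid):.3e})"
        )
    gamma = kinetics.gamma_max * tc / (tc + kinetics.Km_tRNAc)
    lam_i = active_fraction * gamma * M_Rb / M
    B = tc / np.maximum(tu, TRNA_FLOOR)
    unregulated = kinetics.phi_O + extra.total
    if fixed_phi_Rb is None:
        phi_Rb_t = (1.0 - unregulated) * B / (B + kinetics.tau)
    else:
        phi_Rb_t = np.full_like(B, fixed_phi_Rb)
    phi_Mb_t = 1.0 - unregulated - phi_Rb_t
    frame = pd.DataFrame(
        {
            "time_hr": sol.t,
            "M": M,
            "M_Rb": M_Rb,
            "M_Mb": M_Mb,
            "M_O": M_O,
            "M_X": M_X,
            "tRNA_c": tc,
            "tRNA_u": tu,
            "c_nt": c_nt,
            "phi_Rb": phi_Rb_t,
            "phi_Mb": phi_Mb_t,
            "inst_growth_rate_hr": lam_i,
        }
    )
    return Trajectory(frame=frame, model="flux_parity")


def final_fp_state(traj: Trajectory) -> FluxParityState:
    row = traj.frame.iloc[-1]
    return FluxParityState(
        M=row["M"],
        M_Rb=row["M_Rb"],
        M_Mb=row["M_Mb"],
        M_O=row["M_O"],
        tRNA_c=row["tRNA_c"],
        tRNA_u=row["tRNA_u"],
        c_nt=row["c_nt"],
        M_X=row["M_X"],
    )


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

def _stationarity_residuals(tc, tu, kinetics, extra, active_fraction,
                            fixed_phi_Rb=None):
    """Residuals of the two tRNA balance equations with mass fractions at
    their steady-state values (equal to the allocations)."""
    B = tc / tu
    unregulated = kinetics.phi_O + extra.total
    if fixed_phi_Rb is None:
        phi_Rb = fp_allocation(B, unregulated, kinetics.tau)
    else:
        phi_Rb = fixed_phi_Rb
    phi_Mb = 1.0 - unregulated - phi_Rb
    gamma = fp_translation_rate(tc, kinetics.gamma_max, kinetics.Km_tRNAc)
    nu = fp_metabolic_rate(tu, kinetics.nu_max, kinetics.Km_tRNAu)
    kappa = fp_transcription_rate(B, kinetics.kappa_max, kinetics.tau)
    lam = active_fraction * gamma * phi_Rb
    f_c = nu * phi_Mb - lam * (1.0 + tc)
    f_u = kappa + lam - nu * phi_Mb - tu * lam
    return f_c, f_u, lam, phi_Rb, phi_Mb, gamma


def fp_steady_state(
    kinetics: FluxParityKinetics,
    extra_allocation: ExtraAllocation | None = None,
    tol: float = 1e-6,
    active_fraction: float = 1.0,
    init: FluxParityState | None = None,
    t_max: float | None = None,
    fixed_phi_Rb: float | None = None,
) -> tuple[SteadyStateSolution, FluxParityState]:
    """Steady state of the flux-parity circuit under saturating nutrients.

    Integrates in 1-hour windows until the instantaneous growth rate
    settles, then polishes the stationary tRNA pools with a Newton solve of
    the two balance equations (in log coordinates, preserving positivity).
    The returned state is rescaled to ``M = 1`` with sector masses at the
    steady-state fractions, convenient as an initial condition for
    perturbation runs.
    """
    extra = extra_allocation or ExtraAllocation()
    if not 0 < active_fraction <= 1:
        raise DomainError("active_fraction must lie in (0, 1]")
    if init is None:
        init = default_initial_state(kinetics, extra)
    rhs = _vector_rhs(kinetics, extra, active_fraction, True, fixed_phi_Rb)
    if t_max is None:
        t_max = 500.0
    window = 1.0
    t = 0.0
    y = init.as_array()
    lam_prev = None
    converged = False
    while t < t_max:
        sol = solve_ivp(
            rhs, (t, t + window), y, method="LSODA", rtol=RTOL, atol=ATOL
        )
        if not sol.success:
            raise IntegrationError(f"integration failed: {sol.message}")
        y = sol.y[:, -1]
        t += window
        state = FluxParityState.from_array(np.maximum(y, 0.0))
        d = fp_rhs(
            state,
            kinetics,
            extra_allocation=extra,
            active_fraction=active_fraction,
            fixed_phi_Rb=fixed_phi_Rb,
        )
        lam = d.M / state.M
        if lam_prev is not None and lam > 0:
            if abs(lam - lam_prev) / lam < max(tol, 1e-9):
                converged = True
                break
        lam_prev = lam
    if not converged:
        raise ConvergenceError(
            f"flux-parity steady state not reached within {t_max:.0f} hr"
        )

    # The raw pool balances are nearly opposite near the fixed point
    # (their sum is the small transcription-dilution balance), so solve the
    # well-conditioned pair (charged balance, total-pool balance) in log
    # coordinates; residuals are judged relative to the gross turnovers.
    def equations(x):
        tc, tu = np.exp(x)
        f_c, f_u, *_ = _stationarity_residuals(
            tc, tu, kinetics, extra, active_fraction, fixed_phi_Rb
        )
        return [f_c, f_c + f_u]

    def scaled_residual(tc, tu):
        f_c, f_u, lam, phi_Rb, phi_Mb, gamma = _stationarity_residuals(
            tc, tu, kinetics, extra, active_fraction, fixed_phi_Rb
        )
        nu = fp_metabolic_rate(tu, kinetics.nu_max, kinetics.Km_tRNAu)
        kappa = fp_transcription_rate(
            tc / tu, kinetics.kappa_max, kinetics.tau
        )
        s_c = nu * phi_Mb + lam * (1.0 + tc)
        s_tot = kappa + lam * (tc + tu) + ATOL
        return max(abs(f_c) / s_c, abs(f_c + f_u) / s_tot)

    tc = max(state.tRNA_c, TRNA_FLOOR)
    tu = max(state.tRNA_u, TRNA_FLOOR)
    seeds = [
        np.log([tc, tu]),
        np.log([1e-4, 1e-4]),
        np.log([1e-3, 1e-3]),
        np.log([1e-2, 1e-3]),
    ]
    for x0 in seeds:
        res = root(equations, x0, method="hybr", tol=1e-13)
        if res.success and scaled_residual(*np.exp(res.x)) < tol:
            tc, tu = np.exp(res.x)
            break
    else:
        resid = scaled_residual(tc, tu)
        if resid > tol:
            raise ConvergenceError(
                "tRNA pools not stationary at claimed steady state "
                f"(scaled residual {resid:.2e})"
            )
    f_c, f_u, lam, phi_Rb, phi_Mb, gamma = _stationarity_residuals(
        tc, tu, kinetics, extra, active_fraction, fixed_phi_Rb
    )
    realized = AllocationTriple(
        phi_Rb=phi_Rb,
        phi_Mb=phi_Mb,
        phi_O=1.0 - phi_Rb - phi_Mb,
    )
    solution = SteadyStateSolution(
        growth_rate=lam,
        c_pc_star=tc,
        gamma_value=active_fraction * gamma,
        realized_allocation=realized,
        scenario="flux_parity",
    )
    final = FluxParityState(
        M=1.0,
        M_Rb=phi_Rb,
        M_Mb=phi_Mb,
        M_O=kinetics.phi_O,
        tRNA_c=tc,
        tRNA_u=tu,
        c_nt=0.0,
        M_X=extra.total,
    )
    return solution, final


def fp_fixed_allocation_steady_state(
    phi_Rb: float,
    kinetics: FluxParityKinetics,
    extra_allocation: ExtraAllocation | None = None,
    tol: float = 1e-6,
    active_fraction: float = 1.0,
) -> tuple[SteadyStateSolution, FluxParityState]:
    """Steady state with the ribosomal allocation frozen at ``phi_Rb``.

    The tRNA pools and the transcription control remain dynamic; only the
    allocation is decoupled from the charging balance. Used to probe the
    mutual-maximization property and for stepwise-reallocation comparisons.
    """
    extra = extra_allocation or ExtraAllocation()
    if not 0 <= phi_Rb <= 1 - kinetics.phi_O - extra.total:
        raise DomainError("phi_Rb outside the feasible range")
    return fp_steady_state(
        kinetics,
        extra_allocation=extra,
        tol=tol,
        active_fraction=active_fraction,
        fixed_phi_Rb=phi_Rb,
    )


# ---------------------------------------------------------------------------
# Fluxes and ppGpp
# ---------------------------------------------------------------------------

def compute_fluxes(
    state: FluxParityState, kinetics: FluxParityKinetics
) -> FluxPair:
    """Metabolic and translational fluxes of a state (per total biomass).

    ``J_Mb = nu(tRNA_u) M_Mb / M`` and ``J_Tl = gamma(tRNA_c) M_Rb / M``;
    at steady state ``J_Tl`` equals the growth rate.
    """
    nu = fp_metabolic_rate(state.tRNA_u, kinetics.nu_max, kinetics.Km_tRNAu)
    gamma = fp_translation_rate(
        state.tRNA_c, kinetics.gamma_max, kinetics.Km_tRNAc
    )
    return FluxPair(
        J_Mb=nu * state.M_Mb / state.M,
        J_Tl=gamma * state.M_Rb / state.M,
    )


def ppgpp_relative(
    state: FluxParityState,
    reference_state: FluxParityState,
    ansatz: str = "ratiometric",
) -> PpGppPrediction:
    """Relative ppGpp concentration of ``state`` versus ``reference_state``.

    ratiometric : ``B_0 / B`` (alarmone inversely proportional to the
        charging balance).
    binding : ``(1 + B_0) / (1 + B)`` (alarmone proportional to the
        probability of a ribosome binding an uncharged tRNA).
    """
    B = state.charging_balance
    B0 = reference_state.charging_balance
    if ansatz == "ratiometric":
        rel = B0 / B
    elif ansatz == "binding":
        rel = (1.0 + B0) / (1.0 + B)
    else:
        raise DomainError(f"unknown ppGpp ansatz {ansatz!r}")
    return PpGppPrediction(relative_concentration=rel, ansatz=ansatz)


def find_reference_state(
    kinetics: FluxParityKinetics,
    lambda0: float = 1.0,
    nu_bounds: tuple[float, float] = (0.05, 80.0),
) -> tuple[FluxParityKinetics, SteadyStateSolution, FluxParityState]:
    """Find the ``nu_max`` whose steady-state growth rate equals ``lambda0``.

    Root-bracketing (Brent) on the steady-state growth rate as a function
    of ``nu_max``; all other parameters are taken from ``kinetics``.
    """

    def gap(nu):
        sol, _ = fp_steady_state(kinetics.with_nu_max(nu))
        return sol.growth_rate - lambda0

    lo, hi = nu_bounds
    nu_ref = brentq(gap, lo, hi, xtol=1e-8)
    ref_kin = kinetics.with_nu_max(nu_ref)
    sol, st = fp_steady_state(ref_kin)
    return ref_kin, sol, st


def steady_state_scan(
    nu_max_grid: np.ndarray,
    kinetics: FluxParityKinetics,
    extra_allocation: ExtraAllocation | None = None,
    reference_state: FluxParityState | None = None,
) -> pd.DataFrame:
    """Steady-state properties over a grid of metabolic rates.

    Columns: nu_max_hr, growth_rate_hr, phi_Rb, translation_speed_aa_s,
    tRNA_c, tRNA_u, charging_balance, rel_ppGpp_ratiometric,
    rel_ppGpp_binding. The ppGpp columns are normalized to
    ``reference_state`` (found at growth rate ~1/hr if not supplied).
    """
    if reference_state is None:
        _, _, reference_state = find_reference_state(kinetics)
    rows = []
    prev_state = None
    for nu in np.asarray(nu_max_grid, dtype=float):
        sol, st = fp_steady_state(
            kinetics.with_nu_max(nu),
            extra_allocation=extra_allocation,
            init=prev_state,
        )
        prev_state = st
        speed = sol.gamma_value * kinetics.m_Rb / 3600.0
        rows.append(
            {
                "nu_max_hr": nu,
                "growth_rate_hr": sol.growth_rate,
                "phi_Rb": sol.realized_allocation.phi_Rb,
                "translation_speed_aa_s": speed,
                "tRNA_c": st.tRNA_c,
                "tRNA_u": st.tRNA_u,
                "charging_balance": st.charging_balance,
                "rel_ppGpp_ratiometric": ppgpp_relative(
                    st, reference_state, "ratiometric"
                ).relative_concentration,
                "rel_ppGpp_binding": ppgpp_relative(
                    st, reference_state, "binding"
                ).relative_concentration,
            }
        )
    return pd.DataFrame(rows)
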