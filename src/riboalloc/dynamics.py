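"""ODE dynamics of the simple allocation model.

Integrates the mass-flow system: biomass grows at ``dM/dt = gamma(c_pc) *
M_Rb``, new synthesis is partitioned between sectors by the allocation
fractions, the precursor pool balances metabolic production against
consumption by translation and dilution by growth, and (in batch culture)
the external nutrient is depleted according to the yield coefficient.

All runs are deterministic; the integrator is stiff-capable (LSODA) with
tight tolerances so that numerically found steady states can be compared
with the analytic theory at the 1e-5 level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import allocation_core as core
from .errors import ConvergenceError, DomainError, IntegrationError
from .params import AllocationTriple, SimpleKinetics, SteadyStateSolution

__all__ = [
    "SimpleState",
    "Trajectory",
    "SIMPLE_TRAJECTORY_COLUMNS",
    "simple_model_rhs",
    "integrate_trajectory",
    "simulate",
    "default_initial_state",
    "find_steady_state",
    "batch_culture_simulate",
]

RTOL = 1e-8
ATOL = 1e-10
#: Relative residual of (sum of sector masses - M) tolerated along trajectories.
CONSERVATION_TOL = 1e-6
#: States are clipped at this level for rate evaluation only; excursions
#: below -1e-8 (relative to each variable's scale) abort the integration,
#: distinguishing model error from accumulated solver round-off (the
#: dense-output interpolation can undershoot zero by a few times atol
#: when a pool collapses).
NEGATIVE_CLIP = -1e-12
NEGATIVE_ABORT = -1e-8


def check_nonnegative(y: np.ndarray) -> None:
    """Abort if any state variable dips below round-off scale.

    ``y`` has shape (n_vars, n_times); the tolerance for each variable is
    ``NEGATIVE_ABORT`` scaled by its own magnitude (at least 1).
    """
    scale = np.maximum(1.0, np.max(np.abs(y), axis=1))
    worst = np.min(y / scale[:, None])
    if worst < NEGATIVE_ABORT:
        raise IntegrationError(
            f"state went negative beyond round-off (scaled min {worst:.3e})"
        )

SIMPLE_TRAJECTORY_COLUMNS = [
    "time_hr",
    "M",
    "M_Rb",
    "M_Mb",
    "M_O",
    "c_pc",
    "c_nt",
    "inst_growth_rate_hr",
]


@dataclass(frozen=True)
class SimpleState:
    """Instantaneous state of the simple model.

    Masses are in normalized amino-acid units (``M`` is the total protein
    biomass, sectors should sum to it); ``c_pc`` is the precursor relative
    abundance and ``c_nt`` the external nutrient concentration in mM.
    """

    M: float
    M_Rb: float
    M_Mb: float
    M_O: float
    c_pc: float
    c_nt: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.M, self.M_Rb, self.M_Mb, self.M_O, self.c_pc, self.c_nt]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SimpleState":
        return cls(*map(float, y))


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped state series with the instantaneous growth rate.

    ``frame`` holds one row per sample with a leading ``time_hr`` column,
    the state variables, and a trailing ``inst_growth_rate_hr`` column
    (``lambda_i = (dM/dt)/M`` evaluated from the rate laws, not by finite
    differences).
    """

    frame: pd.DataFrame
    model: str = "simple"

    def __post_init__(self) -> None:
        t = self.frame["time_hr"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise DomainError("trajectory times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_hr"].to_numpy()

    @property
    def inst_growth_rate(self) -> np.ndarray:
        return self.frame["inst_growth_rate_hr"].to_numpy()

    def final_state(self) -> SimpleState:
        row = self.frame.iloc[-1]
        return SimpleState(
            M=row["M"],
            M_Rb=row["M_Rb"],
            M_Mb=row["M_Mb"],
            M_O=row["M_O"],
            c_pc=row.get("c_pc", 0.0),
            c_nt=row.get("c_nt", 0.0),
        )


def simple_model_rhs(
    state: SimpleState,
    allocation: AllocationTriple,
    kinetics: SimpleKinetics,
    nutrients_saturating: bool = True,
    _include_dilution: bool = True,
) -> SimpleState:
    """Time derivative of the simple-model state.

    ``_include_dilution`` exists solely as a regression hook: dropping the
    dilution term removes the precursor steady state, and a test documents
    that failure mode.
    """
    if state.M <= 0:
        raise DomainError("total biomass M must be positive")
    gamma = core.translation_rate(
        max(state.c_pc, 0.0), kinetics.gamma_max, kinetics.Km_cpc
    )
    if nutrients_saturating:
        nu = kinetics.nu_max
        dc_nt = 0.0
    else:
        nu = core.metabolic_rate_nutrient(
            max(state.c_nt, 0.0), kinetics.nu_max, kinetics.Km_cnt
        )
        dc_nt = -nu * state.M_Mb / kinetics.Y
    dM = gamma * state.M_Rb
    ribo_per_mass = gamma * state.M_Rb / state.M
    dc_pc = nu * state.M_Mb / state.M - ribo_per_mass
    if _include_dilution:
        dc_pc -= state.c_pc * ribo_per_mass
    return SimpleState(
        M=dM,
        M_Rb=allocation.phi_Rb * dM,
        M_Mb=allocation.phi_Mb * dM,
        M_O=allocation.phi_O * dM,
        c_pc=dc_pc,
        c_nt=dc_nt,
    )


def _vector_rhs(allocation, kinetics, nutrients_saturating, include_dilution):
    def rhs(t, y):
        state = SimpleState.from_array(np.maximum(y, NEGATIVE_CLIP))
        d = simple_model_rhs(
            state,
            allocation,
            kinetics,
            nutrients_saturating=nutrients_saturating,
            _include_dilution=include_dilution,
        )
        return d.as_array()

    return rhs


def integrate_trajectory(
    rhs,
    state0: SimpleState,
    kinetics: SimpleKinetics,
    t_grid: np.ndarray,
    check_conservation: bool = True,
) -> Trajectory:
    """Integrate a simple-model right-hand side over ``t_grid``.

    ``rhs`` has the ``solve_ivp`` signature ``rhs(t, y)`` over the packed
    state ``[M, M_Rb, M_Mb, M_O, c_pc, c_nt]``. The instantaneous growth
    rate is recorded at every sample, mass conservation is verified to
    :data:`CONSERVATION_TOL`, and excursions below ``-1e-9`` abort.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be a strictly increasing 1-D grid")
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
    M, M_Rb, M_Mb, M_O, c_pc, c_nt = y
    if check_conservation:
        resid = np.abs(M_Rb + M_Mb + M_O - M) / M
        if np.max(resid) > CONSERVATION_TOL:
            raise IntegrationError(
                f"sector-mass conservation violated (max residual "
                f"{np.max(resid):.3e})"
            )
    gamma = kinetics.gamma_max * c_pc / (c_pc + kinetics.Km_cpc)
    lam_i = gamma * M_Rb / M
    frame = pd.DataFrame(
        {
            "time_hr": sol.t,
            "M": M,
            "M_Rb": M_Rb,
            "M_Mb": M_Mb,
            "M_O": M_O,
            "c_pc": c_pc,
            "c_nt": c_nt,
            "inst_growth_rate_hr": lam_i,
        }
    )
    return Trajectory(frame=frame, model="simple")


def default_initial_state(
    allocation: AllocationTriple,
    kinetics: SimpleKinetics,
    c_nt0: float = 0.0,
) -> SimpleState:
    """M(0)=1 with sector masses at the allocation fractions and
    ``c_pc(0) = Km_cpc`` - near the physiological manifold, which shortens
    transients without biasing the fixed point."""
    return SimpleState(
        M=1.0,
        M_Rb=allocation.phi_Rb,
        M_Mb=allocation.phi_Mb,
        M_O=allocation.phi_O,
        c_pc=kinetics.Km_cpc,
        c_nt=c_nt0,
    )


def simulate(
    allocation: AllocationTriple,
    kinetics: SimpleKinetics,
    t_grid: np.ndarray,
    state0: SimpleState | None = None,
    nutrients_saturating: bool = True,
    _include_dilution: bool = True,
) -> Trajectory:
    """Constant-allocation simulation of the simple model."""
    if state0 is None:
        state0 = default_initial_state(allocation, kinetics)
    rhs = _vector_rhs(
        allocation, kinetics, nutrients_saturating, _include_dilution
    )
    return integrate_trajectory(rhs, state0, kinetics, t_grid)


def find_steady_state(
    allocation: AllocationTriple,
    kinetics: SimpleKinetics,
    init: SimpleState | None = None,
    tol: float = 1e-6,
    t_max: float | None = None,
) -> SteadyStateSolution:
    """Locate the steady state of a constant-allocation run by integration.

    Integrates in 1-hour windows until the instantaneous growth rate
    changes by less than ``tol`` (relative) across a window. The horizon
    defaults to ``200 / lambda_estimate`` with the estimate taken from the
    analytic root.
    """
    if allocation.phi_Rb <= 0 or allocation.phi_Mb <= 0:
        raise DomainError(
            "feasible allocation requires phi_Rb > 0 and phi_Mb > 0"
        )
    if init is None:
        init = default_initial_state(allocation, kinetics)
    lam_est = core.steady_state_growth_rate(
        allocation.phi_Rb, allocation.phi_O, kinetics
    )
    if t_max is None:
        t_max = 200.0 / max(lam_est, 0.05)
    rhs = _vector_rhs(allocation, kinetics, True, True)
    window = 1.0
    t = 0.0
    state = init
    lam_prev = None
    while t < t_max:
        traj = integrate_trajectory(
            rhs, state, kinetics, np.array([t, t + window])
        )
        state = traj.final_state()
        lam = float(traj.inst_growth_rate[-1])
        t += window
        if lam_prev is not None and lam > 0:
            if abs(lam - lam_prev) / lam < tol:
                return _solution_from_state(state, kinetics)
        lam_prev = lam
    raise ConvergenceError(
        f"no steady state within t_max = {t_max:.1f} hr (last lambda "
        f"{lam_prev!r})"
    )


def _solution_from_state(
    state: SimpleState, kinetics: SimpleKinetics
) -> SteadyStateSolution:
    total = state.M_Rb + state.M_Mb + state.M_O
    realized = AllocationTriple(
        phi_Rb=state.M_Rb / total,
        phi_Mb=state.M_Mb / total,
        phi_O=1.0 - state.M_Rb / total - state.M_Mb / total,
    )
    gamma = core.translation_rate(
        state.c_pc, kinetics.gamma_max, kinetics.Km_cpc
    )
    return SteadyStateSolution(
        growth_rate=gamma * realized.phi_Rb,
        c_pc_star=state.c_pc,
        gamma_value=gamma,
        realized_allocation=realized,
        scenario="I",
    )


def batch_culture_simulate(
    allocation: AllocationTriple,
    kinetics: SimpleKinetics,
    c_nt0: float,
    t_grid: np.ndarray,
    state0: SimpleState | None = None,
) -> Trajectory:
    """Batch-culture run: Monod uptake coupled to nutrient depletion.

    The nutrient trace is monotonically nonincreasing and growth ceases
    once the nutrients are exhausted; the exact mass balance
    ``Y * (c_nt(0) - c_nt(t)) = Delta[M (1 + c_pc)]`` holds along the
    trajectory.
    """
    if c_nt0 < 0:
        raise DomainError(f"c_nt0 must be nonnegative, got {c_nt0!r}")
    if state0 is None:
        state0 = default_initial_state(allocation, kinetics, c_nt0=c_nt0)
    else:
        state0 = replace(state0, c_nt=c_nt0)
    rhs = _vector_rhs(allocation, kinetics, False, True)
    return integrate_trajectory(rhs, state0, kinetics, t_grid)
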