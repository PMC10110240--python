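"""Physiological perturbations on top of the flux-parity circuit.

Four experiment families: ribosome inactivation by a reversibly binding
antibiotic (chloramphenicol), burden from excess (useless) protein
expression, instantaneous nutrient upshifts compared between flux-parity
and stepwise reallocation, and entry into starvation as a batch culture
exhausts its nutrients. Also provides the closed-form inversion that
estimates the maximal metabolic rate from an observed (growth rate,
ribosomal content) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import flux_parity as fp
from .dynamics import Trajectory
from .errors import DomainError, InfeasibleSteadyStateError
from .params import FluxParityKinetics, SteadyStateSolution

__all__ = [
    "ChloramphenicolSpec",
    "OverexpressionSpec",
    "UpshiftSpec",
    "ShiftSummary",
    "chlor_active_fraction",
    "chlor_steady_state",
    "overexpression_steady_state",
    "relative_growth_collapse",
    "estimate_nu_max",
    "phi_useless_for_shift",
    "simulate_upshift",
    "shift_collapse_summary",
    "fp_batch_culture",
    "starvation_synthesis_flux",
]

#: Default effective dissociation constant of chloramphenicol to a unit of
#: ribosomal mass (nM); the extracellular concentration is assumed equal to
#: the intracellular one.
KD_CM_DEFAULT_NM = 0.5

#: Default proportionality (hours) between the pre-shift conditionally
#: useless allocation and the pre/post growth-rate gap. The gap scales the
#: sector; the constant itself is a package convention.
PHI_USELESS_PER_RATE_GAP_HR = 0.15

#: Delay (hours) after the shift at which the "instantaneous post-shift"
#: growth rate is read off. The model's growth rate is continuous through
#: the shift but relaxes on the fast tRNA timescale; this samples the rate
#: after that fast transient.
POST_SHIFT_READOUT_DELAY_HR = 0.05


@dataclass(frozen=True)
class ChloramphenicolSpec:
    """Antibiotic exposure: concentration and effective dissociation constant."""

    c_cm: float
    KD_cm: float = KD_CM_DEFAULT_NM

    def __post_init__(self) -> None:
        if self.c_cm < 0:
            raise DomainError("c_cm must be nonnegative")
        if self.KD_cm <= 0:
            raise DomainError("KD_cm must be strictly positive")


@dataclass(frozen=True)
class OverexpressionSpec:
    """Allocation to a gratuitously expressed excess-protein sector."""

    phi_X: float

    def __post_init__(self) -> None:
        if not 0 <= self.phi_X <= 1:
            raise DomainError("phi_X must lie in [0, 1]")


@dataclass(frozen=True)
class UpshiftSpec:
    """An instantaneous improvement of the nutrient condition.

    At ``t_shift`` the maximal metabolic rate steps from ``nu_max_pre`` to
    ``nu_max_post`` and the conditionally useless sector shrinks from
    ``phi_useless_pre`` to ``phi_useless_post`` (zero after a shift into a
    rich medium). ``mode`` selects the reallocation strategy: dynamic
    flux-parity control or a stepwise jump of the allocation to its
    post-shift steady-state value.
    """

    nu_max_pre: float
    nu_max_post: float
    phi_useless_pre: float = 0.0
    phi_useless_post: float = 0.0
    t_shift: float = 0.0
    mode: str = "flux_parity"

    def __post_init__(self) -> None:
        if self.nu_max_post < self.nu_max_pre:
            raise DomainError(
                "an upshift requires nu_max_post >= nu_max_pre (equality "
                "is the null-shift control)"
            )
        if self.phi_useless_post > self.phi_useless_pre:
            raise DomainError(
                "the useless sector must not grow across an upshift"
            )
        if self.mode not in ("flux_parity", "stepwise"):
            raise DomainError(f"unknown shift mode {self.mode!r}")


@dataclass(frozen=True)
class ShiftSummary:
    """Growth rates characterizing a nutrient shift."""

    lambda_pre: float
    lambda_post_instant: float
    lambda_post_final: float
    shift_magnitude: float

    def __post_init__(self) -> None:
        if self.lambda_post_final < self.lambda_pre - 1e-9:
            raise DomainError(
                "post-shift steady growth must not fall below pre-shift "
                "growth for an upshift"
            )


# ---------------------------------------------------------------------------
# Chloramphenicol
# ---------------------------------------------------------------------------

def chlor_active_fraction(spec: ChloramphenicolSpec) -> float:
    """Probability that a ribosome is unbound: ``1 - c/(c + KD)``."""
    return 1.0 - spec.c_cm / (spec.c_cm + spec.KD_cm)


def chlor_steady_state(
    kinetics: FluxParityKinetics,
    spec: ChloramphenicolSpec,
    **kwargs,
) -> tuple[SteadyStateSolution, fp.FluxParityState]:
    """Flux-parity steady state under antibiotic exposure.

    Only active (unbound) ribosomes translate: the active fraction scales
    every translating-ribosome term. Bound ribosomes still count as
    ribosomal protein mass. Growth slows with dose while the ribosomal
    mass fraction rises in fast media - the classic antibiotic growth-law
    phenomenology.
    """
    return fp.fp_steady_state(
        kinetics, active_fraction=chlor_active_fraction(spec), **kwargs
    )


# ---------------------------------------------------------------------------
# Excess protein expression
# ---------------------------------------------------------------------------

def overexpression_steady_state(
    kinetics: FluxParityKinetics,
    spec: OverexpressionSpec,
    **kwargs,
) -> tuple[SteadyStateSolution, fp.FluxParityState]:
    """Flux-parity steady state with an excess sector ``phi_X``.

    The regulated prefactor becomes ``1 - phi_O - phi_X``; at steady state
    the excess mass fraction equals ``phi_X``.
    """
    if spec.phi_X > 1 - kinetics.phi_O:
        raise DomainError("phi_X must not exceed 1 - phi_O")
    extra = fp.ExtraAllocation(phi_X=spec.phi_X)
    return fp.fp_steady_state(kinetics, extra_allocation=extra, **kwargs)


def relative_growth_collapse(phi_X: float, phi_O: float) -> float:
    """Predicted relative growth rate under excess expression.

    If the excess sector changes nothing but the allocation budget, the
    growth-rate ratio collapses to ``(1 - phi_O - phi_X) / (1 - phi_O)``,
    independent of the medium.
    """
    if not 0 <= phi_X <= 1 or not 0 <= phi_O < 1:
        raise DomainError("fractions out of range")
    if phi_X > 1 - phi_O + 1e-12:
        raise DomainError("phi_X must not exceed 1 - phi_O")
    return (1.0 - phi_O - phi_X) / (1.0 - phi_O)


# ---------------------------------------------------------------------------
# Metabolic-rate inference
# ---------------------------------------------------------------------------

def estimate_nu_max(
    lambda_obs: float,
    phi_Rb_obs: float,
    phi_O: float,
    gamma_max: float,
    Km_cpc: float,
) -> float:
    """Infer the maximal metabolic rate from steady-state observations.

    Inverts the simple-model steady state: from ``lambda = gamma(c*) *
    phi_Rb`` the stationary precursor abundance is

        c* = Km * (lambda / (phi_Rb gamma_max)) / (1 - lambda / (phi_Rb gamma_max)),

    and metabolic flux balance then gives

        nu_max = lambda / (1 - phi_O - phi_Rb) * (c* + 1).

    Raises an infeasibility error at the translation-limit pole
    ``lambda >= phi_Rb * gamma_max`` and when ``phi_Rb + phi_O >= 1``.
    """
    if lambda_obs <= 0 or phi_Rb_obs <= 0:
        raise DomainError("lambda_obs and phi_Rb_obs must be positive")
    if gamma_max <= 0 or Km_cpc <= 0:
        raise DomainError("gamma_max and Km_cpc must be strictly positive")
    if phi_Rb_obs + phi_O >= 1:
        raise InfeasibleSteadyStateError(
            f"phi_Rb + phi_O must be below 1, got {phi_Rb_obs + phi_O!r}"
        )
    saturation = lambda_obs / (phi_Rb_obs * gamma_max)
    if saturation >= 1:
        raise InfeasibleSteadyStateError(
            "lambda_obs >= phi_Rb * gamma_max: the observed growth rate "
            "exceeds the translation limit, the precursor pool diverges"
        )
    c_pc = Km_cpc * saturation / (1.0 - saturation)
    return lambda_obs / (1.0 - phi_O - phi_Rb_obs) * (c_pc + 1.0)


# ---------------------------------------------------------------------------
# Nutrient upshifts
# ---------------------------------------------------------------------------

def phi_useless_for_shift(
    lambda_pre: float,
    lambda_post: float,
    per_rate_gap_hr: float = PHI_USELESS_PER_RATE_GAP_HR,
) -> float:
    """Pre-shift useless allocation, proportional to the growth-rate gap."""
    gap = lambda_post - lambda_pre
    if gap < 0:
        raise DomainError("expected lambda_post >= lambda_pre")
    return per_rate_gap_hr * gap


def simulate_upshift(
    kinetics_pre: FluxParityKinetics,
    kinetics_post: FluxParityKinetics,
    spec: UpshiftSpec,
    t_grid: np.ndarray,
) -> tuple[Trajectory, ShiftSummary]:
    """Simulate a nutrient upshift from a pre-equilibrated culture.

    The system starts at the pre-shift steady state; at ``t_shift`` the
    metabolic rate and the useless sector switch instantaneously. In
    ``flux_parity`` mode the allocation responds dynamically through the
    charging balance; in ``stepwise`` mode regulation reads only the
    environment, so both regulated quantities - the ribosomal allocation
    and the tRNA transcription rate - are pinned at their post-shift
    steady-state values from the shift onward.
    """
    if kinetics_pre.nu_max != spec.nu_max_pre:
        kinetics_pre = kinetics_pre.with_nu_max(spec.nu_max_pre)
    if kinetics_post.nu_max != spec.nu_max_post:
        kinetics_post = kinetics_post.with_nu_max(spec.nu_max_post)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] > spec.t_shift or t_grid[-1] <= spec.t_shift:
        raise DomainError("t_grid must span the shift time")
    extra_pre = fp.ExtraAllocation(phi_useless=spec.phi_useless_pre)
    extra_post = fp.ExtraAllocation(phi_useless=spec.phi_useless_post)
    sol_pre, state_pre = fp.fp_steady_state(
        kinetics_pre, extra_allocation=extra_pre
    )
    sol_post, state_post = fp.fp_steady_state(
        kinetics_post, extra_allocation=extra_post
    )

    pre_grid = t_grid[t_grid <= spec.t_shift]
    if len(pre_grid) < 2 or pre_grid[-1] < spec.t_shift:
        pre_grid = np.unique(np.append(pre_grid, spec.t_shift))
    traj_pre = fp.fp_simulate(
        kinetics_pre,
        pre_grid,
        state0=state_pre,
        extra_allocation=extra_pre,
    )
    state_at_shift = fp.final_fp_state(traj_pre)
    post_grid = np.unique(
        np.append(spec.t_shift, t_grid[t_grid > spec.t_shift])
    )
    fixed_phi = None
    fixed_kappa = None
    if spec.mode == "stepwise":
        fixed_phi = sol_post.realized_allocation.phi_Rb
        fixed_kappa = fp.fp_transcription_rate(
            state_post.charging_balance,
            kinetics_post.kappa_max,
            kinetics_post.tau,
        )
    traj_post = fp.fp_simulate(
        kinetics_post,
        post_grid,
        state0=state_at_shift,
        extra_allocation=extra_post,
        fixed_phi_Rb=fixed_phi,
        fixed_kappa=fixed_kappa,
    )
    frame = pd.concat(
        [
            traj_pre.frame[traj_pre.frame["time_hr"] < spec.t_shift],
            traj_post.frame,
        ],
        ignore_index=True,
    )
    traj = Trajectory(frame=frame, model="flux_parity")
    summary = shift_collapse_summary(
        traj, spec, lambda_post_final=sol_post.growth_rate
    )
    return traj, summary


def shift_collapse_summary(
    traj: Trajectory,
    spec: UpshiftSpec,
    lambda_post_final: float | None = None,
    readout_delay: float = POST_SHIFT_READOUT_DELAY_HR,
) -> ShiftSummary:
    """Extract the shift-characterizing rates from an upshift trajectory.

    ``lambda_pre`` is read just before the shift, ``lambda_post_instant``
    a short delay after it (past the fast tRNA transient), and
    ``lambda_post_final`` at the trajectory end unless supplied. The shift
    magnitude follows the package convention
    ``(lambda_post_final - lambda_pre) / lambda_post_final``; alternative
    normalizations can be computed from the same fields.
    """
    t = traj.times
    lam = traj.inst_growth_rate
    pre_mask = t <= spec.t_shift
    if not np.any(pre_mask) or np.all(pre_mask):
        raise DomainError("trajectory does not span the shift time")
    lambda_pre = float(lam[pre_mask][-1])
    i_inst = int(np.searchsorted(t, spec.t_shift + readout_delay))
    i_inst = min(i_inst, len(t) - 1)
    lambda_post_instant = float(lam[i_inst])
    if lambda_post_final is None:
        lambda_post_final = float(lam[-1])
    magnitude = (lambda_post_final - lambda_pre) / lambda_post_final
    return ShiftSummary(
        lambda_pre=lambda_pre,
        lambda_post_instant=lambda_post_instant,
        lambda_post_final=lambda_post_final,
        shift_magnitude=magnitude,
    )


# ---------------------------------------------------------------------------
# Starvation
# ---------------------------------------------------------------------------

def fp_batch_culture(
    kinetics: FluxParityKinetics,
    c_nt0: float,
    t_grid: np.ndarray,
    state0: fp.FluxParityState | None = None,
    extra_allocation: fp.ExtraAllocation | None = None,
) -> Trajectory:
    """Flux-parity batch culture with nutrient depletion.

    The metabolic rate carries both saturating factors (uncharged tRNA and
    external nutrient); the nutrient is consumed with yield ``Y`` and is
    never replenished, so growth arrests once it is exhausted. The run
    starts from the saturating-nutrient steady state unless an explicit
    initial state is given.
    """
    if c_nt0 < 0:
        raise DomainError("c_nt0 must be nonnegative")
    if state0 is None:
        _, state0 = fp.fp_steady_state(
            kinetics, extra_allocation=extra_allocation
        )
    state0 = replace(state0, c_nt=c_nt0)
    return fp.fp_simulate(
        kinetics,
        t_grid,
        state0=state0,
        extra_allocation=extra_allocation,
        nutrients_saturating=False,
    )


def starvation_synthesis_flux(traj: Trajectory) -> pd.Series:
    """Metabolic-protein synthesis flux along a trajectory, normalized.

    Returns the per-biomass synthesis flux ``phi_Mb(t) * (dM/dt)/M``
    divided by its initial (pre-starvation steady) value, indexed by time.
    The per-biomass normalization makes the saturating-nutrient control
    exactly flat (a steadily growing culture synthesizes metabolic protein
    at a constant specific rate). For a batch culture entering starvation
    the series rises as the charging balance collapses and allocation
    swings toward metabolic proteins, peaks near growth arrest, then decays
    with the vanishing synthesis flux.
    """
    frame = traj.frame
    if "phi_Mb" not in frame.columns:
        raise DomainError(
            "trajectory lacks allocation columns (not a flux-parity run)"
        )
    synthesis = (
        frame["phi_Mb"] * frame["inst_growth_rate_hr"]
    ).to_numpy()
    if synthesis[0] <= 0:
        raise DomainError("pre-starvation synthesis flux must be positive")
    return pd.Series(
        synthesis / synthesis[0], index=frame["time_hr"], name="rel_Mb_synthesis"
    )
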