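"""Synthetic steady-state observations.

Generates tables shaped like collated literature measurements of bacterial
growth physiology: growth rate, ribosomal mass fraction and translation
speed across media of varying nutrient quality (parameterized by the
maximal metabolic rate). Observations sit on the growth-rate-optimal
manifold of the simple model (or the flux-parity steady state) with
multiplicative lognormal measurement noise. The generator is the fixture
factory for parameter-recovery studies; real data differ in having
study-to-study systematic offsets and nonuniform coverage of growth rates,
which these tables do not emulate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import allocation_core as core
from . import flux_parity as fp
from .errors import DomainError
from .params import FluxParityKinetics, SimpleKinetics

__all__ = ["OBSERVATION_COLUMNS", "generate_synthetic_observations"]

OBSERVATION_COLUMNS = [
    "growth_rate_hr",
    "phi_Rb",
    "translation_speed_aa_s",
    "nu_max_true",
    "noise_seed",
]


def generate_synthetic_observations(
    nu_max_grid,
    kinetics: SimpleKinetics | FluxParityKinetics,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_per_condition: int = 1,
    phi_O: float | None = None,
) -> pd.DataFrame:
    """Synthetic (growth rate, ribosomal fraction, translation speed) table.

    For each ``nu_max`` the noiseless observation is the scenario-III
    steady state of the simple model (or the flux-parity steady state when
    flux-parity kinetics are passed). Each of the three observables then
    receives independent multiplicative lognormal noise with coefficient
    of variation ``noise_cv`` (mean-one, so noise does not bias medians).
    Deterministic given ``seed``.
    """
    if noise_cv < 0:
        raise DomainError("noise_cv must be nonnegative")
    if n_per_condition < 1:
        raise DomainError("n_per_condition must be at least 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    is_fp = isinstance(kinetics, FluxParityKinetics)
    if phi_O is None:
        phi_O = kinetics.phi_O if is_fp else 0.55
    rows = []
    for nu in np.asarray(nu_max_grid, dtype=float):
        if is_fp:
            sol, _ = fp.fp_steady_state(kinetics.with_nu_max(nu))
            lam = sol.growth_rate
            phi_Rb = sol.realized_allocation.phi_Rb
            gamma = sol.gamma_value
            m_Rb = kinetics.m_Rb
        else:
            kin = kinetics.with_nu_max(nu)
            phi_Rb = core.scenario_III_allocation(phi_O, kin)
            sol = core.solve_steady_state(phi_Rb, phi_O, kin, scenario="III")
            lam = sol.growth_rate
            gamma = sol.gamma_value
            m_Rb = kinetics.m_Rb if kinetics.m_Rb is not None else 7459.0
        speed = gamma * m_Rb / 3600.0
        for _ in range(n_per_condition):
            if sigma > 0:
                noise = np.exp(
                    rng.normal(-sigma**2 / 2.0, sigma, size=3)
                )
            else:
                noise = np.ones(3)
            rows.append(
                {
                    "growth_rate_hr": lam * noise[0],
                    "phi_Rb": phi_Rb * noise[1],
                    "translation_speed_aa_s": speed * noise[2],
                    "nu_max_true": nu,
                    "noise_seed": seed,
                }
            )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
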