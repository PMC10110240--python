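"""Parameter bundles and shared value types.

Unit conventions used throughout the package:

* time in hours;
* protein masses in amino-acid equivalents, normalized so that the initial
  total protein biomass is ``M(0) = 1``;
* intracellular species (precursors, tRNA pools) as relative mass abundances
  (mass of the pool divided by total protein mass), hence dimensionless;
* extracellular nutrient concentration in mM, coupled to biomass through the
  yield coefficient ``Y`` (biomass units per mM).

The per-hour maximal translation rate is tied to two provenance quantities,
the maximal elongation speed ``vtl_max`` (amino acids per second) and the
proteinaceous mass of a single ribosome ``m_Rb`` (amino acids), via
``gamma_max = vtl_max * 3600 / m_Rb``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import DomainError

__all__ = [
    "VTL_MAX_AA_PER_S",
    "M_RB_AA",
    "GAMMA_MAX_PER_HR",
    "PHI_O_DEFAULT",
    "AllocationTriple",
    "SimpleKinetics",
    "FluxParityKinetics",
    "SteadyStateSolution",
    "default_simple_kinetics",
    "default_flux_parity_kinetics",
]

#: Maximal peptide elongation speed of an E. coli ribosome, AA/s.
VTL_MAX_AA_PER_S = 20.0

#: Proteinaceous mass of a single E. coli ribosome, amino acids.
M_RB_AA = 7459.0

#: Maximal translation rate gamma_max = vtl_max * 3600 / m_Rb, 1/hr (~9.65).
GAMMA_MAX_PER_HR = VTL_MAX_AA_PER_S * 3600.0 / M_RB_AA

#: Allocation to the "other proteins" sector. Suggested default; the value is
#: not pinned by a direct measurement and should be treated as adjustable.
PHI_O_DEFAULT = 0.55

_SUM_TOL = 1e-12


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise DomainError(f"{name} must be strictly positive, got {value!r}")


def _require_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise DomainError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class AllocationTriple:
    """Partitioning of new protein synthesis between proteome sectors.

    ``phi_Rb`` (ribosomal), ``phi_Mb`` (metabolic) and ``phi_O`` (other)
    are fractions that sum to one: ribosomes translate one protein at a
    time, so the allocation fractions exhaust total synthesis.
    """

    phi_Rb: float
    phi_Mb: float
    phi_O: float

    def __post_init__(self) -> None:
        for name in ("phi_Rb", "phi_Mb", "phi_O"):
            _require_fraction(name, getattr(self, name))
        total = self.phi_Rb + self.phi_Mb + self.phi_O
        if abs(total - 1.0) > _SUM_TOL:
            raise DomainError(
                f"allocation fractions must sum to 1 (got {total!r})"
            )

    @classmethod
    def from_ribosomal(cls, phi_Rb: float, phi_O: float) -> "AllocationTriple":
        """Build a triple from (phi_Rb, phi_O), giving the rest to metabolism."""
        return cls(phi_Rb=phi_Rb, phi_Mb=1.0 - phi_Rb - phi_O, phi_O=phi_O)


@dataclass(frozen=True)
class SimpleKinetics:
    """Rate-law parameters of the simple (precursor-pool) allocation model.

    Parameters
    ----------
    gamma_max : float
        Maximal translation rate, 1/hr.
    nu_max : float
        Maximal metabolic rate (nutrient-quality proxy), 1/hr.
    Km_cpc : float
        Michaelis constant of translation w.r.t. the precursor relative
        abundance (dimensionless).
    Km_cnt : float
        Monod constant of nutrient uptake, mM.
    Y : float
        Yield: biomass units produced per mM of nutrient consumed.
    vtl_max, m_Rb : float, optional
        Provenance of ``gamma_max``: elongation speed (AA/s) and ribosome
        protein mass (AA). When both are given they must be consistent with
        ``gamma_max`` to within 1e-9 relative.
    """

    gamma_max: float
    nu_max: float
    Km_cpc: float
    Km_cnt: float = 0.1
    Y: float = 1.0
    vtl_max: float | None = None
    m_Rb: float | None = None

    def __post_init__(self) -> None:
        for name in ("gamma_max", "nu_max", "Km_cpc", "Km_cnt", "Y"):
            _require_positive(name, getattr(self, name))
        if self.vtl_max is not None:
            _require_positive("vtl_max", self.vtl_max)
        if self.m_Rb is not None:
            _require_positive("m_Rb", self.m_Rb)
        if self.vtl_max is not None and self.m_Rb is not None:
            implied = self.vtl_max * 3600.0 / self.m_Rb
            if not math.isclose(implied, self.gamma_max, rel_tol=1e-9):
                raise DomainError(
                    "gamma_max inconsistent with vtl_max*3600/m_Rb "
                    f"({self.gamma_max!r} vs {implied!r})"
                )

    @classmethod
    def from_elongation(
        cls,
        vtl_max: float,
        m_Rb: float,
        nu_max: float,
        Km_cpc: float,
        **kwargs,
    ) -> "SimpleKinetics":
        """Construct with ``gamma_max`` computed from (vtl_max, m_Rb)."""
        return cls(
            gamma_max=vtl_max * 3600.0 / m_Rb,
            nu_max=nu_max,
            Km_cpc=Km_cpc,
            vtl_max=vtl_max,
            m_Rb=m_Rb,
            **kwargs,
        )

    def with_nu_max(self, nu_max: float) -> "SimpleKinetics":
        return replace(self, nu_max=nu_max)


@dataclass(frozen=True)
class FluxParityKinetics:
    """Rate-law parameters of the flux-parity (tRNA charging) circuit.

    In addition to the translation/metabolic Michaelis-Menten rates (now
    functions of the charged and uncharged tRNA pools), the circuit carries
    two regulatory parameters: ``tau``, the charging balance at which the
    ribosomal allocation is half-maximal, and ``kappa_max``, the maximal
    rate of uncharged-tRNA transcription (relative abundance per hour).
    """

    gamma_max: float
    nu_max: float
    Km_tRNAc: float
    Km_tRNAu: float
    tau: float
    kappa_max: float
    phi_O: float
    Km_cnt: float = 0.1
    Y: float = 1.0
    m_Rb: float = M_RB_AA

    def __post_init__(self) -> None:
        for name in (
            "gamma_max",
            "nu_max",
            "Km_tRNAc",
            "Km_tRNAu",
            "tau",
            "kappa_max",
            "Km_cnt",
            "Y",
            "m_Rb",
        ):
            _require_positive(name, getattr(self, name))
        _require_fraction("phi_O", self.phi_O)

    def with_nu_max(self, nu_max: float) -> "FluxParityKinetics":
        return replace(self, nu_max=nu_max)


@dataclass(frozen=True)
class SteadyStateSolution:
    """A steady state of either model.

    At steady state the growth rate factorizes as
    ``growth_rate = gamma_value * phi_Rb``: translation rate per unit
    ribosomal mass times the allocation (equal to the mass fraction).
    ``c_pc_star`` is the stationary precursor abundance in the simple model,
    or the stationary charged-tRNA abundance under flux parity.
    """

    growth_rate: float
    c_pc_star: float
    gamma_value: float
    realized_allocation: AllocationTriple
    scenario: str = "custom"

    _VALID_SCENARIOS = ("I", "II", "III", "flux_parity", "custom")

    def __post_init__(self) -> None:
        if self.scenario not in self._VALID_SCENARIOS:
            raise DomainError(f"unknown scenario tag {self.scenario!r}")
        if self.growth_rate < 0:
            raise DomainError("steady-state growth rate must be nonnegative")
        expected = self.gamma_value * self.realized_allocation.phi_Rb
        if abs(self.growth_rate - expected) > 1e-9 * max(1.0, abs(expected)):
            raise DomainError(
                "inconsistent steady state: growth_rate != gamma * phi_Rb "
                f"({self.growth_rate!r} vs {expected!r})"
            )


def default_simple_kinetics(
    nu_max: float = 4.0, Km_cpc: float = 0.03, **kwargs
) -> SimpleKinetics:
    """E. coli-like simple-model kinetics.

    ``gamma_max`` follows from the measured elongation speed (20 AA/s) and
    ribosome protein mass (7459 AA). ``Km_cpc`` is a suggested value of the
    precursor Michaelis constant; ``nu_max`` parameterizes nutrient quality
    and is expected to be varied by the caller.
    """
    return SimpleKinetics.from_elongation(
        vtl_max=VTL_MAX_AA_PER_S,
        m_Rb=M_RB_AA,
        nu_max=nu_max,
        Km_cpc=Km_cpc,
        **kwargs,
    )


def default_flux_parity_kinetics(
    nu_max: float = 4.0,
    phi_O: float = PHI_O_DEFAULT,
    tau: float = 3.0,
    kappa_max: float = 2.0e-2,
    Km_tRNAc: float = 2.0e-5,
    Km_tRNAu: float = 3.0e-6,
    **kwargs,
) -> FluxParityKinetics:
    """E. coli-like flux-parity kinetics.

    The tRNA pools stand in for the whole precursor pool and are measured
    as relative mass abundances (one amino-acid equivalent per tRNA); the
    steady-state pool size is ``kappa / lambda``, a few 1e-3 at
    physiological growth rates, which sets the scale of ``kappa_max``.
    The Michaelis constants sit one to three orders below the pools
    (synthetases bind uncharged tRNA with higher affinity than the
    ribosome's effective affinity for ternary complexes, hence the smaller
    ``Km_tRNAu``), and ``tau = 3`` keeps the allocation response in its
    sensitive range across the physiological span of charging balances.
    These are suggested values, not direct measurements; the circuit's
    near-optimality is insensitive to order-of-magnitude variation around
    them.
    """
    return FluxParityKinetics(
        gamma_max=GAMMA_MAX_PER_HR,
        nu_max=nu_max,
        Km_tRNAc=Km_tRNAc,
        Km_tRNAu=Km_tRNAu,
        tau=tau,
        kappa_max=kappa_max,
        phi_O=phi_O,
        m_Rb=M_RB_AA,
        **kwargs,
    )
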