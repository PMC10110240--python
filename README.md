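# riboalloc

Low-dimensional ribosomal-allocation models of microbial growth, with
flux-parity (tRNA charging / ppGpp) regulation.

Microbial growth is, to first approximation, a problem of resource
partitioning: ribosomes make all protein, including more ribosomes, but
they depend on metabolic proteins to supply the precursors (charged tRNA,
amino acids, energy) that translation consumes. `riboalloc` implements the
coarse-grained theory of this trade-off for people studying bacterial
growth physiology: it splits the proteome into ribosomal, metabolic and
"other" sectors with allocation fractions φ_Rb + φ_Mb + φ_O = 1, and
follows the flow of mass from nutrients to biomass with a handful of
biologically meaningful parameters.

## The model

Biomass grows by translation, dM/dt = γ(c_pc)·M_Rb, with a
Michaelis–Menten translation rate γ(c_pc) = γ_max·c_pc/(c_pc + K_M). At
fixed allocation and saturating nutrients the steady-state growth rate is
the positive root of

    (1 − K_M) λ² − (N + Γ) λ + N·Γ = 0,    N = ν_max(1 − φ_Rb − φ_O),  Γ = γ_max·φ_Rb,

which lets three regulatory strategies be compared analytically: fixed
allocation (I), constant translation rate (II), and growth-rate-optimal
allocation (III). On top of this sits the *flux-parity circuit*: charged
and uncharged tRNA pools are modeled explicitly, and their ratio — the
charging balance B = tRNA_c/tRNA_u, read out biochemically through the
alarmone ppGpp — dynamically controls both the ribosomal allocation
φ_Rb(B) = (1 − φ_O)·B/(B + τ) and tRNA transcription. The circuit's
steady state self-organizes at the allocation that mutually maximizes
the metabolic flux (uncharged → charged tRNA) and the translational flux
(charged tRNA → protein), reproducing scenario III without any explicit
optimization — and it keeps working out of steady state, which is where
the interesting predictions live: ribosome-targeting antibiotics, excess
protein burden, nutrient upshifts, and entry into starvation.

See `docs/methods.md` for the full equations, parameter table, numerical
choices and known limitations.

## Worked example

```python
import numpy as np
from riboalloc import default_flux_parity_kinetics, default_simple_kinetics
from riboalloc.allocation_core import scenario_III_allocation
from riboalloc.flux_parity import fp_steady_state

kin = default_flux_parity_kinetics(nu_max=4.0)   # a decent carbon source
sol, state = fp_steady_state(kin)
print(f"growth rate           lambda   = {sol.growth_rate:.4f} /hr")
print(f"ribosomal allocation  phi_Rb   = {sol.realized_allocation.phi_Rb:.4f}")
print(f"translation speed     v_tl     = {sol.gamma_value * kin.m_Rb / 3600:.2f} AA/s")
print(f"charging balance      B        = {state.charging_balance:.3f}")

simple = default_simple_kinetics(nu_max=4.0, Km_cpc=kin.Km_tRNAc)
phi_opt = scenario_III_allocation(kin.phi_O, simple)
print(f"optimal allocation    phi_Rb*  = {phi_opt:.4f}")
```

prints

```
growth rate           lambda   = 1.2661 /hr
ribosomal allocation  phi_Rb   = 0.1322
translation speed     v_tl     = 19.85 AA/s
charging balance      B        = 1.248
optimal allocation    phi_Rb*  = 0.1322
```

In a medium supporting λ ≈ 1.27/hr the circuit allocates 13% of protein
synthesis to ribosomes, translation runs near its 20 AA/s ceiling, and —
the central result — the emergent allocation (0.1322) coincides with the
growth-rate-optimal value computed independently from the analytic
theory. Lower `nu_max` (poorer medium) and both numbers drop together;
the two stay within 0.01 of each other from starvation-adjacent media to
rich broth.

A command-line interface exposes the standard scans
(`riboalloc scan-steady`, `riboalloc scenarios`, `riboalloc fluxparity`,
`riboalloc perturb chlor|overexpress|upshift|starve`,
`riboalloc fixtures`); every run writes CSV/JSON with a provenance
header. Configs are flat key-value YAML files with unit-suffixed keys
(`gamma_max_per_hr`, `km_cnt_mM`, ...); CLI flags override config keys.

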