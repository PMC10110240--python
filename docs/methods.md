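# Methods

## The simple allocation model

The model tracks the flow of mass from environmental nutrients into protein
biomass in a well-mixed batch culture. Total protein `M` is split into three
sectors: ribosomal protein `M_Rb`, metabolic protein `M_Mb`, and everything
else `M_O`. Biomass grows by translation,

    dM/dt = gamma(c_pc) * M_Rb,        gamma(c_pc) = gamma_max * c_pc / (c_pc + Km_cpc),

where `c_pc` is the lumped precursor pool (charged tRNA, free amino acids,
energy carriers) measured as a relative mass abundance, and
`gamma_max = vtl_max * 3600 / m_Rb` converts the maximal elongation speed
(AA/s) and the protein mass of one ribosome (AA) into a per-hour rate.
Metabolic proteins synthesize precursors at a rate `nu`, Monod in the
external nutrient and equal to `nu_max` under saturating nutrients. The
precursor balance carries three terms — production, consumption by
translation, and dilution by growth:

    dc_pc/dt = nu * M_Mb/M - gamma * M_Rb/M - c_pc * gamma * M_Rb/M.

The dilution term is essential: without it the precursor pool has no fixed
point whenever metabolic supply exceeds the translation ceiling (a
regression test documents this failure mode). New synthesis is partitioned
by allocation fractions `phi_Rb + phi_Mb + phi_O = 1`; allocation fractions
equal mass fractions only at steady state. In batch culture the nutrient is
depleted as `dc_nt/dt = -nu * M_Mb / Y`.

Units: time in hours; masses normalized to `M(0) = 1`; intracellular pools
as dimensionless relative abundances (the protein density is treated as a
constant and divided out); `c_nt` in mM, coupled to biomass through the
yield `Y` (biomass units per mM, volume factor absorbed).

### Steady state

With fixed allocation and saturating nutrients, writing
`N = nu_max * (1 - phi_Rb - phi_O)` and `Gamma = gamma_max * phi_Rb`, the
growth rate is the positive root of

    (1 - Km_cpc) lambda^2 - (N + Gamma) lambda + N * Gamma = 0,

with the continuous limit `lambda = N*Gamma/(N+Gamma)` at `Km_cpc = 1`
(the implementation switches to the limit form inside `|1 - Km_cpc| <
1e-9`; the root is continuous there so no branch discontinuity arises).
The stationary precursor abundance is `c_pc* = nu_max * phi_Mb / lambda - 1`;
a negative value means the allocation admits no steady state and raises a
typed error instead of returning NaN, so parameter scans fail loudly.

### Regulatory scenarios

* **I — fixed allocation**: `phi_Rb` constant across conditions.
* **II — translation-rate priority**: `phi_Rb` chosen so the precursor
  pool (hence the translation rate) is constant; both the exact form and
  its large-`c*` approximation are implemented.
* **III — growth-rate optimum**: the `phi_Rb` maximizing the steady-state
  growth rate. The closed form is

      phi_Rb = (1 - phi_O) * [nu(gamma + nu - 2 Km gamma) + (gamma - nu) sqrt(Km gamma nu)]
               / [(gamma + nu)^2 - 4 Km gamma nu],

  with the square root spanning only `Km * gamma_max * nu_max`. This was
  re-derived symbolically and validated against a dense-grid brute-force
  argmax (agreement below 1e-8 across random parameters); the brute-force
  optimizer remains in the package as the independent oracle, and the
  closed form falls back to bounded numerical maximization in the single
  degenerate case (`gamma_max = nu_max` with `Km_cpc = 1`, where the
  expression is 0/0 but the optimum is exactly `(1 - phi_O)/2`).

## The flux-parity circuit

The refined model replaces the lumped precursor with explicit charged
(`tRNA_c`) and uncharged (`tRNA_u`) tRNA pools, each a relative mass
abundance with one amino-acid equivalent per tRNA. Metabolism charges
tRNA at `nu(tRNA_u)`, translation consumes charged tRNA at
`gamma(tRNA_c)` and returns it uncharged, transcription adds uncharged
tRNA at rate `kappa`, and growth dilutes both pools. The charging balance
`B = tRNA_c / tRNA_u` is the regulatory signal:

    phi_Rb(B) = (1 - phi_O) * B / (B + tau),      kappa(B) = kappa_max * B / (B + tau).

Biochemically `B` is read out through the alarmone ppGpp, whose
concentration is taken as inversely proportional to `B` (ratiometric
ansatz) or proportional to the probability of a ribosome binding an
uncharged tRNA (binding ansatz, `1/(1+B)`). Only concentrations relative
to a reference condition are reported; the reference is the medium whose
steady-state growth rate is closest to 1/hr, located by root bracketing
in `nu_max`. The two ansatzes agree on allocation but predict different
ppGpp-versus-growth-rate scalings: the binding form is strictly
shallower in log-slope, which is what discriminates them against data.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `vtl_max` | 20 | AA/s | measured maximal elongation speed |
| `m_Rb` | 7459 | AA | protein mass of one ribosome |
| `gamma_max` | 9.65 | 1/hr | `vtl_max*3600/m_Rb` |
| `phi_O` | 0.55 | — | other-protein allocation; suggested, not directly measured |
| `Km_cpc` | 0.03 | — | precursor half-saturation (simple model); suggested |
| `tau` | 3 | — | charging balance at half-maximal `phi_Rb` |
| `kappa_max` | 0.02 | 1/hr | maximal tRNA transcription (relative abundance/hr) |
| `Km_tRNAc` | 2e-5 | — | ribosome's effective affinity for charged tRNA |
| `Km_tRNAu` | 3e-6 | — | synthetase affinity for uncharged tRNA (tighter) |
| `Km_cnt` | 0.1 | mM | Monod constant of nutrient uptake |
| `Y` | 1 | biomass/mM | batch-culture yield |
| `KD_cm` | 0.5 | nM | chloramphenicol effective dissociation constant |

The steady-state tRNA pool is `kappa(B)/lambda`, a few 1e-3 at
physiological growth rates, standing in for the broader precursor pool;
the Michaelis constants sit one to three orders below it so translation
and metabolism run near saturation in steady growth. The regulatory
parameters were chosen once, in the physiological regime, and the
circuit's central property is insensitive to them: the steady-state
allocation tracks the scenario-III optimum to better than 0.01 (absolute)
across `nu_max` from 0.1 to 20/hr and across a tenfold span of both `tau`
and `kappa_max` (the acceptance suite measures a worst-case gap of
~0.004 at the defaults). The optimum used for this comparison is the
simple model with `Km_cpc = Km_tRNAc`, since charged tRNA plays the
precursor role in the refined circuit.

### Steady-state solver

Flux-parity steady states are found by integrating the ODE system in
one-hour windows until the instantaneous growth rate settles (relative
change below `tol`, default 1e-6), then polishing the stationary tRNA
pools with a Newton solve in log coordinates. The two raw pool balances
are nearly opposite near the fixed point, so the solver works on the
well-conditioned pair (charged-pool balance, total-pool balance) and
judges residuals relative to the gross turnover of each. The polished
root is accepted only if it satisfies stationarity to `tol`; otherwise
the ODE endpoint must, or a convergence error is raised.

## Perturbations

**Antibiotic (chloramphenicol).** A reversibly binding, ribosome-targeting
drug leaves a fraction `P_active = 1 - c_cm/(c_cm + KD_cm)` of ribosomes
translating. `P_active` multiplies every translating-ribosome term (growth
and both tRNA-pool couplings); bound ribosomes still count as ribosomal
protein mass. This reproduces the antibiotic growth law: growth falls with
dose while the ribosomal mass fraction rises in fast media.

**Excess expression.** A gratuitous sector `phi_X` shrinks the regulated
budget to `1 - phi_O - phi_X`. Because the charging balance is nearly
unchanged, the relative growth rate collapses onto
`(1 - phi_O - phi_X)/(1 - phi_O)` independently of the medium; the full
circuit matches this line to ~5e-4.

**Metabolic-rate inference.** `estimate_nu_max` inverts the simple-model
steady state: from observed `(lambda, phi_Rb)` it reconstructs `c_pc*`
and solves the flux balance for `nu_max`, raising a typed infeasibility
error at the translation-limit pole `lambda >= phi_Rb * gamma_max`. The
inversion is exact on the model manifold (round trip < 1e-6) and recovers
the generating `nu_max` to a few percent (median) at 10% multiplicative
measurement noise with 50 replicates per condition.

**Nutrient upshift.** At the shift instant `nu_max` steps up and a
conditionally useless sector `phi_useless` drops to zero. Its pre-shift
size is proportional to the pre/post growth-rate gap; the constant
(0.15 hr) is a package convention, as is the shift-magnitude statistic
`(lambda_post_final - lambda_pre)/lambda_post_final` and the readout of
the "instantaneous post-shift" growth rate 0.05 hr after the shift
(past the fast tRNA transient — the model's growth rate is continuous
through the shift and responds on the seconds-to-minutes timescale).
Two reallocation strategies are compared: dynamic flux-parity control,
and a *stepwise* comparator in which regulation reads only the
environment, so both regulated quantities (`phi_Rb` and `kappa`) jump to
their post-shift steady values at the shift. Both modes reach the same
final steady state (within 1e-5); the flux-parity strategy dominates the
stepwise one throughout the adaptation. Two fine-grained caveats, visible
only below experimental resolution: (i) in the first ~10–20 seconds the
stepwise strategy leads infinitesimally, because its allocation jumps
instantly while the charging-balance signal needs time to build; (ii) for
small shifts the two curves cross at the 1e-4 level in the asymptotic
tail where both sit within 0.02% of the final rate. At minute-scale
sampling of a substantial shift, dominance holds at every sample to
better than 1e-6. The instantaneous growth rate also shows a genuine
sub-percent dip mid-transient as the allocation overshoot relaxes; the
approach is monotone after it.

**Starvation.** Batch culture under the flux-parity circuit with the
metabolic rate carrying both saturating factors (uncharged tRNA and
external nutrient). As the nutrient runs out the charging balance
collapses, allocation swings toward metabolic proteins, and the
per-biomass metabolic-synthesis flux `phi_Mb * (dM/dt)/M` (normalized to
its steady pre-starvation value, so the saturating-nutrient control is
exactly flat) rises in a burst that peaks within 0.1 hr of growth arrest
— the behavior of glucose-reporter expression at the onset of starvation.
Default starvation conditions: `nu_max = 8/hr`, 3 mM initial nutrient at
unit yield (about two biomass doublings before arrest).

## Numerics

* Integrator: LSODA (stiff-capable) with `rtol = 1e-8`, `atol = 1e-10`;
  all runs bit-reproducible, no randomness outside the synthetic-data
  generator (which is fully seed-determined).
* States are clipped at −1e-12 for rate evaluation only; excursions below
  −1e-8 (relative to each variable's magnitude) abort with a diagnostic —
  the dense-output interpolation can undershoot zero by a few times
  `atol` when a pool collapses at starvation, which is round-off, not
  model error.
* Sector masses are integrated alongside `M` and their sum is checked to
  a relative residual of 1e-6 at every sample.
* The uncharged-tRNA pool is floored at 1e-12 inside the integrator only
  (the charging balance would otherwise be singular); a floor hit is
  logged as a warning.
* Default initial conditions sit near the physiological manifold (sector
  masses at the allocation fractions, pools at their half-saturation or
  transcription-balance scale); a basin-independence test confirms the
  fixed point does not depend on this choice.
* Steady-state detection (windowed growth-rate convergence, 1-hour
  window, default horizon `200/lambda_estimate`) is a package choice; no
  canonical criterion exists for these models.

## The synthetic-data generator

`generate_synthetic_observations` emulates collated steady-state growth
physiology tables: for each `nu_max` it computes the growth-optimal (or
flux-parity) steady state and reports growth rate, ribosomal mass
fraction and translation speed with independent, mean-one multiplicative
lognormal noise of a chosen coefficient of variation. It does **not**
emulate study-to-study systematic offsets, correlated errors between the
three observables, nonuniform growth-rate coverage, or the slow-growth
regime where protein degradation and inactive ribosomes matter; passing
the recovery tests therefore demonstrates the inversion machinery, not
robustness to those real-data features.

## Known limitations

* Steady-state analytics assume saturating nutrients; nutrient-limited
  conditions are handled only dynamically.
* No multi-nutrient media, diauxie, chemostats, ribosome hibernation,
  protein degradation, or regrowth lag after starvation.
* ppGpp is reported only relative to a reference condition; the model has
  no absolute concentration scale and no explicit RelA/SpoT kinetics.
* Total tRNA abundance floats through the transcription law; no
  fixed-total constraint is imposed (the evidence is conflicting, and
  under a fixed total the two ppGpp ansatzes would coincide).
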