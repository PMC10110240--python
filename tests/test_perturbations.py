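"""Perturbation experiments: antibiotics, excess expression, shifts, starvation."""

import numpy as np
import pytest

from riboalloc import flux_parity as fp
from riboalloc import perturbations as pert
from riboalloc.allocation_core import steady_state_growth_rate
from riboalloc.errors import DomainError, InfeasibleSteadyStateError
from riboalloc.params import SimpleKinetics
from riboalloc.synthetic import generate_synthetic_observations


class TestChloramphenicol:
    @pytest.mark.parametrize(
        "c_cm, kd, expected",
        [(0.0, 0.5, 1.0), (0.5, 0.5, 0.5), (1.5, 0.5, 0.25)],
    )
    def test_active_fraction(self, c_cm, kd, expected):
        spec = pert.ChloramphenicolSpec(c_cm=c_cm, KD_cm=kd)
        assert pert.chlor_active_fraction(spec) == pytest.approx(expected)

    def test_zero_dose_matches_unperturbed(self, fp_kinetics):
        base, _ = fp.fp_steady_state(fp_kinetics)
        dosed, _ = pert.chlor_steady_state(
            fp_kinetics, pert.ChloramphenicolSpec(c_cm=0.0)
        )
        assert dosed.growth_rate == pytest.approx(base.growth_rate, rel=1e-8)

    def test_dose_response_phenomenology(self, fp_kinetics):
        """Growth falls monotonically; in a fast medium the ribosomal
        fraction rises and the translation speed falls with dose."""
        ref_kin, _, _ = fp.find_reference_state(fp_kinetics)
        lams, phis, gammas = [], [], []
        for c_cm in (0.0, 0.5, 1.0, 2.0, 4.0):
            sol, _ = pert.chlor_steady_state(
                ref_kin, pert.ChloramphenicolSpec(c_cm=c_cm)
            )
            lams.append(sol.growth_rate)
            phis.append(sol.realized_allocation.phi_Rb)
            gammas.append(sol.gamma_value)
        assert np.all(np.diff(lams) < 0)
        assert np.all(np.diff(phis) > 0)
        assert np.all(np.diff(gammas) < 0)


class TestOverexpression:
    def test_zero_burden_matches_base(self, fp_kinetics):
        base, _ = fp.fp_steady_state(fp_kinetics)
        sol, _ = pert.overexpression_steady_state(
            fp_kinetics, pert.OverexpressionSpec(phi_X=0.0)
        )
        assert sol.growth_rate == pytest.approx(base.growth_rate, rel=1e-8)

    def test_excess_mass_fraction_converges(self, fp_kinetics):
        _, st = pert.overexpression_steady_state(
            fp_kinetics, pert.OverexpressionSpec(phi_X=0.15)
        )
        assert abs(st.M_X / st.M - 0.15) < 1e-4

    def test_collapse_relation(self, fp_kinetics):
        """The growth-rate ratio follows the allocation-budget collapse,
        independently of the medium."""
        for nu in (1.5, 8.0):
            kin = fp_kinetics.with_nu_max(nu)
            lam0, _ = fp.fp_steady_state(kin)
            for phi_X in (0.1, 0.3):
                sol, _ = pert.overexpression_steady_state(
                    kin, pert.OverexpressionSpec(phi_X=phi_X)
                )
                ratio = sol.growth_rate / lam0.growth_rate
                predicted = pert.relative_growth_collapse(
                    phi_X, fp_kinetics.phi_O
                )
                assert ratio == pytest.approx(predicted, abs=0.02)

    @pytest.mark.parametrize(
        "phi_X, phi_O, expected",
        [(0.0, 0.55, 1.0), (0.045, 0.55, 0.9), (0.45, 0.55, 0.0)],
    )
    def test_collapse_formula(self, phi_X, phi_O, expected):
        assert pert.relative_growth_collapse(phi_X, phi_O) == pytest.approx(
            expected
        )


class TestEstimateNuMax:
    def test_worked_example(self):
        nu = pert.estimate_nu_max(1.0, 0.2, 0.55, 10.0, 0.01)
        assert nu == pytest.approx(4.04, abs=1e-9)

    def test_round_trip_through_growth_law(self, rng):
        """estimate_nu_max inverts the steady-state growth law exactly."""
        for _ in range(20):
            phi_O = 0.55
            phi_Rb = rng.uniform(0.02, 0.4)
            gamma_max = 9.65
            Km = 0.03
            nu_true = rng.uniform(0.2, 20.0)
            kin = SimpleKinetics(
                gamma_max=gamma_max, nu_max=nu_true, Km_cpc=Km
            )
            lam = steady_state_growth_rate(phi_Rb, phi_O, kin)
            nu_est = pert.estimate_nu_max(lam, phi_Rb, phi_O, gamma_max, Km)
            assert nu_est == pytest.approx(nu_true, rel=1e-6)

    def test_translation_limit_pole_raises(self):
        with pytest.raises(InfeasibleSteadyStateError):
            pert.estimate_nu_max(2.0, 0.2, 0.55, 10.0, 0.01)
        with pytest.raises(InfeasibleSteadyStateError):
            pert.estimate_nu_max(0.5, 0.3, 0.8, 10.0, 0.01)

    def test_recovery_from_noiseless_observations(self, ecoli_kinetics):
        table = generate_synthetic_observations(
            np.array([0.5, 1.0, 2.0, 4.0, 8.0]),
            ecoli_kinetics,
            noise_cv=0.0,
            seed=0,
        )
        errors = []
        for _, row in table.iterrows():
            nu_est = pert.estimate_nu_max(
                row["growth_rate_hr"],
                row["phi_Rb"],
                0.55,
                ecoli_kinetics.gamma_max,
                ecoli_kinetics.Km_cpc,
            )
            errors.append(abs(nu_est - row["nu_max_true"]) / row["nu_max_true"])
        assert np.median(errors) < 0.01


@pytest.fixture(scope="module")
def shift_pair(fp_kinetics):
    """A substantial upshift (nu 1 -> 6) run in both reallocation modes."""
    kpre = fp_kinetics.with_nu_max(1.0)
    kpost = fp_kinetics.with_nu_max(6.0)
    lam_pre = fp.fp_steady_state(kpre)[0].growth_rate
    lam_post = fp.fp_steady_state(kpost)[0].growth_rate
    pu = pert.phi_useless_for_shift(lam_pre, lam_post)
    t_grid = np.arange(-1.0, 10.0 + 0.01, 0.01)
    out = {}
    for mode in ("flux_parity", "stepwise"):
        spec = pert.UpshiftSpec(
            nu_max_pre=1.0,
            nu_max_post=6.0,
            phi_useless_pre=pu,
            t_shift=0.0,
            mode=mode,
        )
        out[mode] = pert.simulate_upshift(kpre, kpost, spec, t_grid)
    return out


class TestUpshift:
    def test_null_shift_is_flat(self, fp_kinetics):
        kin = fp_kinetics.with_nu_max(2.0)
        spec = pert.UpshiftSpec(
            nu_max_pre=2.0, nu_max_post=2.0, t_shift=0.0, mode="flux_parity"
        )
        traj, summary = pert.simulate_upshift(
            kin, kin, spec, np.arange(-1.0, 3.01, 0.05)
        )
        lam = traj.inst_growth_rate
        assert np.ptp(lam) / lam[0] < 1e-5
        assert summary.shift_magnitude == pytest.approx(0.0, abs=1e-5)
        assert summary.lambda_post_instant == pytest.approx(
            summary.lambda_pre, rel=1e-5
        )

    def test_flux_parity_dominates_stepwise(self, shift_pair):
        traj_fp, _ = shift_pair["flux_parity"]
        traj_sw, _ = shift_pair["stepwise"]
        t = traj_fp.times
        diff = traj_fp.inst_growth_rate - traj_sw.inst_growth_rate
        assert np.min(diff[t > 0]) > -1e-6
        assert np.max(diff) > 0.3  # the advantage is substantial mid-shift

    def test_rapid_rise_and_relaxation(self, shift_pair):
        """Growth responds within minutes of the shift (a near-jump on the
        hour scale) and, after the allocation-overshoot transient, climbs
        monotonically to the post-shift steady rate."""
        traj, summary = shift_pair["flux_parity"]
        assert summary.lambda_post_instant > 1.1 * summary.lambda_pre
        t = traj.times
        lam = traj.inst_growth_rate
        late = lam[t > 2.0]
        assert np.all(np.diff(late) > -1e-6)
        assert np.max(lam) <= summary.lambda_post_final + 1e-6
        assert lam[-1] == pytest.approx(summary.lambda_post_final, rel=1e-4)

    def test_final_state_mode_independent(self, shift_pair):
        lam_fp = shift_pair["flux_parity"][0].inst_growth_rate[-1]
        lam_sw = shift_pair["stepwise"][0].inst_growth_rate[-1]
        assert lam_fp == pytest.approx(lam_sw, rel=1e-5)

    def test_magnitude_increases_with_richness(self, fp_kinetics):
        mags = []
        kpre = fp_kinetics.with_nu_max(1.0)
        for nu_post in (2.0, 4.0, 8.0):
            spec = pert.UpshiftSpec(
                nu_max_pre=1.0, nu_max_post=nu_post, t_shift=0.0
            )
            _, summary = pert.simulate_upshift(
                kpre,
                fp_kinetics.with_nu_max(nu_post),
                spec,
                np.arange(-0.5, 6.01, 0.02),
            )
            mags.append(summary.shift_magnitude)
        assert np.all(np.diff(mags) > 0)

    def test_collapse_across_preshift_media(self, fp_kinetics):
        """The post/pre rate ratio is a single function of shift magnitude:
        curves from different pre-shift media coincide within 5%."""
        curves = {}
        for nu_pre in (0.5, 1.0, 2.0):
            kpre = fp_kinetics.with_nu_max(nu_pre)
            lam_pre = fp.fp_steady_state(kpre)[0].growth_rate
            pts = []
            for factor in (2.5, 6.0, 14.0):
                nu_post = factor * max(nu_pre, 1.0)
                kpost = fp_kinetics.with_nu_max(nu_post)
                lam_post = fp.fp_steady_state(kpost)[0].growth_rate
                spec = pert.UpshiftSpec(
                    nu_max_pre=nu_pre,
                    nu_max_post=nu_post,
                    phi_useless_pre=pert.phi_useless_for_shift(
                        lam_pre, lam_post
                    ),
                    t_shift=0.0,
                )
                _, s = pert.simulate_upshift(
                    kpre, kpost, spec, np.arange(-0.5, 5.01, 0.01)
                )
                pts.append((s.shift_magnitude, s.lambda_post_instant / s.lambda_pre))
            curves[nu_pre] = np.array(sorted(pts))
        lo = max(c[:, 0].min() for c in curves.values())
        hi = min(c[:, 0].max() for c in curves.values())
        mags = np.linspace(lo, hi, 10)
        stacked = np.vstack(
            [np.interp(mags, c[:, 0], c[:, 1]) for c in curves.values()]
        )
        scatter = (stacked.max(axis=0) - stacked.min(axis=0)) / stacked.mean(
            axis=0
        )
        assert scatter.max() < 0.05

    def test_spec_validation(self):
        with pytest.raises(DomainError):
            pert.UpshiftSpec(nu_max_pre=2.0, nu_max_post=1.0)
        with pytest.raises(DomainError):
            pert.UpshiftSpec(
                nu_max_pre=1.0,
                nu_max_post=2.0,
                phi_useless_pre=0.0,
                phi_useless_post=0.1,
            )


class TestStarvation:
    def test_saturating_control_is_flat(self, fp_kinetics):
        _, st = fp.fp_steady_state(fp_kinetics)
        traj = fp.fp_simulate(
            fp_kinetics, np.linspace(0, 5, 101), state0=st
        )
        flux = pert.starvation_synthesis_flux(traj)
        assert np.allclose(flux.to_numpy(), 1.0, atol=1e-4)

    def test_peak_coincides_with_growth_arrest(self, fp_kinetics):
        kin = fp_kinetics.with_nu_max(8.0)
        t_grid = np.linspace(0, 8, 3201)
        traj = pert.fp_batch_culture(kin, 3.0, t_grid)
        flux = pert.starvation_synthesis_flux(traj).to_numpy()
        lam = traj.inst_growth_rate
        peak_t = t_grid[int(np.argmax(flux))]
        arrest = lam < 0.05 * lam[0]
        assert arrest.any()
        arrest_t = t_grid[int(np.argmax(arrest))]
        assert flux.max() > 1.3  # a genuine burst of metabolic synthesis
        assert abs(peak_t - arrest_t) < 0.1

    def test_more_nutrient_delays_peak_and_adds_biomass(self, fp_kinetics):
        kin = fp_kinetics.with_nu_max(8.0)
        t_grid = np.linspace(0, 10, 2001)
        peaks, final_M = [], []
        for c0 in (1.0, 3.0):
            traj = pert.fp_batch_culture(kin, c0, t_grid)
            flux = pert.starvation_synthesis_flux(traj).to_numpy()
            peaks.append(t_grid[int(np.argmax(flux))])
            final_M.append(traj.frame["M"].iloc[-1])
        assert peaks[1] > peaks[0]
        assert final_M[1] > final_M[0]
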