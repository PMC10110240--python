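"""The flux-parity circuit: rate laws, dynamics, emergent optimality, ppGpp."""

import numpy as np
import pytest

from riboalloc import flux_parity as fp
from riboalloc.allocation_core import scenario_III_allocation
from riboalloc.errors import ChargingSingularityError, DomainError
from riboalloc.params import FluxParityKinetics, SimpleKinetics


class TestRegulatoryRateLaws:
    def test_allocation_half_maximal_at_tau(self):
        assert fp.fp_allocation(3.0, 0.55, 3.0) == pytest.approx(0.45 / 2)

    def test_allocation_limits(self):
        assert fp.fp_allocation(0.0, 0.55, 3.0) == 0.0
        assert fp.fp_allocation(1e6 * 3.0, 0.55, 3.0) == pytest.approx(
            0.45, rel=1e-5
        )

    def test_allocation_negative_balance_raises(self):
        with pytest.raises(DomainError):
            fp.fp_allocation(-1.0, 0.55, 3.0)

    def test_transcription_rate(self):
        assert fp.fp_transcription_rate(3.0, 0.02, 3.0) == pytest.approx(0.01)
        assert fp.fp_transcription_rate(0.0, 0.02, 3.0) == 0.0
        assert fp.fp_transcription_rate(1e9, 0.02, 3.0) == pytest.approx(
            0.02, rel=1e-6
        )

    def test_translation_rate(self):
        assert fp.fp_translation_rate(2e-5, 10.0, 2e-5) == pytest.approx(5.0)
        assert fp.fp_translation_rate(0.0, 10.0, 2e-5) == 0.0
        assert fp.fp_translation_rate(6e-5, 10.0, 2e-5) == pytest.approx(7.5)

    def test_metabolic_rate_product_form(self):
        assert fp.fp_metabolic_rate(3e-6, 4.0, 3e-6) == pytest.approx(2.0)
        assert fp.fp_metabolic_rate(0.0, 4.0, 3e-6) == 0.0
        # both saturating factors at half-saturation multiply
        assert fp.fp_metabolic_rate(
            3e-6, 4.0, 3e-6, c_nt=0.1, Km_cnt=0.1
        ) == pytest.approx(1.0)


class TestRhs:
    KIN = FluxParityKinetics(
        gamma_max=10.0,
        nu_max=4.0,
        Km_tRNAc=0.05,
        Km_tRNAu=0.01,
        tau=5.0,
        kappa_max=0.02,
        phi_O=0.55,
    )

    def test_forced_arithmetic(self):
        # gamma = 5 (tRNA_c at its Km), nu = 2, kappa = 0.01 (B = 5 = tau)
        state = fp.FluxParityState(
            M=1.0, M_Rb=0.2, M_Mb=0.25, M_O=0.55,
            tRNA_c=0.05, tRNA_u=0.01,
        )
        d = fp.fp_rhs(state, self.KIN)
        assert d.tRNA_c == pytest.approx(-0.55)
        assert d.tRNA_u == pytest.approx(0.5)
        assert d.M == pytest.approx(1.0)

    def test_sector_sum_equals_dM(self):
        state = fp.FluxParityState(
            M=1.0, M_Rb=0.3, M_Mb=0.2, M_O=0.5, tRNA_c=1e-3, tRNA_u=1e-3
        )
        d = fp.fp_rhs(state, self.KIN)
        assert d.M_Rb + d.M_Mb + d.M_O + d.M_X == pytest.approx(
            d.M, rel=1e-14
        )

    def test_total_pool_identity(self, rng):
        """d(tRNA_c + tRNA_u)/dt = kappa(B) - (tRNA_c + tRNA_u) * lambda_i."""
        for _ in range(10):
            state = fp.FluxParityState(
                M=1.0,
                M_Rb=rng.uniform(0.05, 0.4),
                M_Mb=rng.uniform(0.05, 0.4),
                M_O=0.3,
                tRNA_c=rng.uniform(1e-4, 1e-2),
                tRNA_u=rng.uniform(1e-4, 1e-2),
            )
            d = fp.fp_rhs(state, self.KIN)
            B = state.tRNA_c / state.tRNA_u
            kappa = fp.fp_transcription_rate(B, self.KIN.kappa_max, self.KIN.tau)
            lam_i = d.M / state.M
            expected = kappa - (state.tRNA_c + state.tRNA_u) * lam_i
            assert d.tRNA_c + d.tRNA_u == pytest.approx(expected, rel=1e-12)

    def test_charging_singularity(self):
        state = fp.FluxParityState(
            M=1.0, M_Rb=0.2, M_Mb=0.25, M_O=0.55, tRNA_c=1e-3, tRNA_u=0.0
        )
        with pytest.raises(ChargingSingularityError):
            fp.fp_rhs(state, self.KIN)


class TestSteadyState:
    def test_matches_trajectory_endpoint(self, fp_kinetics):
        sol, st = fp.fp_steady_state(fp_kinetics)
        traj = fp.fp_simulate(fp_kinetics, np.linspace(0, 60, 121))
        assert traj.inst_growth_rate[-1] == pytest.approx(
            sol.growth_rate, rel=1e-5
        )

    def test_symmetric_limit(self, fp_kinetics):
        """gamma_max = nu_max: the optimum sits at (1 - phi_O)/2."""
        kin = fp_kinetics.with_nu_max(fp_kinetics.gamma_max)
        sol, _ = fp.fp_steady_state(kin)
        assert sol.realized_allocation.phi_Rb == pytest.approx(
            (1 - kin.phi_O) / 2, abs=5e-3
        )

    def test_tracks_optimal_allocation(self, fp_kinetics):
        for nu in (0.5, 2.0, 8.0):
            sol, _ = fp.fp_steady_state(fp_kinetics.with_nu_max(nu))
            simple = SimpleKinetics(
                gamma_max=fp_kinetics.gamma_max,
                nu_max=nu,
                Km_cpc=fp_kinetics.Km_tRNAc,
            )
            opt = scenario_III_allocation(fp_kinetics.phi_O, simple)
            assert abs(sol.realized_allocation.phi_Rb - opt) < 0.01

    def test_mass_fraction_equals_allocation(self, fp_kinetics):
        traj = fp.fp_simulate(fp_kinetics, np.linspace(0, 80, 161))
        row = traj.frame.iloc[-1]
        assert row["M_Rb"] / row["M"] == pytest.approx(
            row["phi_Rb"], abs=1e-5
        )

    def test_mutual_maximization(self, fp_kinetics):
        """Freezing the allocation off the flux-parity point lowers growth."""
        sol, _ = fp.fp_steady_state(fp_kinetics)
        phi_star = sol.realized_allocation.phi_Rb
        for dp in (-0.05, 0.05):
            frozen, _ = fp.fp_fixed_allocation_steady_state(
                phi_star + dp, fp_kinetics
            )
            assert frozen.growth_rate < sol.growth_rate


class TestFluxes:
    def test_translational_flux_equals_growth_rate(self, fp_kinetics):
        sol, st = fp.fp_steady_state(fp_kinetics)
        pair = fp.compute_fluxes(st, fp_kinetics)
        assert pair.J_Tl == pytest.approx(sol.growth_rate, rel=1e-8)

    def test_stationarity_relates_fluxes(self, fp_kinetics):
        """At steady state nu*M_Mb/M = gamma*M_Rb/M * (1 + tRNA_c)."""
        _, st = fp.fp_steady_state(fp_kinetics)
        pair = fp.compute_fluxes(st, fp_kinetics)
        assert pair.J_Mb == pytest.approx(
            pair.J_Tl * (1 + st.tRNA_c), rel=1e-6
        )

    def test_zero_ribosomes_zero_flux(self, fp_kinetics):
        st = fp.FluxParityState(
            M=1.0, M_Rb=0.0, M_Mb=0.45, M_O=0.55, tRNA_c=1e-3, tRNA_u=1e-3
        )
        assert fp.compute_fluxes(st, fp_kinetics).J_Tl == 0.0


class TestPpGpp:
    def _state(self, B):
        return fp.FluxParityState(
            M=1.0, M_Rb=0.2, M_Mb=0.25, M_O=0.55,
            tRNA_c=B * 1e-3, tRNA_u=1e-3,
        )

    def test_reference_equals_one(self):
        st = self._state(2.0)
        for ansatz in ("ratiometric", "binding"):
            assert fp.ppgpp_relative(
                st, st, ansatz
            ).relative_concentration == pytest.approx(1.0)

    def test_ratiometric_and_binding_values(self):
        assert fp.ppgpp_relative(
            self._state(1.0), self._state(2.0), "ratiometric"
        ).relative_concentration == pytest.approx(2.0)
        assert fp.ppgpp_relative(
            self._state(1.0), self._state(3.0), "binding"
        ).relative_concentration == pytest.approx(2.0)

    def test_zero_uncharged_raises(self):
        bad = fp.FluxParityState(
            M=1.0, M_Rb=0.2, M_Mb=0.25, M_O=0.55, tRNA_c=1e-3, tRNA_u=0.0
        )
        with pytest.raises(ChargingSingularityError):
            fp.ppgpp_relative(bad, self._state(1.0))

    def test_scaling_with_growth_rate(self, fp_kinetics):
        """Relative ppGpp is 1 at the lambda ~ 1/hr reference and falls
        strictly with growth rate; the binding ansatz is shallower."""
        ref_kin, ref_sol, ref_st = fp.find_reference_state(fp_kinetics)
        assert ref_sol.growth_rate == pytest.approx(1.0, abs=1e-6)
        assert fp.ppgpp_relative(
            ref_st, ref_st
        ).relative_concentration == pytest.approx(1.0)
        scan = fp.steady_state_scan(
            np.array([0.3, 0.8, 2.0, 5.0, 12.0]),
            fp_kinetics,
            reference_state=ref_st,
        )
        lam = scan["growth_rate_hr"].to_numpy()
        assert np.all(np.diff(lam) > 0)
        assert np.all(np.diff(scan["rel_ppGpp_ratiometric"]) < 0)
        slope_r = np.polyfit(lam, np.log(scan["rel_ppGpp_ratiometric"]), 1)[0]
        slope_b = np.polyfit(lam, np.log(scan["rel_ppGpp_binding"]), 1)[0]
        assert slope_r < slope_b < 0


class TestScanWriterSchema:
    def test_columns(self, fp_kinetics):
        _, _, ref_st = fp.find_reference_state(fp_kinetics)
        scan = fp.steady_state_scan(
            np.array([1.0, 4.0]), fp_kinetics, reference_state=ref_st
        )
        assert list(scan.columns) == [
            "nu_max_hr",
            "growth_rate_hr",
            "phi_Rb",
            "translation_speed_aa_s",
            "tRNA_c",
            "tRNA_u",
            "charging_balance",
            "rel_ppGpp_ratiometric",
            "rel_ppGpp_binding",
        ]
        # translation speed is gamma * m_Rb / 3600, bounded by vtl_max
        assert (scan["translation_speed_aa_s"] < 20.0).all()
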