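"""The closed-form sub-saturated solution and its agreement with the integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import loxsim as lx
from loxsim.oracle import LinearizedModel
from loxsim.pathway import SPECIES


class TestLinearizedModel:
    def test_total_rate_wild_type(self, default_config):
        """K = (8250 + 39000 + 2550) / 490000 = 0.1016 per minute."""
        lin = LinearizedModel.from_config(default_config)
        assert lin.total_rate == pytest.approx(0.101633, abs=1e-5)

    def test_precondition_rejects_saturated_regime(self, default_config):
        cfg = default_config.with_km_scaled("L3", 1e-3)  # Km -> 490 nmol/mL
        with pytest.raises(ValueError, match="sub-saturated"):
            LinearizedModel.from_config(cfg)

    def test_lumped_fractions_sum_to_one(self, default_config):
        lin = LinearizedModel.from_config(default_config)
        from loxsim.parameters import ISOMERS

        assert sum(lin.lumped_fraction(i) for i in ISOMERS) == (
            pytest.approx(1.0, abs=1e-12)
        )


class TestClosedForm:
    def test_initial_condition(self, default_config):
        sol = lx.closed_form(default_config, 0.0)
        assert float(sol["LA"]) == pytest.approx(67.0)
        assert float(sol["hexanal"]) == 0.0

    def test_wild_type_final_hexanal(self, default_config):
        sol = lx.closed_form(default_config, 100.0)
        assert float(sol["hexanal"]) == pytest.approx(49.0, abs=0.5)

    def test_mass_conserved_algebraically(self, default_config):
        from loxsim.parameters import ISOMERS

        t = np.linspace(0, 100, 7)
        sol = lx.closed_form(default_config, t)
        total = sol["LA"] + sum(sol[i] for i in ISOMERS) + sol["hexanal"]
        np.testing.assert_allclose(total, 67.0, rtol=1e-12)

    def test_null_genotype(self, default_config):
        sol = lx.closed_form(default_config.with_genotype("L0"), 50.0)
        assert float(sol["LA"]) == 67.0
        assert float(sol["hexanal"]) == 0.0

    def test_instantaneous_hpl_limit(self, default_config):
        """With HPL rate constants inflated 1e6-fold, every molecule
        routed to the two active isomers has already become hexanal:
        hexanal -> LA0 * F_active * (1 - e^{-Kt})."""
        from dataclasses import replace

        kin = dict(default_config.kinetics)
        for eid in ("HPL_SZE", "HPL_RZE"):
            kin[eid] = replace(kin[eid], vmax_scaled=kin[eid].vmax_scaled * 1e6)
        cfg = replace(default_config, kinetics=kin)
        lin = LinearizedModel.from_config(cfg)
        F = lin.lumped_fraction("13HOD_SZE") + lin.lumped_fraction("13HOD_RZE")
        K = lin.total_rate
        t = 30.0
        expected = 67.0 * F * (1 - np.exp(-K * t))
        assert float(lx.closed_form(cfg, t)["hexanal"]) == pytest.approx(
            expected, rel=1e-4
        )

    def test_degenerate_kappa_equals_K_branch(self, default_config):
        """The kappa ~= K limit is continuous: perturbing kappa by one
        part in 1e10 changes nothing measurable."""
        from dataclasses import replace

        kin = dict(default_config.kinetics)
        lin = LinearizedModel.from_config(default_config)
        K = lin.total_rate
        # pick HPL constants so kappa_SZE == K exactly
        kin["HPL_SZE"] = replace(kin["HPL_SZE"], vmax_scaled=K * kin["HPL_SZE"].km)
        cfg = replace(default_config, kinetics=kin)
        exact = float(lx.closed_form(cfg, 30.0)["hexanal"])
        kin["HPL_SZE"] = replace(
            kin["HPL_SZE"], vmax_scaled=K * kin["HPL_SZE"].km * (1 + 1e-10)
        )
        nearby = float(lx.closed_form(replace(cfg, kinetics=kin), 30.0)["hexanal"])
        assert nearby == pytest.approx(exact, rel=1e-6)


class TestOracleVsIntegrator:
    @pytest.mark.parametrize("genotype", ["L123", "L1", "L3", "L12"])
    def test_agreement_all_species_all_times(self, default_config, genotype):
        """At the default parameters (LA0/Km ~ 1.4e-4) the nonlinear
        integration and the linear closed form agree to <= 1e-3
        relative on every species at every output time."""
        cfg = default_config.with_genotype(genotype)
        tc = lx.simulate(cfg)
        ora = lx.closed_form_vector(cfg, tc.time)
        denom = np.maximum(np.abs(ora), 1e-9 * 67.0)
        assert np.max(np.abs(tc.states - ora) / denom) <= 1e-3

    def test_relative_table_matches_integrator(self, default_config, scan):
        ora = lx.relative_table(default_config)
        for g, val in ora.items():
            assert scan.relative[g] == pytest.approx(val, abs=2e-3)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(
        f1=st.floats(0.1, 10.0),
        f2=st.floats(0.1, 10.0),
        t=st.floats(1.0, 100.0),
    )
    def test_mass_conservation_under_perturbation(self, default_config, f1, f2, t):
        """Mass conservation of the closed form is an algebraic
        identity, robust to Vmax perturbations."""
        from loxsim.parameters import ISOMERS

        cfg = default_config.with_vmax_scaled("L1", f1).with_vmax_scaled("L2", f2)
        sol = lx.closed_form(cfg, t)
        total = float(sol["LA"] + sum(sol[i] for i in ISOMERS) + sol["hexanal"])
        assert total == pytest.approx(67.0, rel=1e-12)
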