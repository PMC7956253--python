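"""Hill uptake, RHS structure, mass accounting and fixture loading."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagopbpk import (
    FormulationParams,
    ModelError,
    ModelSpec,
    OrganKinetics,
    compile_model,
    epr_rhs,
    formulation_names,
    hill_uptake,
    load_formulation,
    mass_balance,
    pcs_rhs,
)
from phagopbpk.physiology import ORGANS


class TestHillUptake:
    def test_midpoint_is_half_maximum(self):
        k = OrganKinetics(P=0.15, PAC=0.001, K_max=12.0, K_50=0.5, n=1.3, K_out=1.0)
        assert hill_uptake(k, 0.5) == pytest.approx(6.0, rel=1e-12)

    def test_saturates_to_k_max(self):
        k = OrganKinetics(P=0.15, PAC=0.001, K_max=7.0, K_50=0.02, n=1.0, K_out=1.0)
        assert hill_uptake(k, 1e6 * k.K_50) == pytest.approx(7.0, rel=1e-3)

    def test_zero_at_time_zero_with_positive_exponent(self):
        k = OrganKinetics(P=0.15, PAC=0.001, K_max=151.0, K_50=0.001, n=0.001, K_out=12.0)
        assert hill_uptake(k, 0.0) == 0.0

    def test_flat_hill_exponent_sits_near_half_maximum(self):
        # liver row of the densest-PEG 80 nm formulation: n ~ 0 flattens the
        # curve so k_up(1 h) ~ K_max/2 within 1%
        k = load_formulation("mPEG5k-28.57%-80 nm").organs["liver"]
        assert (k.K_max, k.K_50, k.n) == (151.0, 0.001, 0.001)
        direct = k.K_max * 1.0 ** k.n / (k.K_50 ** k.n + 1.0 ** k.n)
        val = float(hill_uptake(k, 1.0))
        assert val == pytest.approx(direct, rel=1e-12)
        assert val == pytest.approx(k.K_max / 2, rel=0.01)

    def test_zero_exponent_limit_convention(self):
        k = OrganKinetics(P=0.15, PAC=0.001, K_max=8.0, K_50=0.3, n=0.0, K_out=1.0)
        assert float(hill_uptake(k, 0.0)) == pytest.approx(4.0)
        assert float(hill_uptake(k, 5.0)) == pytest.approx(4.0)

    def test_negative_time_rejected(self):
        k = OrganKinetics(P=0.15, PAC=0.001, K_max=1.0, K_50=0.1, n=1.0, K_out=1.0)
        with pytest.raises(ModelError):
            hill_uptake(k, -0.1)

    def test_monotone_in_time_for_all_packaged_rows(self, formulations):
        t = np.linspace(0.0, 72.0, 500)
        for params in formulations.values():
            for organ, k in params.organs.items():
                vals = hill_uptake(k, t)
                assert np.all(np.diff(vals) >= -1e-12), (params.formulation_name, organ)

    @settings(deadline=None, derandomize=True)
    @given(
        k_max=st.floats(0.01, 600),
        k_50=st.floats(1e-4, 10),
        n=st.floats(1e-4, 3),
        t1=st.floats(0, 72),
        dt=st.floats(0, 10),
    )
    def test_monotone_nondecreasing_property(self, k_max, k_50, n, t1, dt):
        k = OrganKinetics(P=0.15, PAC=0.001, K_max=k_max, K_50=k_50, n=n, K_out=1.0)
        assert hill_uptake(k, t1 + dt) >= hill_uptake(k, t1) - 1e-12 * k_max


class TestRhsStructure:
    @pytest.mark.parametrize("variant,rhs", [("PCs", pcs_rhs), ("EPR", epr_rhs)])
    def test_zero_state_gives_zero_derivative(self, variant, rhs, phys, reference_formulation):
        model = compile_model(ModelSpec(variant=variant), reference_formulation, phys)
        zero = np.zeros(model.layout.n_states)
        out = rhs(zero, 1.7, reference_formulation, phys, ModelSpec(variant=variant))
        assert np.allclose(out, 0.0)

    def test_rhs_linear_in_amounts(self, phys, reference_formulation, pcs_spec):
        model = compile_model(pcs_spec, reference_formulation, phys)
        rng = np.random.default_rng(3)
        y = rng.uniform(0, 1, model.layout.n_states)
        d1 = model.rhs(2.5, y)
        d2 = model.rhs(2.5, 2 * y)
        assert np.allclose(d2, 2 * d1, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("variant", ["PCs", "EPR"])
    def test_derivatives_conserve_mass_at_random_states(self, variant, phys,
                                                        reference_formulation):
        model = compile_model(ModelSpec(variant=variant), reference_formulation, phys)
        rng = np.random.default_rng(11)
        for t in (0.0, 0.05, 1.0, 30.0):
            y = rng.uniform(0, 0.5, model.layout.n_states)
            total_rate = model.rhs(t, y).sum()
            assert abs(total_rate) < 1e-10

    def test_variant_guards(self, phys, reference_formulation):
        y = np.zeros(25)
        with pytest.raises(ModelError):
            pcs_rhs(y, 0.0, reference_formulation, phys, ModelSpec(variant="EPR"))
        with pytest.raises(ModelError):
            epr_rhs(y, 0.0, reference_formulation, phys, ModelSpec(variant="PCs"))


class TestEprTumour:
    def test_zero_rate_constants_decouple_epr_space(self, phys, reference_formulation):
        from dataclasses import replace

        params = replace(reference_formulation, K1=0.0, K2=0.0)
        model = compile_model(ModelSpec(variant="EPR"), params, phys)
        y = model.initial_state(2.0)
        y[model.layout.cap("tumour")] = 0.1
        dy = model.rhs(1.0, y)
        assert dy[model.layout.pc("tumour")] == 0.0
        assert dy[model.layout.tissue("tumour")] == 0.0

    def test_stationary_epr_amount_balances_extravasation(self, phys, reference_formulation):
        # at the fixed point of the EPR space, A_EPR = K1 V_V CV / K2
        model = compile_model(ModelSpec(variant="EPR"), reference_formulation, phys)
        lay = model.layout
        cv = 0.04  # mg/mL held in the tumour capillary
        v_v = phys.capillary_volume_ml("tumour")
        y = np.zeros(lay.n_states)
        y[lay.cap("tumour")] = cv * v_v
        y[lay.pc("tumour")] = reference_formulation.K1 * v_v * cv / reference_formulation.K2
        dy = model.rhs(50.0, y)
        assert dy[lay.pc("tumour")] == pytest.approx(0.0, abs=1e-14)


class TestMassBalance:
    def test_bolus_state_balances_exactly(self, phys, reference_formulation, pcs_spec):
        model = compile_model(pcs_spec, reference_formulation, phys)
        assert mass_balance(model.initial_state(2.0), 2.0) == 0.0

    def test_perturbation_shows_up_as_residual(self, phys, reference_formulation, pcs_spec):
        model = compile_model(pcs_spec, reference_formulation, phys)
        y = model.initial_state(2.0)
        y[5] += 0.1
        assert mass_balance(y, 2.0) == pytest.approx(0.1, abs=1e-12)


class TestFixtures:
    def test_five_formulations_ship(self):
        names = formulation_names()
        assert len(names) == 5
        assert "mPEG5k-9.09%-80 nm" in names

    def test_all_organs_present_with_clearances(self, formulations):
        for params in formulations.values():
            assert set(params.organs) == set(ORGANS)
            assert params.K_bile == 0.0012
            assert params.K_urine == 0.00012

    def test_unknown_formulation_rejected(self):
        with pytest.raises(ModelError, match="unknown formulation"):
            load_formulation("mPEG-nonexistent")

    def test_negative_kinetics_rejected(self):
        with pytest.raises(ModelError):
            OrganKinetics(P=0.15, PAC=0.001, K_max=-1.0, K_50=0.1, n=1.0, K_out=1.0)

    def test_missing_organ_rejected(self, reference_formulation):
        organs = dict(reference_formulation.organs)
        del organs["spleen"]
        with pytest.raises(ModelError, match="spleen"):
            FormulationParams(formulation_name="broken", organs=organs)
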