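"""Unit and property tests for the forward/inverse steady-state equations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from o15pet import (
    ArterialConcentrations,
    PhysioConstants,
    cbf_from_co2,
    cbv_from_co,
    cmro2,
    correct_oef,
    forward_co,
    forward_co2,
    forward_o2,
    oef_uncorrected,
    tissue_water_factor,
    uncorrect_oef,
    vascular_fraction,
)

C = PhysioConstants()

# Dense physiological grids used by the round-trip property checks.
CBF_GRID = np.linspace(0.05, 1.0, 25)
CBV_GRID = np.linspace(0.0, 0.12, 25)
OEF_GRID = np.linspace(0.0, 1.0, 21)

positive_scale = st.floats(min_value=1e-3, max_value=1e3)


class TestTissueWaterFactor:
    def test_direct_evaluation(self):
        # F = CBF/(CBF/p + lam), evaluated independently of the implementation
        for cbf in CBF_GRID:
            assert tissue_water_factor(cbf, C) == pytest.approx(
                cbf / (cbf / C.p + C.lam), rel=1e-14
            )

    def test_zero_flow_gives_zero_signal(self):
        assert tissue_water_factor(0.0, C) == 0.0

    def test_no_decay_limit_reaches_partition_coefficient(self):
        slow_decay = PhysioConstants(lam=1e-12)
        assert tissue_water_factor(0.3, slow_decay) == pytest.approx(C.p, rel=1e-9)

    def test_strictly_monotone_in_cbf(self):
        f = tissue_water_factor(CBF_GRID, C)
        assert np.all(np.diff(f) > 0)
        assert np.all((f >= 0) & (f < C.p))

    def test_negative_cbf_rejected(self):
        with pytest.raises(ValueError):
            tissue_water_factor(-0.1, C)
        assert np.isnan(tissue_water_factor(np.array([-0.1, 0.3]), C)[0])


class TestCO2Chain:
    def test_round_trip_to_machine_precision(self):
        ci = forward_co2(CBF_GRID, 1.0, C)
        rec = cbf_from_co2(ci, 1.0, C)
        np.testing.assert_allclose(rec, CBF_GRID, rtol=1e-10)

    def test_linearity_in_arterial_activity(self):
        assert forward_co2(0.3, 2.0, C) == pytest.approx(2 * forward_co2(0.3, 1.0, C))
        assert forward_co2(0.3, 0.0, C) == 0.0

    def test_zero_brain_activity_is_zero_flow(self):
        assert cbf_from_co2(0.0, 1.0, C) == 0.0

    def test_singularity_flagged(self):
        # Ci >= Ca*p: equilibrium ratio can never reach the partition coefficient
        out = cbf_from_co2(np.array([C.p, 1.5 * C.p, -0.1]), 1.0, C)
        assert np.isnan(out).all()
        with pytest.raises(ValueError):
            cbf_from_co2(1.0, 1.0, C)


class TestCOChain:
    def test_round_trip(self):
        ci = forward_co(0.03, 1.0, C)
        assert ci == pytest.approx(0.0255)
        assert cbv_from_co(ci, 1.0, C) == pytest.approx(0.03, rel=1e-14)

    def test_zero_and_unit_hematocrit(self):
        assert cbv_from_co(0.0, 1.0, C) == 0.0
        unit = PhysioConstants(hct_ratio=1.0)
        assert cbv_from_co(0.02, 1.0, unit) == pytest.approx(0.02)

    def test_nonpositive_arterial_rejected(self):
        with pytest.raises(ValueError):
            cbv_from_co(0.02, 0.0, C)


class TestVascularFraction:
    def test_against_rate_ratio_form(self):
        # Independent algebraic form: X = (CBF/p + lam) / (CBF/((h/H) CBV) + CBF/p + lam)
        for cbf in CBF_GRID:
            for cbv in CBV_GRID[1:]:
                alt = (cbf / C.p + C.lam) / (
                    cbf / (C.hct_ratio * cbv) + cbf / C.p + C.lam
                )
                assert abs(vascular_fraction(cbf, cbv, C) - alt) < 1e-12

    def test_limits(self):
        assert vascular_fraction(0.3, 0.0, C) == 0.0
        assert vascular_fraction(0.3, 1e6, C) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_cbv(self):
        x = vascular_fraction(0.3, CBV_GRID, C)
        assert np.all(np.diff(x) > 0)
        assert np.all((x >= 0) & (x < 1))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            vascular_fraction(0.0, 0.03, C)
        assert np.isnan(vascular_fraction(np.array([0.0]), np.array([0.03]), C)[0])


class TestOEFChain:
    def test_uncorrected_inverts_generating_relation(self):
        # Ci_O2 constructed from the defining relation recovers any x >= 0
        for x in (0.0, 0.25, 0.7, 1.3):
            ci_o2 = 1.0 * (0.4686 / 1.0) * (x + C.Rm)
            assert oef_uncorrected(ci_o2, 0.4686, 1.0, 1.0, C) == pytest.approx(x, abs=1e-12)

    def test_zero_oxygen_signal_gives_minus_rm(self):
        assert oef_uncorrected(0.0, 0.5, 1.0, 1.0, C) == pytest.approx(-C.Rm)

    def test_correct_uncorrect_round_trip(self):
        oef = OEF_GRID[:, None]
        x = np.linspace(0.0, 0.5, 11)[None, :]
        np.testing.assert_allclose(
            correct_oef(uncorrect_oef(oef, x), x), np.broadcast_to(oef, (21, 11)),
            atol=1e-12,
        )

    def test_correction_fixed_points(self):
        assert correct_oef(0.5, 0.0) == 0.5
        assert correct_oef(0.0516, 0.0516) == 0.0
        with pytest.raises(ValueError):
            correct_oef(0.5, 1.0)

    def test_forward_o2_chain_value(self):
        # chained evaluation: F(0.3)=0.46859, X=0.05161, OEF'=0.43097
        ci = forward_o2(0.3, 0.03, 0.4, 1.0, C)
        f = 0.3 / (0.3 / C.p + C.lam)
        x = C.hct_ratio * 0.03 / (f + C.hct_ratio * 0.03)
        expected = f * (0.4 * (1 - x) + x + C.Rm)
        assert ci == pytest.approx(expected, rel=1e-14)
        assert ci == pytest.approx(0.3022, abs=5e-4)

    def test_forward_o2_no_extraction_no_vasculature(self):
        f = tissue_water_factor(0.3, C)
        assert forward_o2(0.3, 0.0, 0.0, 1.0, C) == pytest.approx(f * C.Rm)


class TestFullRoundTrip:
    def test_recover_all_parameters_on_dense_grids(self):
        cbf, cbv, oef = np.meshgrid(CBF_GRID, CBV_GRID, OEF_GRID, indexing="ij")
        ci_co2 = forward_co2(cbf, 1.0, C)
        ci_co = forward_co(cbv, 1.0, C)
        ci_o2 = forward_o2(cbf, cbv, oef, 1.0, C)

        cbf_hat = cbf_from_co2(ci_co2, 1.0, C)
        cbv_hat = cbv_from_co(ci_co, 1.0, C)
        oefp = oef_uncorrected(ci_o2, ci_co2, 1.0, 1.0, C)
        oef_hat = correct_oef(oefp, vascular_fraction(cbf_hat, cbv_hat, C))

        np.testing.assert_allclose(cbf_hat, cbf, rtol=1e-10)
        np.testing.assert_allclose(cbv_hat, cbv, rtol=1e-10)
        np.testing.assert_allclose(oef_hat, oef, rtol=1e-10, atol=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k_co2=positive_scale, k_co=positive_scale, k_o2=positive_scale)
    def test_unit_invariance_per_tracer(self, k_co2, k_co, k_o2):
        """Rescaling each tracer's arterial+brain pair leaves estimates unchanged."""
        cbf, cbv, oef = 0.25, 0.045, 0.55
        ci_co2, ci_co = forward_co2(cbf, 1.0, C), forward_co(cbv, 1.0, C)
        ci_o2 = forward_o2(cbf, cbv, oef, 1.0, C)

        cbf_hat = cbf_from_co2(k_co2 * ci_co2, k_co2 * 1.0, C)
        cbv_hat = cbv_from_co(k_co * ci_co, k_co * 1.0, C)
        oefp = oef_uncorrected(k_o2 * ci_o2, k_co2 * ci_co2, k_o2 * 1.0, k_co2 * 1.0, C)
        oef_hat = correct_oef(oefp, vascular_fraction(cbf_hat, cbv_hat, C))

        assert cbf_hat == pytest.approx(cbf, rel=1e-9)
        assert cbv_hat == pytest.approx(cbv, rel=1e-9)
        assert oef_hat == pytest.approx(oef, rel=1e-8)


class TestCMRO2:
    def test_product_and_scaling(self):
        o2 = PhysioConstants(O2_content=0.19)
        assert cmro2(0.3, 0.4, o2) == pytest.approx(0.0228)
        assert cmro2(0.3, 0.0, o2) == 0.0
        doubled = PhysioConstants(O2_content=0.38)
        assert cmro2(0.3, 0.4, doubled) == pytest.approx(2 * cmro2(0.3, 0.4, o2))

    def test_requires_oxygen_content(self):
        with pytest.raises(ValueError, match="O2_content"):
            cmro2(0.3, 0.4, PhysioConstants())


class TestDomainTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p": 0.0},
            {"lam": -1.0},
            {"hct_ratio": 1.2},
            {"Rm": -0.1},
            {"O2_content": 0.0},
        ],
    )
    def test_constants_validation(self, kwargs):
        with pytest.raises(ValueError):
            PhysioConstants(**kwargs)

    def test_arterial_sum_consistency(self):
        ArterialConcentrations(Ca_CO2=1, Ca_CO=1, Ca_oO2=0.8, Ca_wO2=0.2, Ca_O2=1.0)
        with pytest.raises(ValueError, match="Ca_O2"):
            ArterialConcentrations(Ca_CO2=1, Ca_CO=1, Ca_oO2=0.8, Ca_wO2=0.2, Ca_O2=1.2)
        with pytest.raises(ValueError):
            ArterialConcentrations(Ca_CO2=-1, Ca_CO=1, Ca_oO2=1)
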