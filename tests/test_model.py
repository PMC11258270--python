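"""Unit and property tests for the core model equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gluchip.model import (
    Hypothesis,
    MPSGeometry,
    ModelParameters,
    H2Parameters,
    initial_state,
    insulin_sensitivity,
    ode_rhs,
    pooled_observables,
    secretion_capacity,
)

from conftest import random_params, random_state


# ---------------------------------------------------------------------------
# closed-form subexpressions


class TestInsulinSensitivity:
    def test_origin_returns_initial_value_for_every_hypothesis(self, params_h1, params_h2):
        for p in (params_h1, params_h2, params_h1.with_hypothesis(Hypothesis.LOW_HCT)):
            assert insulin_sensitivity(0.0, 0.0, p) == pytest.approx(p.fast.S_I0)

    def test_h2_vanishes_at_full_hyperglycemic_reduction(self, params_h2):
        p = params_h2.set({"fast.I_max_Si": 1.0})
        assert insulin_sensitivity(100.0, 1e12, p) == pytest.approx(0.0, abs=1e-10)

    def test_h2_half_reduction_at_ec50_time(self, params_h2):
        p = params_h2.set({"h2.I_max_additional": 1.0})
        t = p.h2.EC50_additional
        assert insulin_sensitivity(t, 0.0, p) == pytest.approx(p.fast.S_I0 / 2)

    def test_low_hct_drops_the_time_factor_but_keeps_hyperglycemia_term(self, params_h2):
        p_low = params_h2.with_hypothesis(Hypothesis.LOW_HCT)
        g_int = 200.0
        f = p_low.fast
        expected = f.S_I0 * (1 - f.I_max_Si * g_int / (f.EC50_Si + g_int))
        assert insulin_sensitivity(500.0, g_int, p_low) == pytest.approx(expected)
        assert insulin_sensitivity(500.0, g_int, params_h2) < expected

    @pytest.mark.parametrize("t,g_int", [(-1.0, 0.0), (0.0, -1.0)])
    def test_negative_inputs_rejected(self, params_h1, t, g_int):
        with pytest.raises(ValueError):
            insulin_sensitivity(t, g_int, params_h1)

    @given(
        t=st.floats(0, 1000),
        dt=st.floats(0, 500),
        g=st.floats(0, 1e4),
        dg=st.floats(0, 1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_nonincreasing_in_time_and_exposure(self, params_h2, t, dt, g, dg):
        assert insulin_sensitivity(t + dt, g, params_h2) <= insulin_sensitivity(t, g, params_h2) + 1e-15
        assert insulin_sensitivity(t, g + dg, params_h2) <= insulin_sensitivity(t, g, params_h2) + 1e-15


class TestSecretionCapacity:
    def test_initial_value_and_half_life_shape(self, params_h1):
        f = params_h1.fast
        assert secretion_capacity(0.0, params_h1) == pytest.approx(f.sigma_max)
        assert secretion_capacity(math.sqrt(f.alpha), params_h1) == pytest.approx(f.sigma_max / 2)

    def test_limits_h1_declines_low_hct_constant(self, params_h1):
        p_low = params_h1.with_hypothesis(Hypothesis.LOW_HCT)
        assert secretion_capacity(1e9, params_h1) == pytest.approx(0.0, abs=1e-6)
        assert secretion_capacity(1e9, p_low) == pytest.approx(p_low.fast.sigma_max)

    def test_negative_time_rejected(self, params_h1):
        with pytest.raises(ValueError):
            secretion_capacity(-0.1, params_h1)


# ---------------------------------------------------------------------------
# the right-hand side


def literal_rhs(y, p: ModelParameters, G_d: float = 0.0):
    """Independent, literal transcription of each printed balance
    equation, kept deliberately separate from the implementation."""
    g, f, s = p.geometry, p.fast, p.slow
    NG_l, NG_p, NI_l, NI_p, G_int, G_slow, V_beta, t = y

    if p.hypothesis is Hypothesis.H2:
        extra = 1 - p.h2.I_max_additional * t**2 / (p.h2.EC50_additional**2 + t**2)
    else:
        extra = 1.0
    S_I = f.S_I0 * (1 - f.I_max_Si * G_int / (f.EC50_Si + G_int)) * extra
    if p.hypothesis is Hypothesis.LOW_HCT:
        sigma = f.sigma_max
    else:
        sigma = f.sigma_max * (1 - t**2 / (f.alpha + t**2))

    dNG_l = (
        G_d
        + g.V_HepaRG_spheroids * f.EGP
        - g.V_HepaRG_spheroids * (f.E_G0 + S_I * NI_l / g.V_m_liver) * NG_l / g.V_m_liver
        + g.Q * NG_p / g.V_m_pancreas
        - g.Q * NG_l / g.V_m_liver
    )
    dNG_p = G_d + g.Q * NG_l / g.V_m_liver - g.Q * NG_p / g.V_m_pancreas
    G_p_conc = NG_p / g.V_m_pancreas
    dNI_p = (
        V_beta * sigma * G_p_conc**2 / (f.EC50_I**2 + G_p_conc**2)
        + g.Q * NI_l / g.V_m_liver
        - g.Q * NI_p / g.V_m_pancreas
    )
    dNI_l = (
        g.Q * NI_p / g.V_m_pancreas
        - g.Q * NI_l / g.V_m_liver
        - g.V_HepaRG_spheroids * f.k_elimination_I_spheroids * NI_l / g.V_m_liver
    )
    excess = NG_l / g.V_m_liver - f.G_normo
    dG_int = excess if excess >= 0 else 0.0
    dG_slow = (G_p_conc - G_slow) / s.tau_slow
    dV_beta = s.k_v * (-s.d_0 + s.r1 * G_slow - s.r2 * G_slow**2) * V_beta
    return np.array([dNG_l, dNG_p, dNI_l, dNI_p, dG_int, dG_slow, dV_beta, 1.0])


class TestOdeRhs:
    def test_zero_state_sign_structure(self, params_h1):
        s = params_h1.slow
        y = np.array([0, 0, 0, 0, 0, 0, s.V_beta_0, 0.0])
        dy = ode_rhs(y, params_h1)
        assert dy[0] == 0 and dy[1] == 0  # no glucose anywhere
        assert dy[3] == 0  # Hill term vanishes at G = 0
        assert dy[6] == pytest.approx(-s.k_v * s.d_0 * s.V_beta_0)
        assert dy[7] == 1.0

    def test_inert_parameters_freeze_all_amounts(self, params_h1):
        p = params_h1.set(
            {
                "geometry.Q": 1e-30,
                "fast.E_G0": 0.0,
                "fast.S_I0": 0.0,
                "fast.sigma_max": 0.0,
                "fast.k_elimination_I_spheroids": 0.0,
            }
        )
        rng = np.random.default_rng(0)
        dy = ode_rhs(random_state(rng), p)
        assert np.allclose(dy[:4], 0.0, atol=1e-25)

    @pytest.mark.parametrize("hypothesis", [Hypothesis.H1, Hypothesis.H2, Hypothesis.LOW_HCT])
    def test_matches_literal_equation_transcription(self, hypothesis):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_params(rng, hypothesis)
            y = random_state(rng)
            got = ode_rhs(y, p)
            want = literal_rhs(y, p)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-30)

    def test_euler_step_equals_literal_prediction(self, params_h2):
        rng = np.random.default_rng(7)
        y = random_state(rng)
        h = 1e-3
        np.testing.assert_allclose(
            y + h * ode_rhs(y, params_h2), y + h * literal_rhs(y, params_h2), rtol=1e-12
        )

    def test_nonfinite_state_rejected(self, params_h1):
        y = np.ones(8)
        y[3] = np.nan
        with pytest.raises(ValueError):
            ode_rhs(y, params_h1)


# ---------------------------------------------------------------------------
# observables and initial conditions


class TestPooledObservables:
    def test_equal_concentrations_pass_through(self):
        g = MPSGeometry()
        y = np.array([7 * g.V_m_liver, 7 * g.V_m_pancreas, 3 * g.V_m_liver, 3 * g.V_m_pancreas, 0, 0, 1e-9, 0])
        G, I = pooled_observables(y, g)
        assert G == pytest.approx(7.0) and I == pytest.approx(3.0)

    def test_degenerate_weighting_reads_one_compartment(self):
        g = MPSGeometry(V_sample_pancreas=1e-30)
        y = np.array([10 * g.V_m_liver, 6 * g.V_m_pancreas, 0, 0, 0, 0, 1e-9, 0])
        G, _ = pooled_observables(y, g)
        assert G == pytest.approx(10.0)

    def test_equal_sample_volumes_give_arithmetic_mean(self):
        g = MPSGeometry()  # 15 ul + 15 ul draws
        y = np.array([10 * g.V_m_liver, 6 * g.V_m_pancreas, 0, 0, 0, 0, 1e-9, 0])
        G, _ = pooled_observables(y, g)
        assert G == pytest.approx(8.0)


class TestInitialState:
    def test_glucose_load_without_offsets(self, params_h1):
        y = initial_state(params_h1, 11.0)
        g = params_h1.geometry
        assert y[0] == pytest.approx(11.0 * g.V_m_liver)
        assert y[2] == 0.0 and y[3] == 0.0

    def test_fixed_slow_initials(self, params_h1):
        y = initial_state(params_h1, 5.5)
        assert y[5] == pytest.approx(5.5)  # long-term average starts normoglycemic
        assert y[6] == pytest.approx(8.8e-9)
        assert y[4] == 0.0 and y[7] == 0.0

    def test_insulin_offset_fills_both_compartments(self, params_h1):
        p = params_h1.set({"offsets.dI_d1": 2.0})
        y = initial_state(p, 11.0)
        assert y[3] == pytest.approx(2.0 * p.geometry.V_m_pancreas)


# ---------------------------------------------------------------------------
# parameter container


class TestModelParameters:
    def test_h2_block_present_iff_h2(self, params_h1, params_h2):
        assert params_h1.h2 is None
        assert params_h2.h2 is not None
        with pytest.raises(ValueError):
            ModelParameters(hypothesis=Hypothesis.H1, h2=H2Parameters())

    def test_dotted_get_set_round_trip(self, params_h1):
        p = params_h1.set({"fast.S_I0": 0.5, "slow.tau_slow": 12.0})
        assert p.get("fast.S_I0") == 0.5
        assert p.get("slow.tau_slow") == 12.0
        assert params_h1.get("fast.S_I0") != 0.5  # original untouched

    def test_invalid_values_rejected(self):
        from gluchip.model import FastParameters, OffsetParameters

        with pytest.raises(ValueError):
            FastParameters(I_max_Si=1.5)
        with pytest.raises(ValueError):
            FastParameters(E_G0=-1.0)
        with pytest.raises(ValueError):
            OffsetParameters(dI_d1=-0.5)
        with pytest.raises(ValueError):
            MPSGeometry(Q=0.0)
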