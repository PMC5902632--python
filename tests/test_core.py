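"""Forward-model tests: generator structure, propagation, R1rho extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hoogfit.core import (
    DecayCurve,
    ExchangeModel,
    FieldContext,
    SpinlockCondition,
    build_bm_generator,
    effective_field,
    exchange_contribution,
    initial_state,
    larmor_frequency,
    r1rho_profile,
    simulate_decay,
    simulate_r1rho,
)


class TestLarmor:
    @pytest.mark.parametrize(
        "nucleus,expected",
        [("H1", 700.0), ("C13", 0.2514495 * 700), ("N15", 0.1013664 * 700)],
    )
    def test_published_ratios(self, nucleus, expected):
        assert larmor_frequency(nucleus, 700.0) == pytest.approx(expected, rel=1e-12)

    def test_unknown_nucleus_rejected(self):
        with pytest.raises(ValueError, match="unknown nucleus"):
            larmor_frequency("P31", 700.0)


class TestEffectiveField:
    def test_on_resonance_is_90_degrees(self):
        w, tilt = effective_field(1000.0, 0.0)
        assert w == pytest.approx(2 * np.pi * 1000)
        assert tilt == pytest.approx(90.0)

    def test_equal_power_and_offset_gives_45(self):
        w, tilt = effective_field(1000.0, 1000.0)
        assert w == pytest.approx(2 * np.pi * np.sqrt(2) * 1000)
        assert tilt == pytest.approx(45.0)

    def test_far_downfield_tilt_approaches_180(self):
        w, tilt = effective_field(150.0, -3000.0)
        assert w == pytest.approx(2 * np.pi * 3003.7, rel=1e-4)
        assert 177.0 < tilt < 180.0

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError, match="lock"):
            effective_field(0.0, 500.0)


class TestGenerator:
    def test_forward_backward_rates_from_printed_parameters(self):
        # p_b and k_ex as reported for the bound A3-T10 pair at 10 C
        m = ExchangeModel(0.0207, 743.0, 3.0)
        assert m.k1 == pytest.approx(15.3801)
        assert m.k_minus1 == pytest.approx(727.6199)
        assert m.k1 + m.k_minus1 == pytest.approx(m.k_ex, abs=0)

    def test_no_exchange_reduces_to_single_spin_block(self, field_c13):
        cond = SpinlockCondition(800.0, 300.0, field_c13)
        m = ExchangeModel(0.0, 0.0, 2.0, r1=1.5, r2=22.0)
        L = build_bm_generator(m, cond)
        off = 2 * np.pi * 300.0
        w1 = 2 * np.pi * 800.0
        expected = np.array(
            [[-22.0, -off, 0.0], [off, -22.0, -w1], [0.0, w1, -1.5]]
        )
        np.testing.assert_allclose(L[:3, :3], expected, rtol=1e-12)
        assert np.all(L[:3, 3:] == 0) and np.all(L[3:, :3] == 0)

    def test_exchange_blocks_carry_k1_and_kminus1(self, field_c13):
        m = ExchangeModel(0.02, 1000.0, 3.0)
        L = build_bm_generator(m, SpinlockCondition(500.0, 100.0, field_c13))
        np.testing.assert_allclose(np.diag(L[:3, 3:]), m.k_minus1)
        np.testing.assert_allclose(np.diag(L[3:, :3]), m.k1)

    def test_rate_free_generator_annihilates_aligned_state(self, field_c13):
        # pure rotation about the effective field leaves a parallel state fixed
        m = ExchangeModel(0.2, 0.0, 0.0, r1=0.0, r2=0.0)
        cond = SpinlockCondition(700.0, 400.0, field_c13)
        L = build_bm_generator(m, cond)
        v = np.asarray(initial_state(m, cond).vector)
        np.testing.assert_allclose(L @ v, 0.0, atol=1e-10)


def _rk4_step_doubling(L, m0, t_end, tol=1e-10):
    """Independent brute-force propagator: classic RK4 with step halving."""

    def rk4(y, h, n):
        for _ in range(n):
            k1 = L @ y
            k2 = L @ (y + 0.5 * h * k1)
            k3 = L @ (y + 0.5 * h * k2)
            k4 = L @ (y + h * k3)
            y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        return y

    n = 64
    prev = rk4(m0.copy(), t_end / n, n)
    while True:
        n *= 2
        cur = rk4(m0.copy(), t_end / n, n)
        if np.max(np.abs(cur - prev)) < tol or n > 2**18:
            return cur
        prev = cur


class TestSimulateDecay:
    def test_delay_zero_intensity_is_one(self, field_c13):
        m = ExchangeModel(0.05, 2000.0, -2.5, r1=1.0, r2=30.0)
        cond = SpinlockCondition(300.0, -700.0, field_c13, delays=(0.0, 0.02, 0.04))
        dc = simulate_decay(m, cond)
        assert dc.intensities[0] == pytest.approx(1.0, abs=1e-12)

    def test_pure_transverse_decay_without_exchange(self, field_c13):
        # on resonance, dw = 0: I(t) = exp(-R2 t) exactly
        m = ExchangeModel(0.0, 0.0, 0.0, r1=2.0, r2=20.0)
        cond = SpinlockCondition(1000.0, 0.0, field_c13)
        dc = simulate_decay(m, cond)
        np.testing.assert_allclose(
            dc.intensities, np.exp(-20.0 * np.asarray(cond.delays)), rtol=1e-10
        )

    @pytest.mark.parametrize(
        "p_b,k_ex,dw,omega_sl,offset,alignment",
        [
            (0.0207, 743.0, 3.0, 400.0, -520.0, "ground"),
            (0.0024, 5411.0, 3.0, 1000.0, 0.0, "ground"),
            (0.08, 600.0, -2.0, 200.0, 350.0, "average"),
        ],
    )
    def test_matches_step_doubling_ode_oracle(self, field_c13, p_b, k_ex, dw, omega_sl, offset, alignment):
        m = ExchangeModel(p_b, k_ex, dw, r1=2.5, r2=25.0)
        cond = SpinlockCondition(omega_sl, offset, field_c13, alignment, (0.0, 0.02, 0.05))
        dc = simulate_decay(m, cond)
        L = build_bm_generator(m, cond)
        m0 = np.asarray(initial_state(m, cond).vector)
        n3 = m0[:3] / (1 - m.p_b)  # unit alignment axis (m0 GS block = p_a * n)
        axis6 = np.concatenate([n3, n3])
        for t, obs in zip(cond.delays[1:], dc.intensities[1:]):
            ref = axis6 @ _rk4_step_doubling(L, m0, t)
            assert obs == pytest.approx(ref, abs=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        p_b=st.floats(1e-4, 0.4),
        k_ex=st.floats(50.0, 2e4),
        dw=st.floats(-6.0, 6.0),
        omega_sl=st.floats(100.0, 3500.0),
        offset=st.floats(-4000.0, 4000.0),
    )
    def test_unit_initial_intensity_property(self, p_b, k_ex, dw, omega_sl, offset):
        fld = FieldContext(700.0, "C13")
        m = ExchangeModel(p_b, k_ex, dw)
        cond = SpinlockCondition(omega_sl, offset, fld, delays=(0.0, 0.03))
        dc = simulate_decay(m, cond)
        assert dc.intensities[0] == pytest.approx(1.0, abs=1e-12)
        assert all(np.isfinite(dc.intensities))


class TestR1rho:
    def test_no_exchange_closed_form(self, field_c13):
        # R1rho = R1 cos^2(theta) + R2 sin^2(theta); theta = 45 deg at high
        # power, where non-secular R1/R2 mixing is negligible
        m = ExchangeModel(0.0, 0.0, 0.0, r1=2.0, r2=20.0)
        cond = SpinlockCondition(20000.0, 20000.0, field_c13)
        assert simulate_r1rho(m, cond) == pytest.approx(11.0, abs=1e-6)
        assert simulate_r1rho(m, cond, method="eigen") == pytest.approx(11.0, abs=1e-6)

    def test_fast_exchange_closed_form(self, field_c13):
        # k_ex >> dw: Rex = sin^2(theta) pa pb dw^2 kex / (kex^2 + weff^2)
        dw_rads = 2 * np.pi * 200.0
        dw_ppm = dw_rads / (2 * np.pi * field_c13.larmor_frequency)
        m = ExchangeModel(0.05, 1e5, dw_ppm, r1=2.0, r2=20.0)
        for omega_sl in (500.0, 1000.0, 2000.0):
            cond = SpinlockCondition(omega_sl, 0.0, field_c13)
            rex = exchange_contribution(m, [cond])[0]
            weff = 2 * np.pi * omega_sl
            pred = 0.05 * 0.95 * dw_rads**2 * 1e5 / (1e5**2 + weff**2)
            assert rex == pytest.approx(pred, rel=0.02)

    def test_expfit_and_eigen_methods_agree(self, field_c13):
        m = ExchangeModel(0.01, 1000.0, 3.0, r1=2.5, r2=25.0)
        offsets = np.linspace(-1200, 1200, 20)
        conds = [SpinlockCondition(400.0, o, field_c13) for o in offsets]
        r_fit = r1rho_profile(m, conds, "expfit")
        r_eig = r1rho_profile(m, conds, "eigen")
        np.testing.assert_allclose(r_fit, r_eig, rtol=0.01)

    def test_flat_dispersion_without_exchange(self, field_c13):
        # with p_b = 0 the exchange contribution vanishes at every offset
        m = ExchangeModel(0.0, 0.0, 3.0, r1=2.0, r2=20.0)
        conds = [SpinlockCondition(800.0, o, field_c13) for o in np.linspace(-2000, 2000, 15)]
        rex = exchange_contribution(m, conds)
        assert np.max(np.abs(rex)) < 1e-6

    def test_exchange_contribution_nonnegative(self, field_c13):
        models = [
            ExchangeModel(0.01, 500.0, 3.0, r1=2.0, r2=22.0),
            ExchangeModel(0.03, 3000.0, -2.0, r1=1.0, r2=30.0),
            ExchangeModel(0.002, 10000.0, 4.0, r1=3.0, r2=18.0),
        ]
        conds = [
            SpinlockCondition(p, o, field_c13)
            for p in (150.0, 600.0, 2000.0)
            for o in np.linspace(-2500, 2500, 11)
        ]
        for m in models:
            rex = exchange_contribution(m, conds, method="eigen")
            assert np.min(rex) > -1e-8

    def test_average_alignment_relabeling_invariance(self, field_c13):
        """Swapping state labels (and re-referencing offsets to keep the
        population-averaged shift fixed) must not change simulated R1rho."""
        m = ExchangeModel(0.3, 800.0, 2.0, r1=2.0, r2=24.0)
        dw_hz = field_c13.ppm_to_hz(m.delta_omega)
        offsets = np.linspace(-900, 900, 7)
        for off in offsets:
            c1 = SpinlockCondition(300.0, off, field_c13, "average")
            c2 = SpinlockCondition(300.0, off + dw_hz, field_c13, "average")
            with pytest.warns(UserWarning, match="majority"):
                m2 = ExchangeModel(1 - m.p_b, m.k_ex, -m.delta_omega, m.r1, m.r2)
            r1a = simulate_r1rho(m, c1)
            r1b = simulate_r1rho(m2, c2)
            assert r1a == pytest.approx(r1b, abs=1e-6)

    def test_slow_exchange_rex_peaks_at_excited_state_resonance(self, field_c13):
        # the dispersion asymmetry that signs delta_omega: in the plotted
        # coordinate (R2 + Rex, i.e. Rex divided by the sin^2 of the tilt)
        # the maximum sits at the excited-state resonance offset -dw
        m = ExchangeModel(0.01, 200.0, 3.0, r1=2.5, r2=25.0)
        dw_hz = field_c13.ppm_to_hz(3.0)
        step = 50.0
        offsets = np.arange(-1000.0, 1000.0 + step, step)
        conds = [SpinlockCondition(300.0, o, field_c13) for o in offsets]
        rex = exchange_contribution(m, conds, method="eigen")
        sin2 = np.sin(np.arctan2(300.0, offsets)) ** 2
        peak = offsets[np.argmax(rex / sin2)]
        assert abs(peak - (-dw_hz)) <= step
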