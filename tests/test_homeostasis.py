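import math

import numpy as np
import pytest

from wchomeo import (
    WCParams,
    HomeostasisSpec,
    Mode,
    solve,
    residual,
    rE_nullcline,
    rI_nullcline,
    jacobian,
    sigmoid,
    simulate_homeostatic_odes,
)
from wchomeo.homeostasis import (
    ADAPTED,
    UnsupportedConfigurationError,
    solve_GE_cEI,
)

ALL_MODES = list(Mode)


class TestClosedFormInversion:
    def test_gain_solver_hand_value(self, spec):
        # (cEI*F_I(1.875) + muE) / (cEE/2) with F_I(1.875) = 1/(1+e^-3.5)
        sol = solve("GE", 0.5, 0.0, spec)
        expect = (2.5 / (1 + math.exp(-3.5)) + 1.0) / 1.75
        assert sol.solved["GE"] == pytest.approx(expect, rel=1e-9)
        assert sol.solved["GE"] == pytest.approx(1.95813, abs=1e-5)

    @pytest.mark.parametrize("mode", ALL_MODES, ids=[m.value for m in ALL_MODES])
    def test_residual_zero_inversion(self, mode, spec):
        """Every feasible solution makes the target an exact fixed point."""
        rng = np.random.default_rng(1234)
        n_feasible = 0
        for _ in range(150):
            target = rng.uniform(0.02, 0.6)
            Iext = rng.uniform(0.0, 4.0)
            sol = solve(mode, target, Iext, spec)
            if not sol.feasible:
                continue
            n_feasible += 1
            assert abs(float(residual(target, sol.params))) < 1e-9
        assert n_feasible > 50  # the feasible region is not degenerate

    def test_infeasible_low_targets_are_flagged_not_clamped(self, spec):
        # very low target at high drive requires negative gain
        sol = solve("GE", 0.003, 0.0, spec)
        assert not sol.feasible and "GE" in sol.clamped
        assert sol.solved["GE"] < 0  # the raw value is reported

    def test_cIE_saturation_at_high_input(self, spec):
        """Feedback inhibition saturates: the required inhibitory rate
        exceeds 1 at strong drive, so this mode breaks down there."""
        sol = solve("CIE", 0.1, 6.0, spec)
        assert not sol.feasible
        assert "rI_required_high" in sol.clamped

    def test_cIE_nullcline_consistency(self, spec):
        """The required inhibitory rate matches an independent drift root."""
        from scipy.optimize import brentq
        from wchomeo import drift
        p = spec.baseline.replace(Iext=1.0)
        y_null = float(rE_nullcline(0.2, p))
        y_root = brentq(lambda rI: float(drift(0.2, rI, p)[0]), 1e-9, 1 - 1e-9,
                        xtol=1e-14)
        assert y_null == pytest.approx(y_root, abs=1e-10)

    def test_closed_form_requires_plain_circuit(self):
        spec = HomeostasisSpec(baseline=WCParams(cII=0.5))
        with pytest.raises(UnsupportedConfigurationError):
            solve("GE", 0.2, 1.0, spec)


class TestModeStructure:
    def test_cEI_increasing_in_input(self, spec):
        vals = [solve("CEI", 0.15, I, spec).solved["cEI"]
                for I in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(vals) > 0)

    def test_threshold_shift_is_affine_in_input(self, spec):
        """muE moves by exactly GE*dIext, leaving the Jacobian unchanged."""
        a = solve("MUE", 0.2, 1.0, spec)
        b = solve("MUE", 0.2, 3.5, spec)
        assert b.solved["muE"] - a.solved["muE"] == pytest.approx(2.5, rel=1e-12)
        rI = float(rI_nullcline(0.2, a.params))
        Ja = jacobian(0.2, rI, a.params)
        Jb = jacobian(0.2, float(rI_nullcline(0.2, b.params)), b.params)
        assert np.allclose(Ja, Jb, atol=1e-14)

    def test_zero_input_output_preserved_by_slope_threshold_mode(self, spec):
        sol = solve("MUE_SIGMAE", 0.3, 2.0, spec)
        before = float(sigmoid(0.0, spec.baseline.muE, spec.baseline.sigmaE))
        after = float(sigmoid(0.0, sol.params.muE, sol.params.sigmaE))
        assert after == pytest.approx(before, rel=1e-12)
        assert sol.params.sigmaE / sol.params.muE == pytest.approx(0.25)

    def test_joint_scaling_conservation_laws(self, spec):
        b = spec.baseline
        s2 = solve("GE_CEI", 0.18, 2.0, spec)
        assert s2.solved["GE"] - b.GE == pytest.approx(
            -(s2.solved["cEI"] - b.cEI), rel=1e-12)
        s3 = solve("GE_CEI_MUE", 0.18, 2.0, spec)
        # equal timescales force equal-magnitude displacements:
        # GE-GE0 = -(cEI-cEI0) = -(muE-muE0)
        d = s3.solved["muE"] - b.muE
        assert s3.solved["GE"] == pytest.approx(b.GE - d, rel=1e-12)
        assert s3.solved["cEI"] == pytest.approx(b.cEI + d, rel=1e-12)

    def test_trace_invariant_across_input_for_subtractive_modes(self, spec):
        """CEI and MUE leave GE, cEE, sigmaE untouched, so the Jacobian
        trace at the solved point depends on the target alone."""
        for mode in ("CEI", "MUE"):
            traces = []
            for I in (0.5, 1.0, 2.0, 4.0):
                sol = solve(mode, 0.1, I, spec)
                rI = float(rI_nullcline(0.1, sol.params))
                traces.append(float(np.trace(jacobian(0.1, rI, sol.params))))
            assert max(traces) - min(traces) < 1e-12

    def test_combined_modes_shrink_inhibitory_excursions(self, spec):
        """Joint scaling needs far less cEI modulation than CEI alone."""
        for rho, I in [(0.1, 2.0), (0.05, 4.0), (0.15, 3.0)]:
            alone = solve("CEI", rho, I, spec).solved["cEI"]
            joint = solve("GE_CEI", rho, I, spec).solved["cEI"]
            assert abs(joint - 2.5) < abs(alone - 2.5)

    def test_combined_slope_mode_extends_feasibility_to_lower_targets(self, spec):
        """Combining slope/threshold plasticity with synaptic scaling
        reaches targets that slope/threshold plasticity alone cannot."""
        floor_alone = floor_combined = None
        for rho in np.arange(0.001, 0.1, 0.001):
            if floor_alone is None and solve("MUE_SIGMAE", float(rho), 2.0,
                                             spec).feasible:
                floor_alone = rho
            if floor_combined is None and solve("GE_CEI_MUE_SIGMAE", float(rho),
                                                2.0, spec).feasible:
                floor_combined = rho
        assert floor_combined < floor_alone

    def test_unequal_timescale_constraint(self, spec):
        sol = solve_GE_cEI(0.1, 2.0, spec, timescale_ratio=2.0)
        b = spec.baseline
        assert sol.solved["GE"] - b.GE == pytest.approx(
            -2.0 * (sol.solved["cEI"] - b.cEI), rel=1e-10)
        assert abs(float(residual(0.1, sol.params))) < 1e-9


class TestDynamicHomeostasis:
    def test_gain_loop_recovers_closed_form(self):
        spec = HomeostasisSpec(tau_homeo=50.0)
        res = simulate_homeostatic_odes("GE", 0.1, 2.0, spec, dt=0.2,
                                        duration=60_000.0)
        sol = solve("GE", 0.1, 2.0, spec)
        assert res.converged
        assert res.final_params.GE == pytest.approx(sol.params.GE, abs=1e-6)

    def test_joint_loop_preserves_opposite_displacements(self):
        """Equal-timescale dynamics keep GE-GE0 = -(cEI-cEI0) throughout."""
        spec = HomeostasisSpec(tau_homeo=50.0)
        res = simulate_homeostatic_odes("GE_CEI", 0.1, 2.0, spec, dt=0.2,
                                        duration=60_000.0)
        dG = res.series["GE"] - 1.0
        dC = res.series["cEI"] - 2.5
        assert np.max(np.abs(dG + dC)) < 1e-9

    def test_unequal_timescales_match_weighted_closed_form(self):
        spec = HomeostasisSpec(tau_homeo=100.0)
        res = simulate_homeostatic_odes(
            "GE_CEI", 0.1, 2.0, spec, dt=0.2, duration=100_000.0,
            timescales={"GE": 100.0, "cEI": 200.0})
        sol = solve_GE_cEI(0.1, 2.0, spec, timescale_ratio=2.0)
        assert res.final_params.GE == pytest.approx(sol.params.GE, abs=1e-6)
        assert res.final_params.cEI == pytest.approx(sol.params.cEI, abs=1e-6)

    def test_rejects_fast_homeostasis(self, spec):
        with pytest.raises(ValueError):
            simulate_homeostatic_odes("GE", 0.1, 2.0,
                                      HomeostasisSpec(tau_homeo=20.0))
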