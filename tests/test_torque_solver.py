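"""Equation assembly, bounded minimum-norm solving, spillover iteration,
and work rebalancing."""

import numpy as np
import pytest

import stiffarm as sa
from stiffarm.arm_model import JointConfig
from stiffarm.calibration import SamplingGrid, calibrate
from stiffarm.torque_solver import (EquationSystem, SystemCurves,
                                    build_system, iterate_spillover,
                                    iterate_spillover_batch, rebalance,
                                    residual, solve_bounded_min_norm,
                                    system_curves)

from conftest import random_equation_system


def make_system(x, A):
    x = np.asarray(x, dtype=float)
    A = np.asarray(A, dtype=float)
    return EquationSystem(x, A, 8.0, np.array([50.0, 75.0]),
                          tuple(f"e{j}" for j in range(A.shape[1])))


class TestBuildSystem:
    def test_rows_are_stiffness_minus_passive(self, calib20):
        system = build_system(JointConfig(50.0, 75.0), 8.0, calib20)
        pf, pe = calib20.passive_at(np.array([[50.0, 75.0]]))
        expect = [8.0 - pf[0, 0], -8.0 - pe[0, 0],
                  8.0 - pf[0, 1], -8.0 - pe[0, 1]]
        assert system.x == pytest.approx(expect)

    def test_zero_passive_gives_symmetric_targets(self, calib20):
        # mid-workspace: the one-sided passive components cancel but are
        # individually tiny, so x is close to (S, -S, S, -S)
        system = build_system(JointConfig(50.0, 75.0), 8.0, calib20)
        assert system.x == pytest.approx([8, -8, 8, -8], abs=0.5)

    def test_sign_structure(self, calib20):
        system = build_system(JointConfig(35.0, 60.0), 8.0, calib20)
        assert np.all(system.A[[0, 2]] >= 0)
        assert np.all(system.A[[1, 3]] <= 0)
        # at least half the entries vanish (one action row per joint)
        assert (system.A == 0).sum() >= system.A.size / 2

    def test_biceps_column_in_both_flexion_rows(self, calib20):
        system = build_system(JointConfig(35.0, 60.0), 8.0, calib20)
        j = system.column_labels.index("biceps")
        assert system.A[0, j] > 0 and system.A[2, j] > 0
        assert system.A[1, j] == 0 and system.A[3, j] == 0

    def test_adjustment_halves_one_column_only(self, calib20):
        base = build_system(JointConfig(35.0, 60.0), 8.0, calib20)
        adj = build_system(JointConfig(35.0, 60.0), 8.0, calib20,
                           adjustments={"anterior_deltoid": 0.5})
        j = base.column_labels.index("anterior_deltoid")
        assert adj.A[:, j] == pytest.approx(0.5 * base.A[:, j])
        rest = [k for k in range(6) if k != j]
        assert np.array_equal(adj.A[:, rest], base.A[:, rest])

    def test_nonpositive_stiffness_rejected(self, calib20):
        with pytest.raises(ValueError):
            build_system(JointConfig(35.0, 60.0), 0.0, calib20)


class TestBoundedMinNorm:
    def test_closed_form_redundant_flexors(self):
        # one joint: flexors (10, 10), extensor -15, targets (5, -5);
        # Lagrange closed form c_i = a_i T / sum(a^2) per independent row
        system = make_system([5.0, -5.0, 0.0, 0.0],
                             [[10.0, 10.0, 0.0],
                              [0.0, 0.0, -15.0],
                              [0.0, 0.0, 0.0],
                              [0.0, 0.0, 0.0]])
        sv = solve_bounded_min_norm(system)
        assert sv.c == pytest.approx([0.25, 0.25, 1.0 / 3.0], abs=1e-10)
        assert sv.residual_norm < 1e-10
        assert not sv.infeasible

    def test_forced_saturation_clamps_at_one(self):
        system = make_system([12.0, 0.0, 0.0, 0.0],
                             [[10.0], [0.0], [0.0], [0.0]])
        sv = solve_bounded_min_norm(system)
        assert sv.c[0] == 1.0
        assert sv.status[0] == "clamped_one"
        assert sv.residual_norm == pytest.approx(2.0)
        assert sv.infeasible

    def test_muscles_cannot_push(self):
        # stiffness below net passive flexion: flexion target negative with
        # only flexor columns in that row -> flexor shut off, infeasible
        system = make_system([-1.5, 0.0, 0.0, 0.0],
                             [[10.0], [0.0], [0.0], [0.0]])
        sv = solve_bounded_min_norm(system)
        assert sv.c[0] == 0.0
        assert sv.status[0] == "clamped_zero"
        assert sv.infeasible

    def test_zero_columns_dropped(self):
        system = make_system([5.0, -5.0, 0.0, 0.0],
                             [[10.0, 0.0], [0.0, 0.0],
                              [0.0, 0.0], [0.0, 0.0]])
        sv = solve_bounded_min_norm(system)
        assert sv.status[1] == "dropped"
        assert sv.c[1] == 0.0

    def test_bounds_always_respected(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            sv = solve_bounded_min_norm(random_equation_system(rng))
            assert np.all(sv.c >= 0.0) and np.all(sv.c <= 1.0)

    def test_interior_torque_balance(self, calib20):
        system = build_system(JointConfig(55.0, 80.0), 8.0, calib20)
        sv = solve_bounded_min_norm(system)
        assert sv.interior
        r = system.A @ sv.c - system.x
        assert np.abs(r).max() < 1e-9


class TestSpilloverIteration:
    def test_uniform_ratio_converges_immediately(self, calib20):
        q = JointConfig(35.0, 60.0)
        system = build_system(q, 8.0, calib20)
        res = iterate_spillover(system, system_curves(calib20, q))
        assert res.converged and res.iterations == 1
        # A-matrix entries for the biarticular channels are unchanged, so
        # the solution equals the plain bounded solve
        sv = solve_bounded_min_norm(system)
        assert res.scales.c == pytest.approx(sv.c, abs=1e-9)

    def test_secondary_entry_replaced_by_curve_ratio(self):
        # constructed single-channel case: first solve yields c = 0.9;
        # at the implied stimulation the secondary joint produces 20 %
        # (not 50 %) of the reference torque, so the next A uses 0.2*max
        u = np.linspace(0, 1, 101)
        t_ref = 10.0 * u                          # linear reference curve
        t_sec = np.where(u <= 0.9, 2.0 * u, 1.8 + 32.0 * (u - 0.9))
        curves = SystemCurves(u, np.stack([np.stack([t_sec, t_ref], axis=1)]),
                              np.array([1]))
        system = make_system([4.5, 0.0, 9.0, 0.0],
                             [[5.0], [0.0], [10.0], [0.0]])
        first = solve_bounded_min_norm(system)
        assert first.c[0] == pytest.approx(0.9)
        res = iterate_spillover(system, curves, max_iter=2)
        # after one update the secondary entry is (1.8/9) * 10 = 2, so the
        # second solve works on A = [[2], [0], [10], [0]]
        expect = (2.0 * 4.5 + 10.0 * 9.0) / (4.0 + 100.0)
        assert res.scales.c[0] == pytest.approx(expect, abs=1e-9)
        _, r1 = residual(system, first.c, curves)
        assert r1 > 0.1  # the standard solution misses the secondary joint

    def test_batch_matches_per_system(self):
        arm = sa.make_spillover_arm("B")
        grid = SamplingGrid((15, 85, 20), (20, 130, 20),
                            (3.0, 8.0, 13.0))
        calib = calibrate(arm, grid)
        batch = iterate_spillover_batch(calib, grid.stiffness_nm)
        cfgs = grid.configs()
        nk = len(grid.stiffness_nm)
        for si in [0, 10, 25, 41, 70]:
            q = cfgs[si // nk]
            S = grid.stiffness_nm[si % nk]
            res = iterate_spillover(build_system(q, S, calib),
                                    system_curves(calib, q))
            assert res.iterations == batch.iterations[si]
            assert res.scales.c == pytest.approx(batch.c[si], abs=1e-12)
            assert res.final_residual == pytest.approx(
                batch.final_residual[si], abs=1e-9)

    def test_residual_identity_without_curves(self, calib20):
        system = build_system(JointConfig(55.0, 80.0), 8.0, calib20)
        sv = solve_bounded_min_norm(system)
        r, rn = residual(system, sv.c)
        assert r == pytest.approx(system.A @ sv.c - system.x)
        assert rn < 1e-9

    def test_curve_residual_agrees_for_uniform_channels(self, calib20):
        # on the default arm the curves are exactly what the A matrix says,
        # so the curve-based residual matches the linear one
        q = JointConfig(55.0, 80.0)
        system = build_system(q, 8.0, calib20)
        sv = solve_bounded_min_norm(system)
        _, rn = residual(system, sv.c, system_curves(calib20, q))
        assert rn < 1e-3


class TestRebalance:
    def test_identity_factors_change_nothing(self, calib20):
        plan = rebalance(calib20, np.ones(6))
        q = JointConfig(45.0, 70.0)
        a = solve_bounded_min_norm(plan.build(q, 8.0))
        b = solve_bounded_min_norm(build_system(q, 8.0, calib20))
        assert a.c == pytest.approx(b.c, abs=1e-12)

    def test_closed_form_with_half_scaled_flexor(self):
        # one joint, flexors (10, 10), target 8, alpha = (0.5, 1):
        # scaled maxima (5, 10) -> c = (0.32, 0.64); realised torques
        # c*alpha*max = (1.6, 6.4) still sum to 8
        system = make_system([8.0, 0.0, 0.0, 0.0],
                             [[5.0, 10.0], [0, 0], [0, 0], [0, 0]])
        sv = solve_bounded_min_norm(system)
        assert sv.c == pytest.approx([0.32, 0.64], abs=1e-12)
        realized = sv.c * np.array([0.5, 1.0]) * 10.0
        assert realized == pytest.approx([1.6, 6.4])
        assert realized.sum() == pytest.approx(8.0)

    def test_scenario_11_halves_both_biarticular_columns(self, calib20):
        plan = rebalance(calib20, {"biceps": 0.5, "triceps_long": 0.5})
        q = JointConfig(45.0, 70.0)
        base = build_system(q, 8.0, calib20)
        adj = plan.build(q, 8.0)
        for name in ("biceps", "triceps_long"):
            j = base.column_labels.index(name)
            assert adj.A[:, j] == pytest.approx(0.5 * base.A[:, j])

    def test_rebalanced_norm_not_smaller_on_original_system(self, calib20):
        # shifting work off a muscle moves away from the minimum-norm point
        rng = np.random.default_rng(3)
        for _ in range(20):
            q = JointConfig(rng.uniform(20, 80), rng.uniform(25, 125))
            S = rng.uniform(3, 13)
            std = solve_bounded_min_norm(build_system(q, S, calib20))
            plan = rebalance(calib20, {"anterior_deltoid": 0.5})
            adj = solve_bounded_min_norm(plan.build(q, S))
            if std.interior and adj.interior:
                # express the adjusted c on the original columns
                c_equiv = adj.c * plan.factors
                assert (np.linalg.norm(c_equiv)
                        >= np.linalg.norm(std.c) - 1e-9)

    def test_invalid_factors_rejected(self, calib20):
        with pytest.raises(ValueError):
            rebalance(calib20, {"biceps": 0.0})
        with pytest.raises(ValueError):
            rebalance(calib20, {"biceps": 1.5})
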