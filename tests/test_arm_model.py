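"""Plant behaviour: kinematics, torque components, equilibrium, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stiffarm as sa
from stiffarm.arm_model import FatigueState, JointConfig


class TestKinematics:
    @pytest.mark.parametrize("sho,elb,expected", [
        (0.0, 0.0, (78.0, 0.0)),          # fully extended chain
        (90.0, 0.0, (0.0, 78.0)),         # quarter-turn rotation
        # independent trigonometric evaluation:
        # 33*cos30+45*cos90, 33*sin30+45*sin90
        (30.0, 60.0, (33 * np.cos(np.pi / 6) + 45 * np.cos(np.pi / 2),
                      33 * np.sin(np.pi / 6) + 45 * np.sin(np.pi / 2))),
    ])
    def test_forward_kinematics_matches_trigonometry(self, default_arm,
                                                     sho, elb, expected):
        xy = default_arm.forward_kinematics(JointConfig(sho, elb))
        assert xy == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(16, 84), st.floats(21, 129))
    def test_inverse_kinematics_round_trips(self, sho, elb):
        arm = sa.make_default_arm()
        xy = arm.forward_kinematics(JointConfig(sho, elb))
        cfg = arm.inverse_kinematics(*xy)
        assert cfg.shoulder_deg == pytest.approx(sho, abs=1e-8)
        assert cfg.elbow_deg == pytest.approx(elb, abs=1e-8)

    def test_unreachable_endpoint_refused(self, default_arm):
        with pytest.raises(ValueError, match="reachable"):
            default_arm.inverse_kinematics(200.0, 0.0)

    def test_workspace_flag(self):
        assert JointConfig(50, 75).in_workspace
        assert not JointConfig(10, 75).in_workspace


class TestPassiveTorques:
    def test_components_cancel_at_mid_workspace(self, default_arm):
        pf, pe, net = default_arm.passive_torques(JointConfig(50.0, 75.0))
        assert np.all(pf >= 0) and np.all(pe <= 0)
        assert net == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_stiffening_toward_flexion_limit(self, default_arm):
        _, pe_edge, _ = default_arm.passive_torques(JointConfig(50.0, 129.0))
        _, pe_mid, _ = default_arm.passive_torques(JointConfig(50.0, 75.0))
        assert abs(pe_edge[1]) > abs(pe_mid[1])

    def test_matches_closed_form(self, default_arm):
        # independent evaluation of the documented one-sided exponentials
        sho, elb = 27.0, 111.0
        amp, lam = (default_arm.passive_amplitude_nm,
                    default_arm.passive_length_const_deg)
        pf, pe, _ = default_arm.passive_torques(JointConfig(sho, elb))
        assert pf[0] == pytest.approx(amp * np.exp(-(sho - 15) / lam))
        assert pe[1] == pytest.approx(-amp * np.exp(-(130 - elb) / lam))


class TestActiveTorques:
    def test_zero_stimulation_gives_zero_torque(self, default_arm):
        tq = default_arm.active_torques(np.zeros(6), JointConfig(40, 90))
        assert np.all(tq == 0.0)

    def test_stimulation_bounds_enforced(self, default_arm):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            default_arm.active_torques(np.full(6, 1.2), JointConfig(40, 90))

    def test_superposition_across_electrodes(self, default_arm):
        cfg = JointConfig(35.0, 95.0)
        u = np.array([0.3, 0.5, 0.7, 0.2, 0.8, 0.4])
        total = default_arm.active_torques(u, cfg).sum(axis=0)
        parts = np.zeros(2)
        for e in range(6):
            ue = np.zeros(6)
            ue[e] = u[e]
            parts += default_arm.active_torques(ue, cfg).sum(axis=0)
        assert total == pytest.approx(parts, abs=1e-12)

    def test_biarticular_ratio_constant_in_stimulation(self, default_arm):
        # uniform-recruitment channels keep a stimulation-independent
        # joint-torque ratio (it may still vary with posture)
        cfg = JointConfig(60.0, 50.0)
        bi = list(default_arm.electrode_ids).index("biceps")
        ratios = []
        for u in (0.3, 0.5, 0.7, 1.0):
            uu = np.zeros(6)
            uu[bi] = u
            tq = default_arm.active_torques(uu, cfg)[bi]
            ratios.append(tq[0] / tq[1])
        assert np.ptp(ratios) < 1e-9

    def test_fatigue_monotonically_reduces_torque(self):
        arm = sa.make_default_arm().with_fatigue_rates(
            {"anterior_deltoid": 0.005})
        cfg = JointConfig(40.0, 90.0)
        u = np.full(6, 0.8)
        mags = [np.abs(arm.active_torques(u, cfg, FatigueState(t))).sum()
                for t in (0.0, 30.0, 60.0, 100.0, 250.0)]
        assert np.all(np.diff(mags) <= 1e-12)

    def test_capacity_floors_at_zero(self):
        assert FatigueState(1000.0).capacities(np.array([0.005]))[0] == 0.0


class TestSpilloverArms:
    def test_default_biceps_column_spans_both_flexion_rows(self, default_arm):
        cfg = JointConfig(50.0, 75.0)
        bi = list(default_arm.electrode_ids).index("biceps")
        u = np.zeros(6)
        u[bi] = 1.0
        tq = default_arm.active_torques(u, cfg)[bi]
        assert tq[0] > 0 and tq[1] > 0

    def test_scenario_A_ratio_drifts_with_stimulation(self):
        arm = sa.make_spillover_arm("A")
        e = list(arm.electrode_ids).index("spill_channel")
        cfg = JointConfig(50.0, 75.0)

        def ratio(u):
            uu = np.zeros(6)
            uu[e] = u
            tq = arm.active_torques(uu, cfg)[e]
            return tq[0] / tq[1]       # shoulder / elbow

        assert ratio(0.3) < 0.2 * ratio(1.0)  # second muscle joins late

    def test_scenario_B_torque_ordering_reverses(self):
        arm = sa.make_spillover_arm("B")
        e = list(arm.electrode_ids).index("spill_channel")
        cfg = JointConfig(50.0, 75.0)

        def torques(u):
            uu = np.zeros(6)
            uu[e] = u
            return arm.active_torques(uu, cfg)[e]

        lo, hi = torques(0.4), torques(1.0)
        assert lo[1] > lo[0]    # elbow dominates at low current
        assert hi[0] > hi[1]    # shoulder dominates at full current

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            sa.make_spillover_arm("C")

    def test_arm_serialisation_round_trip(self):
        arm = sa.make_spillover_arm("A")
        clone = sa.ArmModel.from_dict(arm.to_dict())
        cfg = JointConfig(44.0, 63.0)
        u = np.full(6, 0.6)
        assert np.array_equal(arm.active_torques(u, cfg),
                              clone.active_torques(u, cfg))


class TestEquilibrium:
    def test_zero_stimulation_rests_at_passive_balance(self, default_arm):
        # independent 1-D bisection on each joint's passive curve
        def passive_root(joint):
            lo, hi = ((15.0, 85.0), (20.0, 130.0))[joint]
            a, b = lo, hi
            for _ in range(80):
                mid = 0.5 * (a + b)
                cfg = [50.0, 75.0]
                cfg[joint] = mid
                _, _, net = default_arm.passive_torques(JointConfig(*cfg))
                if net[joint] > 0:
                    a = mid
                else:
                    b = mid
            return 0.5 * (a + b)

        res = default_arm.equilibrium(np.zeros(6), JointConfig(30.0, 100.0))
        assert res.converged and res.stable
        assert res.config.shoulder_deg == pytest.approx(passive_root(0),
                                                        abs=1e-4)
        assert res.config.elbow_deg == pytest.approx(passive_root(1),
                                                     abs=1e-4)

    def test_solved_stimulation_is_a_fixed_point(self, default_arm, table20):
        i, j, k = 2, 3, 5
        cfg = JointConfig(table20.sho_angles[i], table20.elb_angles[j])
        res = default_arm.equilibrium(table20.stims[i, j, k], cfg)
        assert res.converged
        assert res.config.shoulder_deg == pytest.approx(cfg.shoulder_deg,
                                                        abs=0.01)
        assert res.config.elbow_deg == pytest.approx(cfg.elbow_deg, abs=0.01)

    def test_all_flexors_saturated_reported_not_converged(self, default_arm):
        u = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])  # flexors only, maxed
        res = default_arm.equilibrium(u, JointConfig(50.0, 75.0))
        # driven into the flexion guard band: either a boundary equilibrium
        # (passive catches it) or a flagged failure with residual reported
        if not res.converged:
            assert np.any(np.abs(res.residual_nm) > 0)
        else:
            assert res.config.elbow_deg > 130.0


class TestDynamics:
    def test_holds_equilibrium_posture(self, default_arm, table20):
        u = table20.stims[1, 2, 4]
        cfg = JointConfig(table20.sho_angles[1], table20.elb_angles[2])
        traj = default_arm.simulate_dynamics(u[None], 1.0, init=cfg)
        assert not traj.halted
        assert np.abs(traj.angles_deg - cfg.as_array()).max() < 0.1

    def test_settles_to_static_equilibrium(self, default_arm, table20):
        u = table20.stims[1, 2, 4]
        cfg = JointConfig(table20.sho_angles[1], table20.elb_angles[2])
        eq = default_arm.equilibrium(u, cfg)
        start = JointConfig(cfg.shoulder_deg + 8.0, cfg.elbow_deg - 8.0)
        traj = default_arm.simulate_dynamics(u[None], 5.0, init=start)
        assert np.abs(traj.velocity_dps[-1]).max() < 0.01
        assert np.abs(traj.angles_deg[-1]
                      - eq.config.as_array()).max() < 0.05

    def test_timestep_cap(self, default_arm):
        with pytest.raises(ValueError, match="1 ms"):
            default_arm.simulate_dynamics(np.zeros((1, 6)), 0.1, dt_s=0.01)
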