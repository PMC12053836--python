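"""The in-silico studies exercising the controller end to end.

Three studies mirror the calibration-and-use story:

* sampling-resolution sweep — how lookup-table accuracy degrades as the
  calibration grid coarsens from 1 to 20 degrees, measured as fingertip
  placement error over a dense evaluation grid;
* spillover iteration census — run the fixed-point solver over every
  (posture, stiffness) combination for the two electrode-spillover arm
  scenarios and record iteration counts and before/after residuals;
* fatigue rebalancing — compare standard and fatigue-resistant tables while
  one or two muscles lose torque capacity at 0.5 %/s over 100 s of holding
  each combination, with a Wilcoxon rank-sum comparison at each timestep.

A simulated user drives closed-loop centre-out reaches: a minimum-jerk
speed profile, visual-feedback re-aiming of the commanded velocity toward
the target every 50 ms, and a stiffness schedule derived from commanded
speed (stiff when slow, compliant at peak speed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .arm_model import (ArmModel, FatigueState, JointConfig, make_default_arm,
                        make_spillover_arm)
from .calibration import CalibrationData, SamplingGrid, calibrate
from .lookup_table import (LookupTable, build_initial_table,
                           downsample_and_interpolate, finalize_table, query,
                           verify_table)

__all__ = [
    "TABLE2_SCENARIOS", "FatigueScenario", "ReachCommand", "ReachResult",
    "resolution_experiment", "spillover_experiment", "fatigue_experiment",
    "stiffness_schedule", "simulated_user", "reach_simulation",
    "center_out_experiment", "default_workspace_grid",
]

# the 11 one- and two-muscle rapid-fatigue scenarios (0.5 adjustment each)
TABLE2_SCENARIOS: dict[int, tuple[str, ...]] = {
    1: ("anterior_deltoid",),
    2: ("posterior_deltoid",),
    3: ("brachialis",),
    4: ("triceps_lateral",),
    5: ("biceps",),
    6: ("triceps_long",),
    7: ("anterior_deltoid", "triceps_lateral"),
    8: ("posterior_deltoid", "brachialis"),
    9: ("anterior_deltoid", "brachialis"),
    10: ("posterior_deltoid", "triceps_lateral"),
    11: ("biceps", "triceps_long"),
}


@dataclass(frozen=True)
class FatigueScenario:
    scenario_id: int
    muscles: tuple[str, ...]
    adjustment: float = 0.5
    fatigue_rate: float = 0.005   # capacity fraction lost per second
    horizon_s: float = 100.0

    @classmethod
    def from_id(cls, scenario_id: int) -> "FatigueScenario":
        return cls(scenario_id, TABLE2_SCENARIOS[scenario_id])


def default_workspace_grid(step_deg: float = 5.0,
                           stiffness_nm=None) -> SamplingGrid:
    S = tuple(float(s) for s in range(3, 14)) if stiffness_nm is None \
        else tuple(float(s) for s in np.atleast_1d(stiffness_nm))
    return SamplingGrid((15.0, 85.0, step_deg), (20.0, 130.0, step_deg), S)


# --------------------------------------------------------------- resolution
def resolution_experiment(arm: ArmModel | None = None,
                          resolutions_deg=(1.0, 5.0, 10.0, 20.0),
                          stiffness_nm=(8.0,),
                          dense_step_deg: float = 1.0,
                          dense_calib: CalibrationData | None = None):
    """Fingertip error fields versus calibration sampling resolution.

    Calibrates densely once, builds a table from each down-sampled subset,
    queries it at every dense posture, lets the plant settle, and reports
    the fingertip displacement per node plus workspace medians.

    Returns (per-node DataFrame, median DataFrame).
    """
    arm = arm or make_default_arm()
    S_levels = tuple(float(s) for s in np.atleast_1d(stiffness_nm))
    if dense_calib is None:
        dense_calib = calibrate(arm, default_workspace_grid(dense_step_deg,
                                                            S_levels))
    eval_q = dense_calib.grid.configs()                     # (N, 2)
    rows = []
    for r in resolutions_deg:
        table = downsample_and_interpolate(dense_calib, r, S_levels, arm=arm)
        for S in S_levels:
            u, extrap = query(table, eval_q, S)
            th, ok, _, _ = arm.equilibrium_batch(u, eval_q)
            err = np.linalg.norm(arm.forward_kinematics_batch(th)
                                 - arm.forward_kinematics_batch(eval_q),
                                 axis=1)
            rows.append(pd.DataFrame({
                "resolution_deg": r, "stiffness_nm": S,
                "shoulder_deg": eval_q[:, 0], "elbow_deg": eval_q[:, 1],
                "error_cm": err, "settled": ok, "extrapolated": extrap}))
    per_node = pd.concat(rows, ignore_index=True)
    medians = (per_node.groupby(["resolution_deg", "stiffness_nm"])
               ["error_cm"].median().reset_index()
               .rename(columns={"error_cm": "median_error_cm"}))
    return per_node, medians


# ---------------------------------------------------------------- spillover
def spillover_experiment(scenario: str, grid_step_deg: float = 5.0,
                         stiffness_nm=None, tol: float = 1e-3,
                         max_iter: int = 1000,
                         arm: ArmModel | None = None) -> pd.DataFrame:
    """Iteration census over every (stiffness, posture) combination.

    One row per combination with the iteration count and the residual norm
    of the first (standard) and final solutions, both measured against the
    measured stimulation-to-torque curves.
    """
    from .torque_solver import iterate_spillover_batch
    arm = arm or make_spillover_arm(scenario)
    grid = default_workspace_grid(grid_step_deg, stiffness_nm)
    calib = calibrate(arm, grid)
    S_levels = np.asarray(grid.stiffness_nm)
    res = iterate_spillover_batch(calib, S_levels, tol=tol,
                                  max_iter=max_iter)
    cfgs = np.repeat(grid.configs(), S_levels.size, axis=0)
    return pd.DataFrame({
        "stiffness_nm": np.tile(S_levels, cfgs.shape[0] // S_levels.size),
        "shoulder_deg": cfgs[:, 0], "elbow_deg": cfgs[:, 1],
        "iterations": res.iterations, "converged": res.converged,
        "initial_residual_nm": res.initial_residual,
        "final_residual_nm": res.final_residual})


# ------------------------------------------------------------------ fatigue
def _table_errors(arm: ArmModel, table: LookupTable, fatigue: FatigueState,
                  tol_nm: float = 1e-10):
    """Endpoint (cm) and stiffness (Nm) error per node on a fatigued plant."""
    shape = table.stims.shape[:3]
    n = int(np.prod(shape))
    U = table.stims.reshape(n, -1)
    intended = np.repeat(table.node_configs().reshape(-1, 2), shape[2], axis=0)
    S_des = np.tile(table.stiffness_nm, n // shape[2])
    th, ok, _, _ = arm.equilibrium_batch(U, intended, fatigue, tol_nm)
    pos_err = np.linalg.norm(arm.forward_kinematics_batch(th)
                             - arm.forward_kinematics_batch(intended), axis=1)
    S_ach = arm.achieved_stiffness(U, th, fatigue).mean(axis=1)
    stiff_err = np.abs(S_ach - S_des)
    return pos_err, stiff_err, ok & table.feasible.reshape(-1)


def fatigue_experiment(scenarios=None, timestep_s: float = 5.0,
                       grid_step_deg: float = 5.0, stiffness_nm=None,
                       sweep_steps: int = 1601,
                       calib: CalibrationData | None = None,
                       standard_table: LookupTable | None = None):
    """Standard versus fatigue-resistant tables on a fatiguing plant.

    For each scenario the marked muscles lose capacity at the scenario rate
    while every (posture, stiffness) combination is held open-loop with the
    stimulation from each table. Per timestep: median endpoint and stiffness
    errors for both tables and a two-sided Wilcoxon rank-sum p-value across
    combinations (failed equilibria excluded pairwise).
    """
    arm0 = make_default_arm()
    grid = default_workspace_grid(grid_step_deg, stiffness_nm)
    if calib is None:
        calib = calibrate(arm0, grid, sweep_steps=sweep_steps)
    if standard_table is None:
        standard_table = build_initial_table(calib)
        ach, ok, _ = verify_table(standard_table, arm0)
        standard_table = finalize_table(standard_table, ach, ok)
    if scenarios is None:
        scenarios = sorted(TABLE2_SCENARIOS)
    recs = []
    for sid in scenarios:
        sc = sid if isinstance(sid, FatigueScenario) \
            else FatigueScenario.from_id(sid)
        adj = {m: sc.adjustment for m in sc.muscles}
        fr_table = build_initial_table(calib, adjustments=adj)
        ach, ok, _ = verify_table(fr_table, arm0)
        fr_table = finalize_table(fr_table, ach, ok)
        arm = arm0.with_fatigue_rates({m: sc.fatigue_rate for m in sc.muscles})
        times = np.arange(0.0, sc.horizon_s + 1e-9, timestep_s)
        for t in times:
            fat = FatigueState(t)
            p_std, s_std, ok_std = _table_errors(arm, standard_table, fat)
            p_fr, s_fr, ok_fr = _table_errors(arm, fr_table, fat)
            keep = ok_std & ok_fr
            ps, pf = p_std[keep], p_fr[keep]
            ss, sf = s_std[keep], s_fr[keep]
            recs.append({
                "scenario": sc.scenario_id, "t_s": t, "n": int(keep.sum()),
                "median_pos_err_std_cm": float(np.median(ps)),
                "median_pos_err_fr_cm": float(np.median(pf)),
                "median_stiff_err_std_nm": float(np.median(ss)),
                "median_stiff_err_fr_nm": float(np.median(sf)),
                "p_pos": float(ranksums(ps, pf).pvalue) if t > 0 else 1.0,
                "p_stiff": float(ranksums(ss, sf).pvalue) if t > 0 else 1.0,
                "max_pos_diff_t0_cm": float(np.max(np.abs(ps - pf)))
                if t == 0 else np.nan,
            })
    return pd.DataFrame(recs)


# ------------------------------------------------------- simulated BMI user
def stiffness_schedule(speed_cms, v_peak_cms, s_min: float = 3.0,
                       s_max: float = 13.0):
    """Commanded stiffness from commanded speed: compliant when fast.

    Linear in speed between S_max at rest and S_min at peak speed — the
    reach starts and ends stiff (stable posture) and softens mid-movement
    while accelerating, consistent with reports that accuracy and energy
    improve when co-contraction drops while speeding up and rises again
    while slowing down.
    """
    frac = np.clip(np.abs(speed_cms)
                   / np.maximum(np.asarray(v_peak_cms, dtype=float), 1e-12),
                   0.0, 1.0)
    return s_max - (s_max - s_min) * frac


def _minjerk_speed(t, d, T):
    """Bell-shaped speed profile of a minimum-jerk reach of length d."""
    tau = np.clip(t / T, 0.0, 1.0)
    return d / T * (30 * tau ** 2 - 60 * tau ** 3 + 30 * tau ** 4)


@dataclass
class ReachCommand:
    """50 ms-cadence desired postures and stiffness for one reach."""

    t_s: np.ndarray
    configs_deg: np.ndarray     # (n, 2)
    stiffness_nm: np.ndarray    # (n,)
    endpoints_cm: np.ndarray    # (n, 2) commanded fingertip path


@dataclass
class ReachResult:
    command: ReachCommand
    t_s: np.ndarray
    angles_deg: np.ndarray
    endpoint_cm: np.ndarray
    target_cm: np.ndarray
    final_error_cm: float


def simulated_user(arm: ArmModel, start: JointConfig, target_cm,
                   duration_s: float = 1.3, feedback: bool = False,
                   endpoint_source=None, s_min: float = 3.0,
                   s_max: float = 13.0, dt_s: float = 0.05) -> ReachCommand:
    """Generate the 50 ms command stream a BMI user would produce.

    The commanded endpoint follows a minimum-jerk bell-shaped speed profile
    toward the target. With feedback on, the velocity direction is re-aimed
    from the *current* endpoint toward the target at every loop before
    integrating (supply ``endpoint_source``, a callable returning the
    simulated fingertip position; without one the commanded position is
    used, which reduces to the open-loop straight path).
    """
    target = np.asarray(target_cm, dtype=float)
    p0 = np.array(arm.forward_kinematics(start))
    d = float(np.linalg.norm(target - p0))
    if d < 1e-12:
        n = int(round(duration_s / dt_s)) + 1
        t = dt_s * np.arange(n)
        return ReachCommand(t, np.tile(start.as_array(), (n, 1)),
                            np.full(n, s_max), np.tile(p0, (n, 1)))
    v_peak = 1.875 * d / duration_s
    n = int(round(duration_s / dt_s))
    t = dt_s * np.arange(n + 1)
    p_cmd = p0.copy()
    pts, cfgs, stiff = [p0.copy()], [start.as_array()], [s_max]
    for k in range(n):
        speed = _minjerk_speed(t[k] + 0.5 * dt_s, d, duration_s)
        origin = p_cmd
        if feedback and endpoint_source is not None:
            origin_aim = np.asarray(endpoint_source(), dtype=float)
        else:
            origin_aim = p_cmd
        gap = target - origin_aim
        dist = np.linalg.norm(gap)
        direction = gap / dist if dist > 1e-9 else np.zeros(2)
        p_cmd = p_cmd + min(speed * dt_s, dist) * direction
        cfg = arm.inverse_kinematics(*p_cmd)
        pts.append(p_cmd.copy())
        cfgs.append(cfg.as_array())
        stiff.append(stiffness_schedule(speed, v_peak, s_min, s_max))
    return ReachCommand(t, np.array(cfgs), np.array(stiff), np.array(pts))


def _command_config(arm: ArmModel, p_cm) -> np.ndarray:
    """Commanded endpoint -> workspace-clamped joint command.

    The user can only command postures the controller covers, so the
    endpoint is pulled into the reachable annulus and the resulting joint
    angles are clipped to the calibrated workspace before the table lookup.
    """
    from .arm_model import ELBOW_LIMITS, SHOULDER_LIMITS
    l1, l2 = 100.0 * np.asarray(arm.link_lengths_m)
    p = np.asarray(p_cm, dtype=float)
    r = np.linalg.norm(p)
    r_lo = np.sqrt(l1 ** 2 + l2 ** 2
                   + 2 * l1 * l2 * np.cos(np.radians(ELBOW_LIMITS[1])))
    r_hi = np.sqrt(l1 ** 2 + l2 ** 2
                   + 2 * l1 * l2 * np.cos(np.radians(ELBOW_LIMITS[0])))
    r_c = np.clip(r, r_lo + 1e-6, r_hi - 1e-6)
    if r > 0 and r_c != r:
        p = p * (r_c / r)
    cfg = arm.inverse_kinematics(*p).as_array()
    cfg[0] = np.clip(cfg[0], *SHOULDER_LIMITS)
    cfg[1] = np.clip(cfg[1], *ELBOW_LIMITS)
    return cfg


class _BatchDynamics:
    """Vectorised rigid-body integrator for several reaches at once."""

    def __init__(self, arm: ArmModel, q0_deg: np.ndarray):
        self.arm = arm
        m1, m2 = arm.link_masses_kg
        l1, l2 = arm.link_lengths_m
        lc2 = l2 / 2.0
        i1 = m1 * l1 ** 2 / 12.0
        i2 = m2 * l2 ** 2 / 12.0
        self._a = i1 + i2 + m1 * (l1 / 2) ** 2 + m2 * (l1 ** 2 + lc2 ** 2)
        self._b = m2 * l1 * lc2
        self._m22 = i2 + m2 * lc2 ** 2
        self.q = np.deg2rad(np.asarray(q0_deg, dtype=float))
        self.w = np.zeros_like(self.q)

    def _deriv(self, q, w, U):
        tau, _ = self.arm.net_torque(U, np.rad2deg(q))
        act = self.arm._activations(U).sum(axis=1)
        damp = (self.arm.damping_base
                + self.arm.damping_per_activation * act)[:, None]
        c2 = np.cos(q[:, 1])
        s2 = np.sin(q[:, 1])
        m11 = self._a + 2 * self._b * c2
        m12 = self._m22 + self._b * c2
        m22 = self._m22
        cor1 = -self._b * s2 * (2 * w[:, 0] * w[:, 1] + w[:, 1] ** 2)
        cor2 = self._b * s2 * w[:, 0] ** 2
        rhs = tau - damp * w - np.stack([cor1, cor2], axis=1)
        det = m11 * m22 - m12 * m12
        acc = np.stack([(m22 * rhs[:, 0] - m12 * rhs[:, 1]) / det,
                        (m11 * rhs[:, 1] - m12 * rhs[:, 0]) / det], axis=1)
        return w, acc

    def step(self, U, dt):
        q, w = self.q, self.w
        k1q, k1w = self._deriv(q, w, U)
        k2q, k2w = self._deriv(q + 0.5 * dt * k1q, w + 0.5 * dt * k1w, U)
        k3q, k3w = self._deriv(q + 0.5 * dt * k2q, w + 0.5 * dt * k2w, U)
        k4q, k4w = self._deriv(q + dt * k3q, w + dt * k3w, U)
        self.q = q + dt / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
        self.w = w + dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)

    @property
    def angles_deg(self):
        return np.rad2deg(self.q)


def _simulate_reaches(table: LookupTable, arm: ArmModel,
                      start: JointConfig, targets_cm: np.ndarray,
                      duration_s: float = 1.3, feedback: bool = True,
                      s_min: float = 3.0, s_max: float = 13.0,
                      homing_s: float = 2.0, settle_s: float = 0.5,
                      dt_s: float = 1e-3, cmd_dt_s: float = 0.05,
                      homing_gain: float = 0.7,
                      homing_interval_s: float = 0.4):
    """Run N closed-loop reaches in lockstep; returns per-reach histories.

    During the bell-profile phase the commanded velocity magnitude follows
    the minimum-jerk profile while (with feedback) its direction is re-aimed
    at the target from the current fingertip each 50 ms. Feedback reaches
    then keep steering — the commanded position accumulates a fraction of
    the remaining visual error each loop — before a final hold to settle.
    """
    targets = np.atleast_2d(np.asarray(targets_cm, dtype=float))
    n = targets.shape[0]
    p0 = np.array(arm.forward_kinematics(start))
    d = np.linalg.norm(targets - p0, axis=1)
    v_peak = 1.875 * d / duration_s
    dyn = _BatchDynamics(arm, np.tile(start.as_array(), (n, 1)))
    p_cmd = np.tile(p0, (n, 1))
    steps_per_cmd = int(round(cmd_dt_s / dt_s))
    n_cmd_profile = int(round(duration_s / cmd_dt_s))
    n_cmd_homing = int(round(homing_s / cmd_dt_s)) if feedback else 0
    n_cmd_settle = int(round(settle_s / cmd_dt_s))
    total_cmds = n_cmd_profile + n_cmd_homing + n_cmd_settle

    hist_t, hist_q, cmd_cfg, cmd_S, cmd_p = [0.0], [dyn.angles_deg.copy()], [], [], []
    U = np.zeros((n, table.n_electrodes))
    for k in range(total_cmds):
        t = k * cmd_dt_s
        actual = arm.forward_kinematics_batch(dyn.angles_deg)
        if k < n_cmd_profile:
            speed = _minjerk_speed(t + 0.5 * cmd_dt_s, d, duration_s)
            origin = actual if feedback else p_cmd
            gap = targets - origin
            dist = np.linalg.norm(gap, axis=1)
            direction = np.where(dist[:, None] > 1e-9,
                                 gap / np.maximum(dist, 1e-12)[:, None], 0.0)
            step = np.minimum(speed * cmd_dt_s, dist)
            p_cmd = p_cmd + step[:, None] * direction
            S = stiffness_schedule(speed, np.maximum(v_peak, 1e-9),
                                   s_min, s_max)
        elif k < n_cmd_profile + n_cmd_homing:
            # sparse visual corrections: nudge the command by a fraction of
            # the remaining error, then give the arm time to settle
            k_h = k - n_cmd_profile
            every = max(1, int(round(homing_interval_s / cmd_dt_s)))
            if k_h % every == every - 1:
                gap = targets - actual
                corr = homing_gain * gap
                norm = np.linalg.norm(corr, axis=1)
                corr *= np.minimum(1.0, 3.0 / np.maximum(norm, 1e-12))[:, None]
                p_cmd = p_cmd + corr
            S = np.full(n, s_max)
        else:
            S = np.full(n, s_max)
        cfg = np.array([_command_config(arm, p) for p in p_cmd])
        U, _ = query(table, cfg, S)
        cmd_cfg.append(cfg)
        cmd_S.append(np.array(S, dtype=float, copy=True))
        cmd_p.append(p_cmd.copy())
        for _ in range(steps_per_cmd):
            dyn.step(U, dt_s)
        hist_t.append((k + 1) * cmd_dt_s)
        hist_q.append(dyn.angles_deg.copy())

    hist_q = np.array(hist_q)                       # (T, n, 2)
    ends = arm.forward_kinematics_batch(hist_q)     # (T, n, 2)
    final_err = np.linalg.norm(ends[-1] - targets, axis=1)
    results = []
    for i in range(n):
        cmd = ReachCommand(cmd_dt_s * np.arange(total_cmds),
                           np.array(cmd_cfg)[:, i],
                           np.array(cmd_S)[:, i], np.array(cmd_p)[:, i])
        results.append(ReachResult(cmd, np.array(hist_t), hist_q[:, i],
                                   ends[:, i], targets[i],
                                   float(final_err[i])))
    return results


def reach_simulation(table: LookupTable, arm: ArmModel, start: JointConfig,
                     target_cm, **kwargs) -> ReachResult:
    """Single closed-loop reach (see :func:`_simulate_reaches`)."""
    return _simulate_reaches(table, arm, start,
                             np.asarray(target_cm, dtype=float)[None],
                             **kwargs)[0]


def center_out_experiment(table: LookupTable, arm: ArmModel | None = None,
                          n_targets: int = 8, radius_cm: float = 14.0,
                          start: JointConfig = JointConfig(50.0, 75.0),
                          feedback: bool = True, **kwargs) -> pd.DataFrame:
    """Radial centre-out reaches; one row per target with the final error."""
    arm = arm or make_default_arm()
    p0 = np.array(arm.forward_kinematics(start))
    ang = 2.0 * np.pi * np.arange(n_targets) / n_targets
    targets = p0 + radius_cm * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    res = _simulate_reaches(table, arm, start, targets, feedback=feedback,
                            **kwargs)
    return pd.DataFrame({
        "target_x_cm": targets[:, 0], "target_y_cm": targets[:, 1],
        "final_error_cm": [r.final_error_cm for r in res],
        "feedback": feedback})
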