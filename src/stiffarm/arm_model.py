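"""Synthetic planar two-joint, six-muscle arm used as the ground-truth plant.

The plant plays the role of a paralysed human arm responding to functional
electrical stimulation (FES), together with the measurement harness an
instrumented exoskeleton would provide. It is deliberately simple but keeps
the features the controller has to cope with: redundant flexors/extensors at
each joint, biarticular muscles coupling shoulder and elbow, one-sided
passive elastic torques that stiffen toward the range limits, sigmoidal
recruitment from normalised stimulation to activation, optional electrode
"spillover" (one channel recruiting two muscles with different thresholds),
and a constant-rate fatigue model that erodes torque capacity over time.

Conventions
-----------
* Angles are degrees at every public interface. Flexion torques are
  positive, extension negative (right-hand rule).
* The shoulder angle is measured from the +x axis; the elbow angle is the
  interior flexion angle added to the upper-arm direction. Movement is in
  the horizontal plane, so gravity plays no role.
* Stimulation is a normalised command u in [0, 1] per electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "JointConfig", "JointAction", "MuscleSpec", "ElectrodeTarget",
    "ElectrodeSpec", "FatigueState", "ArmModel", "EquilibriumResult",
    "Trajectory", "make_default_arm", "make_spillover_arm", "make_arm",
    "SHOULDER_LIMITS", "ELBOW_LIMITS",
]

SHOULDER_LIMITS = (15.0, 85.0)
ELBOW_LIMITS = (20.0, 130.0)
JOINTS = ("shoulder", "elbow")
_LIMITS = (SHOULDER_LIMITS, ELBOW_LIMITS)

# passive elastic components: one-sided exponentials engaging near each limit
PASSIVE_AMPLITUDE_NM = 2.5
PASSIVE_LENGTH_CONST_DEG = 15.0

# force-length factor defaults (Gaussian with a floor)
FL_WIDTH_DEG = 60.0
FL_FLOOR = 0.3
FL_OFFSET_DEG = 20.0  # flexor optimum below mid-range, extensor above


@dataclass(frozen=True)
class JointConfig:
    """A shoulder/elbow posture in degrees."""

    shoulder_deg: float
    elbow_deg: float

    @property
    def in_workspace(self) -> bool:
        return (SHOULDER_LIMITS[0] <= self.shoulder_deg <= SHOULDER_LIMITS[1]
                and ELBOW_LIMITS[0] <= self.elbow_deg <= ELBOW_LIMITS[1])

    def as_array(self) -> np.ndarray:
        return np.array([self.shoulder_deg, self.elbow_deg], dtype=float)


@dataclass(frozen=True)
class JointAction:
    """One muscle's action on one joint."""

    joint: str                 # "shoulder" | "elbow"
    peak_torque_nm: float      # signed: + flexion, - extension
    fl_center_deg: float
    fl_width_deg: float = FL_WIDTH_DEG
    fl_floor: float = FL_FLOOR


@dataclass(frozen=True)
class MuscleSpec:
    name: str
    actions: tuple[JointAction, ...]
    recruitment_threshold: float = 0.1
    recruitment_saturation: float = 0.9
    fatigue_rate: float = 0.0  # fraction of capacity lost per second

    def __post_init__(self):
        joints = [a.joint for a in self.actions]
        if len(set(joints)) != len(joints):
            raise ValueError(f"{self.name}: one action per joint")
        for a in self.actions:
            if a.peak_torque_nm == 0.0:
                raise ValueError(f"{self.name}: zero peak torque on {a.joint}")


@dataclass(frozen=True)
class ElectrodeTarget:
    """A muscle recruited by an electrode, with channel-specific thresholds."""

    muscle: str
    threshold: float | None = None    # None -> use the muscle's own
    saturation: float | None = None


@dataclass(frozen=True)
class ElectrodeSpec:
    id: str
    targets: tuple[ElectrodeTarget, ...]

    @property
    def is_spillover(self) -> bool:
        return len(self.targets) > 1


@dataclass(frozen=True)
class FatigueState:
    """Elapsed use; capacity of muscle i is max(0, 1 - rate_i * t)."""

    elapsed_s: float = 0.0

    def capacities(self, rates: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, 1.0 - rates * self.elapsed_s)


@dataclass
class EquilibriumResult:
    config: JointConfig
    converged: bool
    stable: bool
    residual_nm: np.ndarray  # (2,) net torque at the returned posture


@dataclass
class Trajectory:
    t_s: np.ndarray             # (n,)
    angles_deg: np.ndarray      # (n, 2)
    velocity_dps: np.ndarray    # (n, 2)
    endpoint_cm: np.ndarray     # (n, 2)
    halted: bool = False
    halt_reason: str = ""


def _recruitment(u, threshold, saturation):
    """Normalised logistic activation: 0 at u=0, 1 at u=1, ~5%/95% at
    threshold/saturation."""
    u = np.asarray(u, dtype=float)
    c = 0.5 * (threshold + saturation)
    k = 2.0 * np.log(19.0) / (saturation - threshold)
    raw = 1.0 / (1.0 + np.exp(-k * (u - c)))
    r0 = 1.0 / (1.0 + np.exp(k * c))
    r1 = 1.0 / (1.0 + np.exp(-k * (1.0 - c)))
    return (raw - r0) / (r1 - r0)


class ArmModel:
    """The compiled plant: fast array kernels over the declarative specs."""

    def __init__(self,
                 muscles: Sequence[MuscleSpec],
                 electrodes: Sequence[ElectrodeSpec],
                 link_lengths_m: tuple[float, float] = (0.33, 0.45),
                 link_masses_kg: tuple[float, float] = (2.0, 1.7),
                 damping_base: float = 0.8,
                 damping_per_activation: float = 2.0,
                 passive_amplitude_nm: float = PASSIVE_AMPLITUDE_NM,
                 passive_length_const_deg: float = PASSIVE_LENGTH_CONST_DEG,
                 scenario: str = "custom"):
        self.muscles = tuple(muscles)
        self.electrodes = tuple(electrodes)
        self.link_lengths_m = tuple(link_lengths_m)
        self.link_masses_kg = tuple(link_masses_kg)
        self.damping_base = float(damping_base)
        self.damping_per_activation = float(damping_per_activation)
        self.passive_amplitude_nm = float(passive_amplitude_nm)
        self.passive_length_const_deg = float(passive_length_const_deg)
        self.scenario = scenario
        self._compile()

    # ------------------------------------------------------------------ setup
    def _compile(self):
        names = [m.name for m in self.muscles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate muscle names")
        self._mus_index = {n: i for i, n in enumerate(names)}
        nm = len(self.muscles)
        self._peak = np.zeros((nm, 2))
        self._fl_center = np.zeros((nm, 2))
        self._fl_width = np.ones((nm, 2))
        self._fl_floor = np.zeros((nm, 2))
        self._rates = np.array([m.fatigue_rate for m in self.muscles])
        for i, m in enumerate(self.muscles):
            for a in m.actions:
                j = JOINTS.index(a.joint)
                self._peak[i, j] = a.peak_torque_nm
                self._fl_center[i, j] = a.fl_center_deg
                self._fl_width[i, j] = a.fl_width_deg
                self._fl_floor[i, j] = a.fl_floor
        # electrode targets as flat arrays: (electrode idx, muscle idx, thr, sat)
        te, tm, tt, ts = [], [], [], []
        for e_idx, e in enumerate(self.electrodes):
            for tgt in e.targets:
                mi = self._mus_index[tgt.muscle]
                mus = self.muscles[mi]
                te.append(e_idx)
                tm.append(mi)
                tt.append(tgt.threshold if tgt.threshold is not None
                          else mus.recruitment_threshold)
                ts.append(tgt.saturation if tgt.saturation is not None
                          else mus.recruitment_saturation)
        self._tgt_elec = np.array(te, dtype=int)
        self._tgt_mus = np.array(tm, dtype=int)
        self._tgt_thr = np.array(tt)
        self._tgt_sat = np.array(ts)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def electrode_ids(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.electrodes)

    def fatigue_rates(self) -> np.ndarray:
        return self._rates.copy()

    def with_fatigue_rates(self, rates: dict[str, float]) -> "ArmModel":
        """A copy of this arm with the given per-muscle fatigue rates."""
        new = [replace(m, fatigue_rate=rates.get(m.name, m.fatigue_rate))
               for m in self.muscles]
        return ArmModel(new, self.electrodes, self.link_lengths_m,
                        self.link_masses_kg, self.damping_base,
                        self.damping_per_activation, self.passive_amplitude_nm,
                        self.passive_length_const_deg, self.scenario)

    # ------------------------------------------------------- kernel functions
    def _fl(self, thetas: np.ndarray):
        """Force-length factor and its angle derivative.

        thetas : (N, 2) degrees -> factors (N, n_mus, 2), d/dtheta same shape.
        """
        th = thetas[:, None, :]
        z = (th - self._fl_center[None]) / self._fl_width[None]
        g = np.exp(-0.5 * z * z)
        span = 1.0 - self._fl_floor[None]
        fl = self._fl_floor[None] + span * g
        dfl = span * g * (-z / self._fl_width[None])
        return fl, dfl

    def _passive(self, thetas: np.ndarray):
        """Pf (>=0) and Pe (<=0) per joint, (N, 2) each, plus derivatives."""
        lam = self.passive_length_const_deg
        amp = self.passive_amplitude_nm
        lo = np.array([_LIMITS[0][0], _LIMITS[1][0]])
        hi = np.array([_LIMITS[0][1], _LIMITS[1][1]])
        pf = amp * np.exp(-(thetas - lo) / lam)
        pe = -amp * np.exp(-(hi - thetas) / lam)
        dpf = -pf / lam
        dpe = pe / lam
        return pf, pe, dpf, dpe

    def _activations(self, U: np.ndarray):
        """Per-target activation, (N, n_targets)."""
        u = U[:, self._tgt_elec]
        return _recruitment(u, self._tgt_thr[None], self._tgt_sat[None])

    def _active(self, U: np.ndarray, thetas: np.ndarray,
                capacities: np.ndarray, per_electrode: bool = False):
        """Active torques. Returns (N, 2) or, per_electrode, (N, m, 2)."""
        act = self._activations(U)                       # (N, T)
        fl, _ = self._fl(thetas)                         # (N, nm, 2)
        contrib = (act[:, :, None]
                   * self._peak[self._tgt_mus][None]
                   * fl[:, self._tgt_mus, :]
                   * capacities[self._tgt_mus][None, :, None])  # (N, T, 2)
        if per_electrode:
            out = np.zeros((U.shape[0], self.n_electrodes, 2))
            np.add.at(out, (slice(None), self._tgt_elec), contrib)
            return out
        out = np.zeros((U.shape[0], 2))
        for k in range(contrib.shape[1]):
            out += contrib[:, k]
        return out

    def _dactive(self, U: np.ndarray, thetas: np.ndarray,
                 capacities: np.ndarray):
        """d(active torque at joint j)/d(theta_j), (N, 2)."""
        act = self._activations(U)
        _, dfl = self._fl(thetas)
        contrib = (act[:, :, None]
                   * self._peak[self._tgt_mus][None]
                   * dfl[:, self._tgt_mus, :]
                   * capacities[self._tgt_mus][None, :, None])
        return contrib.sum(axis=1)

    def net_torque(self, U: np.ndarray, thetas: np.ndarray,
                   fatigue: FatigueState | None = None):
        """Net joint torque (N, 2) and its diagonal Jacobian (N, 2)."""
        caps = (fatigue or FatigueState()).capacities(self._rates)
        pf, pe, dpf, dpe = self._passive(thetas)
        tau = pf + pe + self._active(U, thetas, caps)
        dtau = dpf + dpe + self._dactive(U, thetas, caps)
        return tau, dtau

    # ------------------------------------------------------------ public ops
    def forward_kinematics(self, config: JointConfig) -> tuple[float, float]:
        """Fingertip position in cm for a posture."""
        xy = self.forward_kinematics_batch(config.as_array()[None])[0]
        return float(xy[0]), float(xy[1])

    def forward_kinematics_batch(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.asarray(thetas, dtype=float)
        l1, l2 = (100.0 * np.asarray(self.link_lengths_m))
        a1 = np.deg2rad(thetas[..., 0])
        a12 = np.deg2rad(thetas[..., 0] + thetas[..., 1])
        return np.stack([l1 * np.cos(a1) + l2 * np.cos(a12),
                         l1 * np.sin(a1) + l2 * np.sin(a12)], axis=-1)

    def inverse_kinematics(self, x_cm: float, y_cm: float) -> JointConfig:
        """Closed-form two-link IK on the elbow-flexed (positive) branch."""
        l1, l2 = (100.0 * np.asarray(self.link_lengths_m))
        r2 = x_cm ** 2 + y_cm ** 2
        ce = (r2 - l1 ** 2 - l2 ** 2) / (2.0 * l1 * l2)
        if not (-1.0 <= ce <= 1.0):
            raise ValueError(f"endpoint ({x_cm:.1f}, {y_cm:.1f}) cm is outside "
                             "the reachable annulus")
        elbow = np.degrees(np.arccos(ce))          # positive-flexion branch
        beta = np.degrees(np.arctan2(l2 * np.sin(np.radians(elbow)),
                                     l1 + l2 * np.cos(np.radians(elbow))))
        shoulder = np.degrees(np.arctan2(y_cm, x_cm)) - beta
        return JointConfig(float(shoulder), float(elbow))

    def passive_torques(self, config: JointConfig):
        """(Pf, Pe, net) arrays of shape (2,), ordered (shoulder, elbow)."""
        pf, pe, _, _ = self._passive(config.as_array()[None])
        return pf[0], pe[0], pf[0] + pe[0]

    def active_torques(self, stim: np.ndarray, config: JointConfig,
                       fatigue: FatigueState | None = None) -> np.ndarray:
        """Per-electrode signed joint torques, shape (m, 2)."""
        stim = np.asarray(stim, dtype=float)
        if stim.shape != (self.n_electrodes,):
            raise ValueError(f"stim must have shape ({self.n_electrodes},)")
        if np.any(stim < 0.0) or np.any(stim > 1.0):
            raise ValueError("stimulation commands must lie in [0, 1]")
        caps = (fatigue or FatigueState()).capacities(self._rates)
        return self._active(stim[None], config.as_array()[None], caps,
                            per_electrode=True)[0]

    def electrode_sweep(self, e_idx: int, thetas: np.ndarray, u: np.ndarray,
                        fatigue: FatigueState | None = None) -> np.ndarray:
        """Active torques of one electrode alone over a stimulation sweep.

        thetas : (N, 2) postures, u : (k,) levels -> (k, N, 2) torques.
        This is what the exoskeleton harness observes after subtracting the
        passive hold torques.
        """
        thetas = np.asarray(thetas, dtype=float)
        u = np.asarray(u, dtype=float)
        caps = (fatigue or FatigueState()).capacities(self._rates)
        fl, _ = self._fl(thetas)                              # (N, nm, 2)
        sel = np.where(self._tgt_elec == e_idx)[0]
        out = np.zeros((u.shape[0], thetas.shape[0], 2))
        for s in sel:
            mi = self._tgt_mus[s]
            a = _recruitment(u, self._tgt_thr[s], self._tgt_sat[s])  # (k,)
            gain = self._peak[mi][None] * fl[:, mi, :] * caps[mi]    # (N, 2)
            out += a[:, None, None] * gain[None]
        return out

    # -------------------------------------------------------- static balance
    def equilibrium(self, stim: np.ndarray, init: JointConfig,
                    fatigue: FatigueState | None = None,
                    tol_nm: float = 1e-6) -> EquilibriumResult:
        th, conv, stab, res = self.equilibrium_batch(
            np.asarray(stim, dtype=float)[None], init.as_array()[None],
            fatigue, tol_nm)
        return EquilibriumResult(JointConfig(float(th[0, 0]), float(th[0, 1])),
                                 bool(conv[0]), bool(stab[0]), res[0])

    def equilibrium_batch(self, U: np.ndarray, init: np.ndarray,
                          fatigue: FatigueState | None = None,
                          tol_nm: float = 1e-6):
        """Stable static postures for many stimulation vectors at once.

        The net torque at each joint depends only on that joint's angle
        (both passive components and the force-length factors are local to
        a joint), so the 2-D balance decouples into two scalar root finds
        which are run as damped Newton iterations over the whole batch,
        with a scan-and-bisect fallback for rows Newton does not settle.
        Stability requires d(tau)/d(theta) < 0 at both joints.
        """
        U = np.asarray(U, dtype=float)
        init = np.asarray(init, dtype=float)
        n = U.shape[0]
        lo = np.array([_LIMITS[0][0], _LIMITS[1][0]]) - 15.0
        hi = np.array([_LIMITS[0][1], _LIMITS[1][1]]) + 15.0

        th = init.copy()
        for _ in range(60):
            tau, dtau = self.net_torque(U, th, fatigue)
            if np.max(np.abs(tau)) < tol_nm:
                break
            with np.errstate(divide="ignore", invalid="ignore"):
                step = tau / dtau
            step = np.where(np.isfinite(step), step, 0.0)
            step = np.clip(step, -8.0, 8.0)
            move = np.abs(tau) >= tol_nm
            th = np.where(move, np.clip(th - step, lo, hi), th)

        tau, dtau = self.net_torque(U, th, fatigue)
        ok = (np.abs(tau) < tol_nm) & (dtau < 0.0)
        bad_rows = np.where(~ok.all(axis=1))[0]
        if bad_rows.size:
            th[bad_rows] = self._equilibrium_fallback(
                U[bad_rows], init[bad_rows], th[bad_rows], fatigue, lo, hi)
            tau, dtau = self.net_torque(U, th, fatigue)

        converged = (np.abs(tau) < tol_nm).all(axis=1)
        stable = (dtau < 0.0).all(axis=1)
        return th, converged & stable, stable, tau

    def _equilibrium_fallback(self, U, init, th_newton, fatigue, lo, hi):
        """Dense scan for a stable bracket nearest the intended posture.

        Because each joint's net torque depends only on its own angle the
        scan and the subsequent bisection run vectorised over all rows.
        """
        n = U.shape[0]
        out = th_newton.copy()
        for j in range(2):
            grid = np.arange(lo[j], hi[j] + 0.25, 0.25)
            th_scan = np.repeat(init[:, None, :], grid.size, axis=1)
            th_scan[:, :, j] = grid[None, :]
            Urep = np.repeat(U, grid.size, axis=0)
            tau, _ = self.net_torque(Urep, th_scan.reshape(-1, 2), fatigue)
            tau_j = tau[:, j].reshape(n, grid.size)
            # stable roots are + -> - sign changes of tau_j along the grid
            cross = (tau_j[:, :-1] > 0) & (tau_j[:, 1:] <= 0)
            has = cross.any(axis=1)
            if not has.any():
                continue
            mids = 0.5 * (grid[:-1] + grid[1:])
            dist = np.where(cross, np.abs(mids[None] - init[:, [j]]), np.inf)
            cell = np.argmin(dist, axis=1)
            a = np.where(has, grid[cell], out[:, j])
            b = np.where(has, grid[cell + 1], out[:, j])
            probe = init.copy()
            for _ in range(60):
                m = 0.5 * (a + b)
                probe[:, j] = m
                t, _ = self.net_torque(U, probe, fatigue)
                pos = t[:, j] > 0
                a = np.where(pos, m, a)
                b = np.where(pos, b, m)
            out[has, j] = (0.5 * (a + b))[has]
        return out

    def achieved_stiffness(self, U: np.ndarray, thetas: np.ndarray,
                           fatigue: FatigueState | None = None) -> np.ndarray:
        """Flexion-side opposing-torque sum per joint, (N, 2) in Nm.

        At a balanced equilibrium this equals the extension-side magnitude
        and is the realised stiffness S of each joint.
        """
        caps = (fatigue or FatigueState()).capacities(self._rates)
        pf, _, _, _ = self._passive(thetas)
        per_e = self._active(U, thetas, caps, per_electrode=True)
        return pf + np.clip(per_e, 0.0, None).sum(axis=1)

    # ------------------------------------------------------------- dynamics
    def simulate_dynamics(self, stim_schedule: np.ndarray, duration_s: float,
                          dt_s: float = 1e-3, command_dt_s: float = 0.05,
                          init: JointConfig | None = None,
                          init_velocity_dps: np.ndarray | None = None,
                          fatigue: FatigueState | None = None) -> Trajectory:
        """Forward rigid-body simulation under a piecewise-constant schedule.

        stim_schedule : (n_cmd, m); command k is held on
            [k*command_dt_s, (k+1)*command_dt_s). The last command persists.
        Joint damping grows linearly with total recruitment, reflecting the
        damping increase seen with co-contraction.
        """
        if dt_s > 1e-3 + 1e-12:
            raise ValueError("dt_s must be <= 1 ms")
        sched = np.atleast_2d(np.asarray(stim_schedule, dtype=float))
        if init is None:
            init = JointConfig(50.0, 75.0)
        caps = (fatigue or FatigueState()).capacities(self._rates)

        m1, m2 = self.link_masses_kg
        l1, l2 = self.link_lengths_m
        lc1, lc2 = l1 / 2.0, l2 / 2.0
        i1 = m1 * l1 ** 2 / 12.0
        i2 = m2 * l2 ** 2 / 12.0
        a_const = i1 + i2 + m1 * lc1 ** 2 + m2 * (l1 ** 2 + lc2 ** 2)
        b_const = m2 * l1 * lc2
        m22 = i2 + m2 * lc2 ** 2

        n_steps = int(round(duration_s / dt_s))
        lo = np.array([_LIMITS[0][0], _LIMITS[1][0]]) - 20.0
        hi = np.array([_LIMITS[0][1], _LIMITS[1][1]]) + 20.0

        q = np.deg2rad(init.as_array())
        w = (np.zeros(2) if init_velocity_dps is None
             else np.deg2rad(np.asarray(init_velocity_dps, dtype=float)))
        ts = np.empty(n_steps + 1)
        qs = np.empty((n_steps + 1, 2))
        ws = np.empty((n_steps + 1, 2))
        qs[0], ws[0], ts[0] = np.rad2deg(q), np.rad2deg(w), 0.0
        halted, reason = False, ""

        def deriv(q, w, u):
            th_deg = np.rad2deg(q)[None]
            tau_mus, _ = self.net_torque(u[None], th_deg, fatigue)
            act = self._activations(u[None]).sum()
            damp = self.damping_base + self.damping_per_activation * act
            c2 = np.cos(q[1])
            s2 = np.sin(q[1])
            M = np.array([[a_const + 2 * b_const * c2, m22 + b_const * c2],
                          [m22 + b_const * c2, m22]])
            cor = np.array([-b_const * s2 * (2 * w[0] * w[1] + w[1] ** 2),
                            b_const * s2 * w[0] ** 2])
            acc = np.linalg.solve(M, tau_mus[0] - cor - damp * w)
            return w, acc

        for k in range(n_steps):
            t = k * dt_s
            u = sched[min(int(t / command_dt_s), sched.shape[0] - 1)]
            k1q, k1w = deriv(q, w, u)
            k2q, k2w = deriv(q + 0.5 * dt_s * k1q, w + 0.5 * dt_s * k1w, u)
            k3q, k3w = deriv(q + 0.5 * dt_s * k2q, w + 0.5 * dt_s * k2w, u)
            k4q, k4w = deriv(q + dt_s * k3q, w + dt_s * k3w, u)
            q = q + dt_s / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
            w = w + dt_s / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
            qs[k + 1] = np.rad2deg(q)
            ws[k + 1] = np.rad2deg(w)
            ts[k + 1] = t + dt_s
            if np.any(qs[k + 1] < lo) or np.any(qs[k + 1] > hi):
                halted, reason = True, (
                    f"joint limit guard band exceeded at t={t + dt_s:.3f}s "
                    f"(angles {qs[k + 1].round(2)})")
                qs, ws, ts = qs[:k + 2], ws[:k + 2], ts[:k + 2]
                break

        return Trajectory(ts, qs, ws, self.forward_kinematics_batch(qs),
                          halted, reason)

    # -------------------------------------------------------- serialisation
    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "link_lengths_m": list(self.link_lengths_m),
            "link_masses_kg": list(self.link_masses_kg),
            "damping_base": self.damping_base,
            "damping_per_activation": self.damping_per_activation,
            "passive_amplitude_nm": self.passive_amplitude_nm,
            "passive_length_const_deg": self.passive_length_const_deg,
            "muscles": [
                {"name": m.name,
                 "recruitment_threshold": m.recruitment_threshold,
                 "recruitment_saturation": m.recruitment_saturation,
                 "fatigue_rate": m.fatigue_rate,
                 "actions": [{"joint": a.joint,
                              "peak_torque_nm": a.peak_torque_nm,
                              "fl_center_deg": a.fl_center_deg,
                              "fl_width_deg": a.fl_width_deg,
                              "fl_floor": a.fl_floor} for a in m.actions]}
                for m in self.muscles],
            "electrodes": [
                {"id": e.id,
                 "targets": [{"muscle": t.muscle, "threshold": t.threshold,
                              "saturation": t.saturation}
                             for t in e.targets]}
                for e in self.electrodes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArmModel":
        muscles = [MuscleSpec(
            name=m["name"],
            actions=tuple(JointAction(**a) for a in m["actions"]),
            recruitment_threshold=m["recruitment_threshold"],
            recruitment_saturation=m["recruitment_saturation"],
            fatigue_rate=m["fatigue_rate"]) for m in d["muscles"]]
        electrodes = [ElectrodeSpec(
            id=e["id"],
            targets=tuple(ElectrodeTarget(**t) for t in e["targets"]))
            for e in d["electrodes"]]
        return cls(muscles, electrodes,
                   tuple(d["link_lengths_m"]), tuple(d["link_masses_kg"]),
                   d["damping_base"], d["damping_per_activation"],
                   d["passive_amplitude_nm"], d["passive_length_const_deg"],
                   d.get("scenario", "custom"))


# ------------------------------------------------------------- arm factories
def _mid(j: int) -> float:
    return 0.5 * (_LIMITS[j][0] + _LIMITS[j][1])


def _flex(joint: str, peak: float) -> JointAction:
    j = JOINTS.index(joint)
    return JointAction(joint, peak, _mid(j) - FL_OFFSET_DEG)


def _ext(joint: str, peak: float) -> JointAction:
    j = JOINTS.index(joint)
    return JointAction(joint, -abs(peak), _mid(j) + FL_OFFSET_DEG)


def _base_muscles() -> list[MuscleSpec]:
    return [
        MuscleSpec("anterior_deltoid", (_flex("shoulder", 40.0),)),
        MuscleSpec("posterior_deltoid", (_ext("shoulder", 40.0),)),
        MuscleSpec("brachialis", (_flex("elbow", 30.0),)),
        MuscleSpec("triceps_lateral", (_ext("elbow", 30.0),)),
        MuscleSpec("biceps", (_flex("shoulder", 10.0), _flex("elbow", 25.0))),
        MuscleSpec("triceps_long", (_ext("shoulder", 10.0), _ext("elbow", 25.0))),
    ]


def make_default_arm() -> ArmModel:
    """Six muscles, one dedicated electrode each (uniform-recruitment case)."""
    muscles = _base_muscles()
    electrodes = [ElectrodeSpec(m.name, (ElectrodeTarget(m.name),))
                  for m in muscles]
    return ArmModel(muscles, electrodes, scenario="default")


def make_spillover_arm(scenario: str) -> ArmModel:
    """Replace the biceps channel with one electrode recruiting two
    hypothetical monoarticular flexors (one shoulder, one elbow).

    Scenario "A" (the commoner shape): the second muscle recruits at higher
    current, so both joint torques rise monotonically but their ratio drifts
    with stimulation level.

    Scenario "B" (the rarer shape): staggered recruitment plus early
    saturation of the first muscle, so the joint-torque ordering reverses
    across the stimulation range.
    """
    scenario = scenario.upper()
    muscles = [m for m in _base_muscles() if m.name != "biceps"]
    if scenario == "A":
        muscles += [
            MuscleSpec("spill_elbow_flexor", (_flex("elbow", 25.0),),
                       recruitment_threshold=0.10, recruitment_saturation=0.90),
            MuscleSpec("spill_shoulder_flexor", (_flex("shoulder", 10.0),),
                       recruitment_threshold=0.45, recruitment_saturation=0.95),
        ]
    elif scenario == "B":
        muscles += [
            MuscleSpec("spill_elbow_flexor", (_flex("elbow", 12.0),),
                       recruitment_threshold=0.05, recruitment_saturation=0.45),
            MuscleSpec("spill_shoulder_flexor", (_flex("shoulder", 20.0),),
                       recruitment_threshold=0.35, recruitment_saturation=0.90),
        ]
    else:
        raise ValueError(f"unknown spillover scenario {scenario!r}")
    electrodes = [ElectrodeSpec(m.name, (ElectrodeTarget(m.name),))
                  for m in muscles if not m.name.startswith("spill_")]
    electrodes.insert(4, ElectrodeSpec(
        "spill_channel", (ElectrodeTarget("spill_elbow_flexor"),
                          ElectrodeTarget("spill_shoulder_flexor"))))
    return ArmModel(muscles, electrodes, scenario=f"spillover_{scenario}")


def make_arm(name: str) -> ArmModel:
    """Factory by preset name: 'default', 'spillover_A', 'spillover_B'."""
    if name == "default":
        return make_default_arm()
    if name.startswith("spillover_"):
        return make_spillover_arm(name.split("_", 1)[1])
    raise ValueError(f"unknown arm scenario {name!r}")
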