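"""Balanced-torque equation systems and the bounded minimum-norm solver.

For a posture and a stiffness level S (Nm of balanced opposing torques),
each joint contributes a flexion equation S - Pf = sum_i c_i * Afmax_i and
an extension equation -S - Pe = sum_i c_i * Aemax_i. Stacking both joints
gives x = A c with one column per electrode and 2 rows per joint; the
least-squares minimum-norm solution distributes work across redundant
muscles, and an iterative clamping pass enforces c in [0, 1] (a muscle can
neither push nor exceed its maximum).

When one electrode recruits several muscles with different thresholds
("current spillover"), the joint-torque ratio of that channel depends on the
stimulation level, so a fixed A matrix built from per-joint maxima is wrong
at the operating point. :func:`iterate_spillover` re-solves while replacing
the channel's secondary-joint entry with its torque at the stimulation level
implied by the current solution, until the coefficients stop moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._curves import MonotoneCurveSet
from .calibration import CalibrationData

__all__ = [
    "ROW_LABELS", "EquationSystem", "ScaleVector", "SpilloverResult",
    "SystemCurves", "build_system", "system_curves", "solve_bounded_min_norm",
    "iterate_spillover", "residual", "rebalance", "RebalancePlan",
]

ROW_LABELS = ("shoulder_flexion", "shoulder_extension",
              "elbow_flexion", "elbow_extension")

_INTERIOR, _CLAMPED_ZERO, _CLAMPED_ONE, _DROPPED = (
    "interior", "clamped_zero", "clamped_one", "dropped")


@dataclass
class EquationSystem:
    x: np.ndarray                      # (4,) torque targets per row
    A: np.ndarray                      # (4, m) signed max active torques
    S: float
    config: np.ndarray                 # (2,) shoulder, elbow degrees
    column_labels: tuple[str, ...]

    @property
    def n_columns(self) -> int:
        return self.A.shape[1]


@dataclass
class ScaleVector:
    c: np.ndarray                      # (m,) in [0, 1]
    status: list[str]
    residual: np.ndarray               # (4,) A c - x
    residual_norm: float
    infeasible: bool = False

    @property
    def interior(self) -> bool:
        return all(s == _INTERIOR for s in self.status)


@dataclass
class SpilloverResult:
    scales: ScaleVector
    iterations: int
    converged: bool
    residual_trace: list[float]
    notes: list[str] = field(default_factory=list)

    @property
    def initial_residual(self) -> float:
        return self.residual_trace[0]

    @property
    def final_residual(self) -> float:
        return self.residual_trace[-1]


def build_system(config, S: float, calib: CalibrationData,
                 adjustments: np.ndarray | dict | None = None) -> EquationSystem:
    """Assemble x and A for one (posture, stiffness) pair.

    Off-grid postures use per-dimension linear interpolation of the passive
    and max-torque tables. ``adjustments`` scales whole columns (the work
    redistribution mechanism); give a per-electrode array or a dict keyed by
    electrode id.
    """
    if S <= 0:
        raise ValueError("stiffness must be positive")
    q = np.asarray(getattr(config, "as_array", lambda: config)(), dtype=float)
    pf, pe = calib.passive_at(q[None])
    pf, pe = pf[0], pe[0]
    maxt = calib.max_torque_at(q[None])[0]          # (m, 2) signed
    x = np.array([S - pf[0], -S - pe[0], S - pf[1], -S - pe[1]])
    m = maxt.shape[0]
    A = np.zeros((4, m))
    for j in range(2):
        A[2 * j] = np.where(maxt[:, j] > 0, maxt[:, j], 0.0)
        A[2 * j + 1] = np.where(maxt[:, j] < 0, maxt[:, j], 0.0)
    if adjustments is not None:
        A = A * _as_factors(adjustments, calib.electrode_ids)[None, :]
    return EquationSystem(x, A, float(S), q, calib.electrode_ids)


def _as_factors(adjustments, electrode_ids) -> np.ndarray:
    if isinstance(adjustments, dict):
        f = np.ones(len(electrode_ids))
        for k, v in adjustments.items():
            f[list(electrode_ids).index(k)] = v
    else:
        f = np.asarray(adjustments, dtype=float)
    if np.any(f <= 0.0) or np.any(f > 1.0):
        raise ValueError("adjustment factors must lie in (0, 1]")
    return f


def _kkt_violation(A: np.ndarray, x: np.ndarray, c: np.ndarray) -> float:
    """Stationarity violation of min ||Ac - x|| over the [0, 1] box."""
    g = A.T @ (A @ c - x)
    v = np.where(c <= 1e-12, np.minimum(g, 0.0),
                 np.where(c >= 1.0 - 1e-12, np.maximum(g, 0.0), g))
    return float(np.abs(v).max(initial=0.0))


def _solve_bounded(A0: np.ndarray, x0: np.ndarray,
                   bound_tol: float = 1e-9):
    """Core bounded minimum-norm solve. Returns (c, status, residual).

    Primary path: the one-at-a-time clamping pass (drop pushing muscles,
    saturate over-asked ones, re-solve). On near-degenerate systems —
    typically two nearly proportional biarticular columns — that pass can
    clamp the wrong column first; a KKT stationarity check catches this and
    a box-constrained least-squares polish restores the optimal residual.
    """
    m = A0.shape[1]
    status = [_INTERIOR] * m
    c = np.zeros(m)
    active = [j for j in range(m) if np.linalg.norm(A0[:, j]) > 1e-12]
    dropped_zero = [j for j in range(m) if j not in active]
    for j in dropped_zero:
        status[j] = _DROPPED
    x_work = x0.copy()

    while active:
        Aw = A0[:, active]
        cw = np.linalg.pinv(Aw, rcond=1e-12) @ x_work
        neg = cw < -bound_tol
        over = cw > 1.0 + bound_tol
        if not (neg.any() or over.any()):
            for k, j in enumerate(active):
                c[j] = min(max(cw[k], 0.0), 1.0)
            break
        viol = np.where(neg, -cw, 0.0) + np.where(over, cw - 1.0, 0.0)
        k = int(np.argmax(viol))
        j = active[k]
        if neg[k]:
            status[j] = _CLAMPED_ZERO
            c[j] = 0.0
        else:
            status[j] = _CLAMPED_ONE
            c[j] = 1.0
            x_work = x_work - A0[:, j]
        active.remove(j)

    clamped = any(s in (_CLAMPED_ZERO, _CLAMPED_ONE) for s in status)
    if clamped and _kkt_violation(A0, x0, c) > 1e-7 * max(
            1.0, float(np.abs(A0).max())):
        from scipy.optimize import lsq_linear
        sol = lsq_linear(A0, x0, bounds=(0.0, 1.0), method="bvls",
                         tol=1e-14)
        c = np.clip(sol.x, 0.0, 1.0)
        for j in range(m):
            if j in dropped_zero:
                continue
            status[j] = (_CLAMPED_ZERO if c[j] <= 1e-10 else
                         _CLAMPED_ONE if c[j] >= 1.0 - 1e-10 else _INTERIOR)

    return c, status, A0 @ c - x0


def solve_bounded_min_norm(system: EquationSystem,
                           bound_tol: float = 1e-9) -> ScaleVector:
    """Least-squares minimum-norm solve with [0, 1] bounds on the scales.

    The unconstrained minimum-norm solution is computed by pseudoinverse
    (singular values below 1e-12 of the largest are cut). Bounds are then
    enforced one violation at a time, largest first: a negative scale means
    the solution wants the muscle to push, so that column is removed and the
    system re-solved; a scale above one is fixed at its maximum by removing
    the column and subtracting its full torques from the targets.
    """
    if system.n_columns < 1:
        raise ValueError("system has no columns")
    c, status, r = _solve_bounded(system.A, system.x, bound_tol)
    rnorm = float(np.linalg.norm(r))
    return ScaleVector(c, status, r, rnorm, infeasible=rnorm > 1e-6)


@dataclass
class SystemCurves:
    """Per-electrode stimulation-to-torque samples at one posture."""

    u: np.ndarray            # (k,)
    torque: np.ndarray       # (m, k, 2) signed
    reference_joint: np.ndarray  # (m,) int

    def __post_init__(self):
        # monotone magnitude curves on each electrode's reference joint
        ref = np.abs(self.torque[np.arange(self.torque.shape[0]), :,
                                 self.reference_joint])    # (m, k)
        self._ref_inv = MonotoneCurveSet(self.u, ref.T)
        self._fwd = MonotoneCurveSet(self.u, np.moveaxis(self.torque, 1, 0))

    def stim_for_reference_torque(self, target_mag: np.ndarray):
        """Invert each reference curve at |target| -> (u, clipped flags)."""
        return self._ref_inv.invert(np.asarray(target_mag, dtype=float))

    def torques_at(self, u: np.ndarray) -> np.ndarray:
        """Signed per-joint torques (m, 2) at per-electrode levels u (m,)."""
        return self._fwd.evaluate(np.asarray(u, dtype=float)[:, None])


def system_curves(calib: CalibrationData, config) -> SystemCurves:
    """Curves for one posture, interpolated from the calibration grid."""
    q = np.asarray(getattr(config, "as_array", lambda: config)(), dtype=float)
    tq = calib.curves_at(q[None])[0]                  # (m, k, 2)
    ref = np.argmax(np.abs(tq).max(axis=1), axis=-1)
    return SystemCurves(calib.curve_u, tq, ref)


def residual(system: EquationSystem, c: np.ndarray,
             curves: SystemCurves | None = None):
    """Per-row torque errors and their norm for a candidate solution.

    Without curves this is simply A c - x. With curves, the "actual" torques
    are read off the measured sweeps at the stimulation each coefficient
    implies (inverting the reference-joint curve at c_i times the reference
    max), which exposes the error a spillover channel really produces.
    """
    c = np.asarray(c, dtype=float)
    if curves is None:
        r = system.A @ c - system.x
        return r, float(np.linalg.norm(r))
    m = system.n_columns
    ref = curves.reference_joint
    ref_max = np.abs(system.A[:, np.arange(m)][2 * ref, np.arange(m)])
    ref_max = np.maximum(ref_max, np.abs(
        system.A[2 * ref + 1, np.arange(m)]))
    u, _ = curves.stim_for_reference_torque(c * ref_max)
    u = np.where(c <= 0.0, 0.0, u)
    tq = curves.torques_at(u)                          # (m, 2) signed
    actual = np.zeros(4)
    for j in range(2):
        tj = tq[:, j]
        actual[2 * j] += tj[tj > 0].sum()
        actual[2 * j + 1] += tj[tj < 0].sum()
    r = actual - system.x
    return r, float(np.linalg.norm(r))


def iterate_spillover(system: EquationSystem, curves: SystemCurves,
                      tol: float = 1e-3, max_iter: int = 1000,
                      mode: str = "norm") -> SpilloverResult:
    """Fixed-point iteration for stimulation-dependent joint-torque ratios.

    Each pass solves the bounded minimum-norm problem, then, for every
    electrode acting on both joints, replaces the secondary-joint entry of A
    with that channel's measured torque at the stimulation level the current
    coefficient implies (scaled so the reference entry stays the measured
    max). Stops when the coefficient change is below ``tol`` (vector norm by
    default, per-element with mode="element") or at ``max_iter``.
    """
    if mode not in ("norm", "element"):
        raise ValueError("mode must be 'norm' or 'element'")
    m = system.n_columns
    ref = curves.reference_joint
    multi = [j for j in range(m)
             if np.count_nonzero(np.abs(system.A[:, j]) > 1e-12) > 1]
    A_work = system.A.copy()
    notes: list[str] = []
    trace: list[float] = []
    c_prev = None
    sv = None
    iterations = 0
    converged = False
    for it in range(1, max_iter + 1):
        iterations = it
        work = EquationSystem(system.x, A_work, system.S, system.config,
                              system.column_labels)
        sv = solve_bounded_min_norm(work)
        _, rn = residual(system, sv.c, curves)
        trace.append(rn)
        if c_prev is not None:
            delta = sv.c - c_prev
            d = np.linalg.norm(delta) if mode == "norm" else np.abs(delta).max()
            if d < tol:
                converged = True
                iterations = it - 1  # the previous solution already held
                break
        c_prev = sv.c.copy()
        for j in multi:
            rj = int(ref[j])
            ref_row = 2 * rj if system.A[2 * rj, j] != 0 else 2 * rj + 1
            ref_entry = system.A[ref_row, j]
            if sv.c[j] <= 0.0:
                notes.append(f"iter {it}: c=0 on column {j}, entry kept")
                continue
            u_star, _ = curves.stim_for_reference_torque(
                np.where(np.arange(m) == j, sv.c[j] * abs(ref_entry), 0.0))
            tq = curves.torques_at(u_star)[j]          # (2,) signed
            t_ref = tq[rj]
            if abs(t_ref) < 1e-12:
                notes.append(f"iter {it}: zero reference torque on column {j}")
                continue
            other = 1 - rj
            scale = abs(ref_entry) / abs(t_ref)
            val = tq[other] * scale
            A_work[2 * other, j] = val if val > 0 else 0.0
            A_work[2 * other + 1, j] = val if val < 0 else 0.0
    if not converged:
        notes.append(f"not converged after {max_iter} iterations")
    return SpilloverResult(sv, iterations, converged, trace, notes)


@dataclass
class SpilloverBatchResult:
    """Lockstep fixed-point iteration results over many systems.

    Systems are ordered posture-major with the stiffness index fastest.
    """

    c: np.ndarray                  # (Nsys, m)
    iterations: np.ndarray         # (Nsys,)
    converged: np.ndarray          # (Nsys,) bool
    initial_residual: np.ndarray   # (Nsys,) curve residual of first solve
    final_residual: np.ndarray     # (Nsys,)
    linear_residual: np.ndarray    # (Nsys,) ||A c - x|| of the final solve
    interior: np.ndarray           # (Nsys,) bool


def iterate_spillover_batch(calib: CalibrationData, stiffness_nm,
                            adjustments=None, tol: float = 1e-3,
                            max_iter: int = 1000,
                            mode: str = "norm") -> SpilloverBatchResult:
    """Run the spillover fixed-point iteration over a whole grid at once.

    Semantically identical to calling :func:`iterate_spillover` for every
    (posture, stiffness) pair, but the curve inversions and evaluations run
    vectorised across all systems while only the not-yet-converged systems
    are re-solved each sweep.
    """
    S_levels = np.atleast_1d(np.asarray(stiffness_nm, dtype=float))
    nk = S_levels.size
    m = calib.n_electrodes
    ncfg = calib.sho_angles.size * calib.elb_angles.size
    nsys = ncfg * nk
    alpha = (np.ones(m) if adjustments is None
             else _as_factors(adjustments, calib.electrode_ids))

    pf = calib.pf.reshape(ncfg, 2)
    pe = calib.pe.reshape(ncfg, 2)
    maxt = calib.max_torque.reshape(ncfg, m, 2)
    A_cfg = np.zeros((ncfg, 4, m))
    for j in range(2):
        A_cfg[:, 2 * j] = np.where(maxt[..., j] > 0, maxt[..., j], 0.0)
        A_cfg[:, 2 * j + 1] = np.where(maxt[..., j] < 0, maxt[..., j], 0.0)
    A_cfg *= alpha[None, None, :]
    A = np.repeat(A_cfg, nk, axis=0)                       # (Nsys, 4, m)
    x = np.empty((nsys, 4))
    x[:, 0] = (S_levels[None] - pf[:, [0]]).reshape(-1)
    x[:, 1] = (-S_levels[None] - pe[:, [0]]).reshape(-1)
    x[:, 2] = (S_levels[None] - pf[:, [1]]).reshape(-1)
    x[:, 3] = (-S_levels[None] - pe[:, [1]]).reshape(-1)

    fwd, inv = calib.reference_curve_sets(n_rep=nk)
    ref = np.repeat(calib.reference_joints().reshape(ncfg, m), nk, axis=0)
    ref_entry = np.abs(np.take_along_axis(
        np.repeat(maxt, nk, axis=0), ref[:, :, None], axis=2))[:, :, 0]
    ref_entry = ref_entry * alpha[None, :]                 # (Nsys, m)
    multi = [e for e in range(m)
             if np.any(np.count_nonzero(np.abs(A_cfg[:, :, e]) > 1e-12,
                                        axis=1) > 1)]

    def _curve_residual_norms(c):
        u = np.empty((nsys, m))
        for e in range(m):
            ue, _ = inv[e].invert(c[:, e] * ref_entry[:, e])
            u[:, e] = np.where(c[:, e] <= 0.0, 0.0, ue)
        actual = np.zeros((nsys, 4))
        for e in range(m):
            tq = fwd[e].evaluate(u[:, [e]])                # (Nsys, 2)
            for j in range(2):
                tj = tq[:, j]
                actual[:, 2 * j] += np.where(tj > 0, tj, 0.0)
                actual[:, 2 * j + 1] += np.where(tj < 0, tj, 0.0)
        return np.linalg.norm(actual - x, axis=1)

    c = np.zeros((nsys, m))
    lin_res = np.zeros(nsys)
    interior = np.zeros(nsys, dtype=bool)
    iterations = np.zeros(nsys, dtype=int)
    converged = np.zeros(nsys, dtype=bool)
    initial = np.zeros(nsys)
    final = np.zeros(nsys)
    active = np.ones(nsys, dtype=bool)
    c_prev = None

    for it in range(1, max_iter + 1):
        idx = np.where(active)[0]
        for s in idx:
            cs, status, r = _solve_bounded(A[s], x[s])
            c[s] = cs
            lin_res[s] = np.linalg.norm(r)
            interior[s] = all(st == _INTERIOR for st in status)
        rn = _curve_residual_norms(c)
        if it == 1:
            initial[:] = rn
        final[idx] = rn[idx]
        iterations[idx] = it
        if c_prev is not None:
            delta = c - c_prev
            d = (np.linalg.norm(delta, axis=1) if mode == "norm"
                 else np.abs(delta).max(axis=1))
            done = active & (d < tol)
            converged |= done
            iterations[done] = it - 1  # previous solution already held
            active &= ~done
            if not active.any():
                break
        c_prev = c.copy()
        for e in multi:
            u_star, _ = inv[e].invert(c[:, e] * ref_entry[:, e])
            tq = fwd[e].evaluate(u_star[:, None])          # (Nsys, 2)
            t_ref = np.take_along_axis(tq, ref[:, [e]], axis=1)[:, 0]
            other = 1 - ref[:, e]
            t_oth = np.take_along_axis(tq, other[:, None], axis=1)[:, 0]
            ok = active & (c[:, e] > 0.0) & (np.abs(t_ref) > 1e-12)
            idx_ok = np.where(ok)[0]
            v = (t_oth[idx_ok] * ref_entry[idx_ok, e]
                 / np.abs(t_ref[idx_ok]))
            rp = 2 * other[idx_ok]
            A[idx_ok, rp, e] = np.where(v > 0, v, 0.0)
            A[idx_ok, rp + 1, e] = np.where(v < 0, v, 0.0)
    return SpilloverBatchResult(c, iterations, converged, initial, final,
                                lin_res, interior)


@dataclass
class RebalancePlan:
    """Column scaling that shifts work away from de-emphasised muscles.

    Solving with columns scaled by alpha makes the minimum-norm objective
    treat the scaled muscle as weaker, so redundancy partners take over.
    Converting the resulting coefficient to stimulation must target
    c_i * alpha_i times the *unscaled* max on the unscaled measured curve, so
    at build time the plant lands on exactly the same equilibrium.
    """

    calib: CalibrationData
    factors: np.ndarray          # (m,) in (0, 1]

    def build(self, config, S: float) -> EquationSystem:
        return build_system(config, S, self.calib, adjustments=self.factors)

    def realized_torque_targets(self, c: np.ndarray, config) -> np.ndarray:
        """Signed per-joint torques each electrode is asked to produce."""
        q = np.asarray(getattr(config, "as_array", lambda: config)(), dtype=float)
        maxt = self.calib.max_torque_at(q[None])[0]
        return c[:, None] * self.factors[:, None] * maxt


def rebalance(calib: CalibrationData,
              factors: np.ndarray | dict) -> RebalancePlan:
    """Validated column-scaling plan (alpha in (0, 1] per electrode)."""
    return RebalancePlan(calib, _as_factors(factors, calib.electrode_ids))
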