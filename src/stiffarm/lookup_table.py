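"""Building, verifying and querying the stimulation lookup table.

The controller's product is a table over (shoulder angle, elbow angle,
stiffness) holding the stimulation vector that puts the plant at that
posture with that degree of balanced co-contraction. Building it follows the
calibration-session recipe: solve the balanced-torque system at every grid
node, convert scale factors to stimulation through the measured
stimulation-to-torque curves, apply the stimulation to the (simulated) arm
to record where it actually settles, and key the final table by those
achieved postures. Queries interpolate linearly one dimension at a time;
queries outside the sampled hull extrapolate from the edge cell and are
flagged, and anything more than 10 degrees beyond the hull is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arm_model import ArmModel, FatigueState, JointConfig
from .calibration import CalibrationData
from .torque_solver import (ScaleVector, SystemCurves, build_system,
                            solve_bounded_min_norm, system_curves)

__all__ = [
    "LookupTable", "scales_to_stims", "build_initial_table", "verify_table",
    "finalize_table", "query", "downsample_and_interpolate",
    "workspace_feasibility",
]

PROV_MEASURED, PROV_INTERPOLATED, PROV_EXTRAPOLATED = 0, 1, 2


@dataclass
class LookupTable:
    sho_angles: np.ndarray             # (Ns,)
    elb_angles: np.ndarray             # (Ne,)
    stiffness_nm: np.ndarray           # (Nk,)
    stims: np.ndarray                  # (Ns, Ne, Nk, m) in [0, 1]
    scales: np.ndarray                 # (Ns, Ne, Nk, m) solved c vectors
    feasible: np.ndarray               # (Ns, Ne, Nk) bool
    residual_norm: np.ndarray          # (Ns, Ne, Nk)
    provenance: np.ndarray             # (Ns, Ne, Nk) int
    electrode_ids: tuple[str, ...]
    metadata: dict = field(default_factory=dict)
    achieved: np.ndarray | None = None # (Ns, Ne, Nk, 2) after verification
    achieved_ok: np.ndarray | None = None

    @property
    def n_electrodes(self) -> int:
        return self.stims.shape[-1]

    @property
    def is_final(self) -> bool:
        return self.achieved is not None

    def node_configs(self) -> np.ndarray:
        """Intended (shoulder, elbow) per node, (Ns, Ne, 2)."""
        return np.stack(np.meshgrid(self.sho_angles, self.elb_angles,
                                    indexing="ij"), axis=-1)


def scales_to_stims(scales: ScaleVector | np.ndarray, curves: SystemCurves,
                    ref_max: np.ndarray,
                    adjustments: np.ndarray | None = None):
    """Invert the measured curves to stimulation for one solved node.

    Each electrode's target torque is c_i * alpha_i * |max_i| on its
    reference joint, inverted on the *unscaled* measured curve. c = 0 maps
    to u = 0; targets beyond the curve maximum (possible against a fatigued
    plant) clamp to u = 1 and are flagged.
    """
    c = scales.c if isinstance(scales, ScaleVector) else np.asarray(scales)
    alpha = np.ones_like(c) if adjustments is None else np.asarray(adjustments)
    target = c * alpha * np.abs(ref_max)
    u, clipped = curves.stim_for_reference_torque(target)
    u = np.where(clipped & (target > 0), 1.0, u)
    u = np.where(c * alpha <= 0.0, 0.0, u)
    return np.clip(u, 0.0, 1.0), clipped


def build_initial_table(calib: CalibrationData,
                        stiffness_nm=None,
                        adjustments: np.ndarray | dict | None = None,
                        spillover_tol: float = 1e-3,
                        spillover_max_iter: int = 1000) -> LookupTable:
    """Solve every (posture, stiffness) node and convert to stimulation.

    Channels flagged as spillover trigger the fixed-point iteration;
    otherwise the single bounded minimum-norm solve suffices. Infeasible
    nodes (requested stiffness unreachable at that posture) are flagged but
    the table still completes.
    """
    from .torque_solver import (_as_factors, _solve_bounded,
                                iterate_spillover_batch)
    sho, elb = calib.sho_angles, calib.elb_angles
    S_levels = np.asarray(stiffness_nm if stiffness_nm is not None
                          else calib.grid.stiffness_nm, dtype=float)
    m = calib.n_electrodes
    nk = S_levels.size
    ncfg = sho.size * elb.size
    nsys = ncfg * nk
    alpha = (None if adjustments is None
             else _as_factors(adjustments, calib.electrode_ids))
    alpha_vec = np.ones(m) if alpha is None else alpha
    use_iteration = bool(calib.spillover.any())

    shape = (sho.size, elb.size, nk)
    iters = np.zeros(shape, dtype=int)
    conv = np.ones(shape, dtype=bool)

    pf = calib.pf.reshape(ncfg, 2)
    pe = calib.pe.reshape(ncfg, 2)
    maxt = calib.max_torque.reshape(ncfg, m, 2)
    x = np.empty((nsys, 4))
    x[:, 0] = (S_levels[None] - pf[:, [0]]).reshape(-1)
    x[:, 1] = (-S_levels[None] - pe[:, [0]]).reshape(-1)
    x[:, 2] = (S_levels[None] - pf[:, [1]]).reshape(-1)
    x[:, 3] = (-S_levels[None] - pe[:, [1]]).reshape(-1)

    if use_iteration:
        batch = iterate_spillover_batch(calib, S_levels, alpha,
                                        spillover_tol, spillover_max_iter)
        c = batch.c
        resid = batch.linear_residual
        feasible = batch.converged & (batch.linear_residual < 1e-6)
        iters = batch.iterations.reshape(shape)
        conv = batch.converged.reshape(shape)
    else:
        A_cfg = np.zeros((ncfg, 4, m))
        for j in range(2):
            A_cfg[:, 2 * j] = np.where(maxt[..., j] > 0, maxt[..., j], 0.0)
            A_cfg[:, 2 * j + 1] = np.where(maxt[..., j] < 0,
                                           maxt[..., j], 0.0)
        A_cfg *= alpha_vec[None, None, :]
        c = np.empty((nsys, m))
        resid = np.empty(nsys)
        for s in range(nsys):
            cs, _, r = _solve_bounded(A_cfg[s // nk], x[s])
            c[s] = cs
            resid[s] = np.linalg.norm(r)
        feasible = resid < 1e-6

    # convert scales to stimulation through the measured (unscaled) curves
    _, inv = calib.reference_curve_sets(n_rep=1)
    ref = calib.reference_joints().reshape(ncfg, m)
    ref_max = np.abs(np.take_along_axis(maxt, ref[:, :, None],
                                        axis=2))[:, :, 0]   # (Ncfg, m)
    stims = np.empty((nsys, m))
    c3 = c.reshape(ncfg, nk, m)
    u3 = np.empty((ncfg, nk, m))
    for e in range(m):
        for k in range(nk):
            target = c3[:, k, e] * alpha_vec[e] * ref_max[:, e]
            ue, _ = inv[e].invert(target)
            u3[:, k, e] = np.where(target <= 0.0, 0.0, ue)
    stims = np.clip(u3.reshape(nsys, m), 0.0, 1.0)

    return LookupTable(
        sho, elb, S_levels, stims.reshape(shape + (m,)),
        c.reshape(shape + (m,)), feasible.reshape(shape),
        resid.reshape(shape),
        np.full(shape, PROV_MEASURED, dtype=int), calib.electrode_ids,
        metadata={
            "arm_scenario": calib.arm_scenario,
            "grid_step_deg": [calib.grid.shoulder[2], calib.grid.elbow[2]],
            "adjustments": None if alpha is None else alpha.tolist(),
            "spillover_iteration": use_iteration,
            "spillover_iterations": iters,
            "spillover_converged": conv,
        })


def verify_table(table: LookupTable, arm: ArmModel,
                 fatigue: FatigueState | None = None):
    """Apply every node's stimulation and record where the arm settles.

    Returns (achieved (Ns, Ne, Nk, 2), ok mask, fingertip displacement cm).
    """
    shape = table.stims.shape[:3]
    n = int(np.prod(shape))
    U = table.stims.reshape(n, -1)
    intended = np.repeat(table.node_configs().reshape(-1, 2),
                         shape[2], axis=0)
    th, ok, _, _ = arm.equilibrium_batch(U, intended, fatigue)
    disp = np.linalg.norm(arm.forward_kinematics_batch(th)
                          - arm.forward_kinematics_batch(intended), axis=1)
    return (th.reshape(shape + (2,)), ok.reshape(shape),
            disp.reshape(shape))


def finalize_table(table: LookupTable, achieved: np.ndarray,
                   achieved_ok: np.ndarray | None = None) -> LookupTable:
    """Key the table by achieved postures (index grid plus offset).

    The achieved angles form a slightly irregular grid; queries treat the
    intended angles as the index grid and correct the query point by the
    locally interpolated achieved-minus-intended offset, an approximation
    that is exact when the offsets vanish (noise-free calibration).
    """
    out = LookupTable(
        table.sho_angles, table.elb_angles, table.stiffness_nm,
        table.stims.copy(), table.scales.copy(), table.feasible.copy(),
        table.residual_norm.copy(), table.provenance.copy(),
        table.electrode_ids, dict(table.metadata),
        achieved=np.asarray(achieved, dtype=float),
        achieved_ok=(np.ones(table.stims.shape[:3], dtype=bool)
                     if achieved_ok is None else achieved_ok))
    return out


def _interp_3d(sho, elb, S_levels, values, q, S):
    """Per-dimension linear interpolation (shoulder, elbow, stiffness)."""
    n = q.shape[0]
    Sq = np.broadcast_to(np.asarray(S, dtype=float), (n,))

    def _locate(pts, x):
        if pts.size == 1:
            return np.zeros(x.shape, dtype=int), np.zeros_like(x)
        i = np.clip(np.searchsorted(pts, x, side="right") - 1, 0, pts.size - 2)
        return i, (x - pts[i]) / (pts[i + 1] - pts[i])

    i, wi = _locate(sho, q[:, 0])
    j, wj = _locate(elb, q[:, 1])
    k, wk = _locate(S_levels, Sq)
    v = values
    acc = 0.0
    for di, fi in ((0, 1 - wi), (1, wi)):
        ii = np.minimum(i + di, sho.size - 1)
        for dj, fj in ((0, 1 - wj), (1, wj)):
            jj = np.minimum(j + dj, elb.size - 1)
            for dk, fk in ((0, 1 - wk), (1, wk)):
                kk = np.minimum(k + dk, S_levels.size - 1)
                w = (fi * fj * fk)[:, None]
                acc = acc + w * v[ii, jj, kk]
    return acc


def _cubic_seq(sho, elb, S_levels, values, q, S):
    """Per-dimension spline interpolation (shoulder, elbow, stiffness).

    Cubic where an axis has >= 4 nodes, degrading gracefully on short axes.
    Queries are clipped to the hull (cubic extrapolation is not offered).
    """
    from scipy.interpolate import make_interp_spline
    n = q.shape[0]
    Sq = np.broadcast_to(np.asarray(S, dtype=float), (n,))
    out = np.empty((n, values.shape[-1]))
    axes = (sho, elb, S_levels)
    for i in range(n):
        coords = (q[i, 0], q[i, 1], Sq[i])
        v = values
        for pts, x in zip(axes, coords):
            if pts.size == 1:
                v = v[0]
                continue
            k = min(3, pts.size - 1)
            xq = float(np.clip(x, pts[0], pts[-1]))
            v = make_interp_spline(pts, v, k=k, axis=0)(xq)
        out[i] = v
    return out


def query(table: LookupTable, config, S,
          refuse_beyond_deg: float = 10.0, method: str = "linear"):
    """Stimulation vector(s) for desired posture(s) and stiffness.

    config : JointConfig or (N, 2) array; S scalar or (N,).
    Returns (stims, extrapolated flags). Inside the grid the default is
    linear interpolation one dimension at a time (trilinear); outside the
    hull the edge cell extrapolates linearly and the query is flagged; more
    than ``refuse_beyond_deg`` beyond the hull raises. ``method="cubic"``
    switches to per-dimension cubic splines (hull-clipped, no
    extrapolation).
    """
    if method not in ("linear", "cubic"):
        raise ValueError("method must be 'linear' or 'cubic'")
    scalar = isinstance(config, JointConfig)
    q = (config.as_array()[None] if scalar
         else np.asarray(config, dtype=float))
    lo = np.array([table.sho_angles[0], table.elb_angles[0]])
    hi = np.array([table.sho_angles[-1], table.elb_angles[-1]])
    if np.any(q < lo - refuse_beyond_deg) or np.any(q > hi + refuse_beyond_deg):
        raise ValueError("query more than "
                         f"{refuse_beyond_deg} deg beyond the table hull")
    extrap = np.any((q < lo) | (q > hi), axis=1)
    q_eff = q
    if table.is_final:
        offs = table.achieved - table.node_configs()[:, :, None, :]
        delta = _interp_3d(table.sho_angles, table.elb_angles,
                           table.stiffness_nm, offs, q, S)
        q_eff = q - delta
        # querying a node's achieved posture must return its stored
        # stimulation bit-identically: snap near-node corrected queries
        for ax, pts in ((0, table.sho_angles), (1, table.elb_angles)):
            i = np.clip(np.searchsorted(pts, q_eff[:, ax]), 0, pts.size - 1)
            j = np.clip(i - 1, 0, pts.size - 1)
            for idx in (i, j):
                near = np.abs(q_eff[:, ax] - pts[idx]) < 1e-6
                q_eff[near, ax] = pts[idx][near]
    interp = _interp_3d if method == "linear" else _cubic_seq
    u = interp(table.sho_angles, table.elb_angles, table.stiffness_nm,
               table.stims, q_eff, S)
    u = np.clip(u, 0.0, 1.0)
    if scalar:
        return u[0], bool(extrap[0])
    return u, extrap


def downsample_and_interpolate(dense_calib: CalibrationData,
                               resolution_deg: float,
                               stiffness_nm=None,
                               arm: ArmModel | None = None,
                               adjustments=None) -> LookupTable:
    """Build a table from a down-sampled subset of a dense calibration.

    Mirrors the clinical shortcut: calibrate sparsely, interpolate the
    stimulation values everywhere. The returned table is built on the sparse
    grid (and, if ``arm`` is given, verified and finalised on it); callers
    evaluate it at dense postures through :func:`query`.
    """
    calib = (dense_calib if resolution_deg == dense_calib.grid.shoulder[2]
             else dense_calib.subsample(resolution_deg))
    table = build_initial_table(calib, stiffness_nm, adjustments)
    if arm is not None:
        achieved, ok, _ = verify_table(table, arm)
        table = finalize_table(table, achieved, ok)
    return table


def workspace_feasibility(arm: ArmModel, grid_step_deg: float = 5.0,
                          stiffness_nm=(3.0, 8.0, 13.0)) -> float:
    """Fraction of (posture, stiffness) nodes with an all-interior solution.

    The default arm is designed so that for stiffness anywhere in 3-13 Nm
    virtually every workspace posture admits a solution with every scale
    factor strictly inside (0, 1).
    """
    from .calibration import SamplingGrid, calibrate
    grid = SamplingGrid((15.0, 85.0, grid_step_deg),
                        (20.0, 130.0, grid_step_deg), tuple(stiffness_nm))
    calib = calibrate(arm, grid)
    total, interior = 0, 0
    for q in grid.configs():
        for S in stiffness_nm:
            sv = solve_bounded_min_norm(build_system(q, S, calib))
            total += 1
            interior += all(s == "interior" for s in sv.status) \
                and np.all(sv.c > 0.0) and np.all(sv.c < 1.0)
    return interior / total
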