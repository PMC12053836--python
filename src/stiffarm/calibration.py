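"""Simulated exoskeleton-held calibration of the controller.

This module plays the clinical data-collection session: with the arm held
stationary at every node of a configuration grid, record (a) the passive
torques the harness must supply, (b) per-electrode stimulation sweeps giving
stimulation-to-active-torque curves, and (c) each electrode's maximum active
torque per joint. The resulting :class:`CalibrationData` is everything the
torque solver and lookup-table builder need; with measurement noise off it
is an exact, reproducible function of the plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arm_model import ArmModel, JointConfig

__all__ = [
    "SamplingGrid", "StimTorqueCurve", "CalibrationData",
    "grid_points", "grid_count", "measure_passive", "measure_recruitment",
    "calibrate",
]


def grid_points(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive-start floor convention: lo, lo+step, ... largest <= hi."""
    if step <= 0:
        raise ValueError("step must be positive")
    if hi < lo:
        raise ValueError("hi must be >= lo")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class SamplingGrid:
    """Workspace sampling: per-axis (lo, hi, step) plus stiffness levels."""

    shoulder: tuple[float, float, float] = (15.0, 85.0, 5.0)
    elbow: tuple[float, float, float] = (20.0, 130.0, 5.0)
    stiffness_nm: tuple[float, ...] = tuple(float(s) for s in range(3, 14))

    def shoulder_points(self) -> np.ndarray:
        return grid_points(*self.shoulder)

    def elbow_points(self) -> np.ndarray:
        return grid_points(*self.elbow)

    def configs(self) -> np.ndarray:
        """All (shoulder, elbow) pairs, shape (Ns*Ne, 2), shoulder-major."""
        s = self.shoulder_points()
        e = self.elbow_points()
        return np.stack(np.meshgrid(s, e, indexing="ij"), axis=-1).reshape(-1, 2)


def grid_count(grid: SamplingGrid) -> int:
    """Number of angular sample configurations (stiffness counted apart)."""
    return grid.shoulder_points().size * grid.elbow_points().size


@dataclass
class StimTorqueCurve:
    """One electrode's measured sweep at one posture (active-only torques)."""

    electrode_id: str
    config: JointConfig
    u: np.ndarray              # (k,) normalised stimulation levels
    torque_nm: np.ndarray      # (k, 2) signed per-joint active torque
    max_torque_nm: np.ndarray  # (2,) signed, at the largest magnitude seen
    warnings: list[str] = field(default_factory=list)

    @property
    def reference_joint(self) -> int:
        return int(np.argmax(np.abs(self.max_torque_nm)))


def _bilinear(sho: np.ndarray, elb: np.ndarray, values: np.ndarray,
              q: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of values (Ns, Ne, ...) at queries q (N, 2).

    Queries outside the grid use linear extrapolation from the edge cell
    (the caller decides whether that is acceptable).
    """
    q = np.asarray(q, dtype=float)
    out_axes = values.shape[2:]
    v = values.reshape(sho.size, elb.size, -1)

    def _locate(axis_pts, x):
        if axis_pts.size == 1:
            return np.zeros(x.shape, dtype=int), np.zeros_like(x)
        i = np.clip(np.searchsorted(axis_pts, x, side="right") - 1,
                    0, axis_pts.size - 2)
        w = (x - axis_pts[i]) / (axis_pts[i + 1] - axis_pts[i])
        return i, w

    i, wi = _locate(sho, q[:, 0])
    j, wj = _locate(elb, q[:, 1])
    v00 = v[i, j]
    v10 = v[np.minimum(i + 1, sho.size - 1), j]
    v01 = v[i, np.minimum(j + 1, elb.size - 1)]
    v11 = v[np.minimum(i + 1, sho.size - 1), np.minimum(j + 1, elb.size - 1)]
    wi = wi[:, None]
    wj = wj[:, None]
    res = ((1 - wi) * (1 - wj) * v00 + wi * (1 - wj) * v10
           + (1 - wi) * wj * v01 + wi * wj * v11)
    return res.reshape((q.shape[0],) + out_axes)


@dataclass
class CalibrationData:
    """Complete calibration record on a configuration grid.

    curves has shape (n_electrodes, k, Ns, Ne, 2): per-electrode sweeps at
    every grid posture; max_torque is (Ns, Ne, n_electrodes, 2), signed.
    """

    grid: SamplingGrid
    sho_angles: np.ndarray
    elb_angles: np.ndarray
    pf: np.ndarray                     # (Ns, Ne, 2)
    pe: np.ndarray                     # (Ns, Ne, 2)
    curve_u: np.ndarray                # (k,)
    curves: np.ndarray                 # (n_elec, k, Ns, Ne, 2)
    max_torque: np.ndarray             # (Ns, Ne, n_elec, 2)
    electrode_ids: tuple[str, ...]
    spillover: np.ndarray              # (n_elec,) bool, multi-muscle channel
    arm_scenario: str = "default"
    attribution: str = "component"
    noise_sd: float = 0.0
    seed: int | None = None

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    # -------------------------------------------------- interpolated access
    def passive_at(self, q: np.ndarray):
        """(pf, pe) each (N, 2) at query postures q (N, 2)."""
        return (_bilinear(self.sho_angles, self.elb_angles, self.pf, q),
                _bilinear(self.sho_angles, self.elb_angles, self.pe, q))

    def max_torque_at(self, q: np.ndarray) -> np.ndarray:
        """(N, n_elec, 2) signed max active torques at query postures."""
        return _bilinear(self.sho_angles, self.elb_angles, self.max_torque, q)

    def curves_at(self, q: np.ndarray) -> np.ndarray:
        """(N, n_elec, k, 2) sweep samples interpolated to query postures."""
        v = getattr(self, "_curves_moved", None)
        if v is None:
            v = np.ascontiguousarray(
                np.moveaxis(self.curves, (0, 1), (2, 3)))
            object.__setattr__(self, "_curves_moved", v)
        return _bilinear(self.sho_angles, self.elb_angles, v, q)

    def reference_curve_sets(self, n_rep: int = 1):
        """Batched curve interpolants over every grid posture.

        Returns (fwd, inv): per-electrode lists where ``fwd[e]`` evaluates
        signed per-joint torques (columns (Ncfg*n_rep, 2)) and ``inv[e]``
        inverts the torque magnitude on the electrode's reference joint
        (columns (Ncfg*n_rep,)). ``n_rep`` tiles each posture's curve, which
        lets callers query several stiffness levels per posture in one shot.
        """
        from ._curves import MonotoneCurveSet
        m = self.n_electrodes
        ncfg = self.sho_angles.size * self.elb_angles.size
        ref = self.reference_joints().reshape(ncfg, m)
        fwd, inv = [], []
        for e in range(m):
            y = self.curves[e].reshape(-1, ncfg, 2)           # (k, Ncfg, 2)
            if n_rep > 1:
                y = np.repeat(y, n_rep, axis=1)
            fwd.append(MonotoneCurveSet(self.curve_u, y))
            mag = np.abs(np.take_along_axis(
                self.curves[e].reshape(-1, ncfg, 2),
                ref[None, :, e, None], axis=2))[:, :, 0]      # (k, Ncfg)
            if n_rep > 1:
                mag = np.repeat(mag, n_rep, axis=1)
            inv.append(MonotoneCurveSet(self.curve_u, mag))
        return fwd, inv

    def reference_joints(self) -> np.ndarray:
        """(Ns, Ne, n_elec) index of each electrode's larger-torque joint."""
        return np.argmax(np.abs(self.max_torque), axis=-1)

    def subsample(self, step_deg: float) -> "CalibrationData":
        """Down-sampled copy on a coarser grid (step must be a multiple)."""
        def _sel(angles, lo, step0):
            f = step_deg / step0
            if abs(f - round(f)) > 1e-9:
                raise ValueError("target resolution must be a multiple of "
                                 "the calibrated step")
            return np.arange(0, angles.size, int(round(f)))

        si = _sel(self.sho_angles, *self.grid.shoulder[::2])
        ei = _sel(self.elb_angles, *self.grid.elbow[::2])
        g = SamplingGrid(
            (self.grid.shoulder[0], self.grid.shoulder[1], step_deg),
            (self.grid.elbow[0], self.grid.elbow[1], step_deg),
            self.grid.stiffness_nm)
        return CalibrationData(
            g, self.sho_angles[si], self.elb_angles[ei],
            self.pf[np.ix_(si, ei)], self.pe[np.ix_(si, ei)],
            self.curve_u, self.curves[:, :, si][:, :, :, ei],
            self.max_torque[np.ix_(si, ei)], self.electrode_ids,
            self.spillover, self.arm_scenario, self.attribution,
            self.noise_sd, self.seed)


def measure_passive(arm: ArmModel, grid: SamplingGrid,
                    attribution: str = "component", noise_sd: float = 0.0,
                    seed: int | None = None):
    """Passive flexion/extension torque tables over the grid.

    attribution 'component' records the plant's two one-sided components
    separately (what a harness able to perturb in both directions can
    identify); 'net' records only the net hold torque and attributes a
    positive net to the flexion side and a negative net to the extension
    side, as a single-measurement clinical protocol would.
    """
    sho = grid.shoulder_points()
    elb = grid.elbow_points()
    q = grid.configs()
    pf_flat, pe_flat, _, _ = arm._passive(q)
    pf = pf_flat.reshape(sho.size, elb.size, 2)
    pe = pe_flat.reshape(sho.size, elb.size, 2)
    if attribution == "net":
        net = pf + pe
        pf = np.maximum(net, 0.0)
        pe = np.minimum(net, 0.0)
    elif attribution != "component":
        raise ValueError("attribution must be 'component' or 'net'")
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        pf = pf + rng.normal(0.0, noise_sd, pf.shape)
        pe = pe + rng.normal(0.0, noise_sd, pe.shape)
    return pf, pe


def measure_recruitment(arm: ArmModel, config: JointConfig, electrode_id: str,
                        sweep_steps: int = 101,
                        plateau_eps: float = 0.01) -> StimTorqueCurve:
    """Sweep one electrode at one posture and record the active-torque curve.

    The sweep rises over an even grid u = 0..1 and is truncated at the first
    level where every joint's torque has changed by less than plateau_eps
    over the last three steps (the "torque stopped changing" stopping rule),
    or at u = 1.
    """
    if sweep_steps < 21:
        raise ValueError("sweep_steps must be >= 21")
    e_idx = list(arm.electrode_ids).index(electrode_id)
    u = np.linspace(0.0, 1.0, sweep_steps)
    tq = arm.electrode_sweep(e_idx, config.as_array()[None], u)[:, 0, :]
    d = np.abs(np.diff(tq, axis=0))
    stop = sweep_steps - 1
    started = False
    for i in range(3, sweep_steps):
        # "stops changing" means after recruitment has begun: the flat
        # stretch below the activation threshold does not count
        started = started or np.any(d[i - 3:i] >= plateau_eps)
        if started and np.all(d[i - 3:i] < plateau_eps):
            stop = i
            break
    u, tq = u[:stop + 1], tq[:stop + 1]
    amax = np.argmax(np.abs(tq), axis=0)
    max_t = tq[amax, np.arange(2)]
    warnings = []
    ref = int(np.argmax(np.abs(max_t)))
    mag = np.abs(tq[:, ref])
    if np.any(np.diff(mag) < -1e-9):
        warnings.append(f"non-monotone torque on reference joint {ref}")
    return StimTorqueCurve(electrode_id, config, u, tq, max_t, warnings)


def calibrate(arm: ArmModel, grid: SamplingGrid, sweep_steps: int = 101,
              attribution: str = "component", noise_sd: float = 0.0,
              seed: int | None = None) -> CalibrationData:
    """Full calibration: passive tables plus per-electrode sweeps everywhere.

    Batch counterpart of :func:`measure_passive` / :func:`measure_recruitment`
    (sweeps are stored untruncated on the shared u grid; the recorded maxima
    use the same largest-magnitude rule).
    """
    sho = grid.shoulder_points()
    elb = grid.elbow_points()
    q = grid.configs()
    pf, pe = measure_passive(arm, grid, attribution, noise_sd, seed)
    u = np.linspace(0.0, 1.0, sweep_steps)
    m = arm.n_electrodes
    curves = np.empty((m, sweep_steps, sho.size, elb.size, 2))
    rng = np.random.default_rng(None if seed is None else seed + 1)
    for e in range(m):
        tq = arm.electrode_sweep(e, q, u)                    # (k, Ncfg, 2)
        if noise_sd > 0.0:
            tq = tq + rng.normal(0.0, noise_sd, tq.shape)
            tq[0] = 0.0  # the zero-stimulation baseline defines "active"
        curves[e] = tq.reshape(sweep_steps, sho.size, elb.size, 2)
    amax = np.argmax(np.abs(curves), axis=1)                 # (m, Ns, Ne, 2)
    max_t = np.take_along_axis(curves, amax[:, None], axis=1)[:, 0]
    max_torque = np.moveaxis(max_t, 0, 2)                    # (Ns, Ne, m, 2)
    spill = np.array([e.is_spillover for e in arm.electrodes])
    return CalibrationData(grid, sho, elb, pf, pe, u, curves, max_torque,
                           arm.electrode_ids, spill, arm.scenario,
                           attribution, noise_sd, seed)
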