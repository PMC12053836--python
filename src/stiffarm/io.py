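"""Run configuration and CSV/JSON artifact serialisation.

Artifacts are deliberately plain: long-format CSV for tables (diff-able,
language-neutral) with a JSON sidecar for nested metadata, and a manifest
listing every written file with its SHA-256 checksum so that a noise-free
run is verifiably reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationData, SamplingGrid
from .lookup_table import LookupTable

__all__ = ["RunConfig", "save_calibration", "load_calibration",
           "save_table", "load_table", "write_manifest"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run from a text file."""

    arm_scenario: str = "default"
    shoulder: tuple[float, float, float] = (15.0, 85.0, 5.0)
    elbow: tuple[float, float, float] = (20.0, 130.0, 5.0)
    stiffness_nm: tuple[float, ...] = tuple(float(s) for s in range(3, 14))
    sweep_steps: int = 101
    attribution: str = "component"
    noise_sd: float = 0.0
    seed: int | None = None
    spillover_tol: float = 1e-3
    spillover_max_iter: int = 1000
    resolutions_deg: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0)
    fatigue_timestep_s: float = 5.0
    fatigue_scenarios: tuple[int, ...] = tuple(range(1, 12))
    reach_radius_cm: float = 14.0
    reach_targets: int = 8
    reach_feedback: bool = True
    out_dir: str = "stiffarm_out"

    def __post_init__(self):
        for name in ("shoulder", "elbow"):
            lo, hi, step = getattr(self, name)
            if step <= 0:
                raise ValueError(f"{name}: step must be positive")
            if hi < lo:
                raise ValueError(f"{name}: hi must be >= lo")
        if any(s <= 0 for s in self.stiffness_nm):
            raise ValueError("stiffness_nm: all levels must be positive")
        if self.sweep_steps < 21:
            raise ValueError("sweep_steps must be >= 21")

    def grid(self) -> SamplingGrid:
        return SamplingGrid(tuple(self.shoulder), tuple(self.elbow),
                            tuple(self.stiffness_nm))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("shoulder", "elbow", "stiffness_nm", "resolutions_deg",
                    "fatigue_scenarios"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ------------------------------------------------------------- calibration
def save_calibration(calib: CalibrationData, out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sho, elb = calib.sho_angles, calib.elb_angles
    cfg = calib.grid.configs()
    passive = pd.DataFrame({
        "shoulder_deg": cfg[:, 0], "elbow_deg": cfg[:, 1],
        "pf_shoulder_nm": calib.pf[..., 0].reshape(-1),
        "pe_shoulder_nm": calib.pe[..., 0].reshape(-1),
        "pf_elbow_nm": calib.pf[..., 1].reshape(-1),
        "pe_elbow_nm": calib.pe[..., 1].reshape(-1)})
    p1 = out / "passive_torques.csv"
    passive.to_csv(p1, index=False, float_format="%.17g")

    recs = []
    for e, eid in enumerate(calib.electrode_ids):
        flat = calib.max_torque[:, :, e, :].reshape(-1, 2)
        recs.append(pd.DataFrame({
            "shoulder_deg": cfg[:, 0], "elbow_deg": cfg[:, 1],
            "electrode": eid, "max_shoulder_nm": flat[:, 0],
            "max_elbow_nm": flat[:, 1]}))
    p2 = out / "max_torques.csv"
    pd.concat(recs, ignore_index=True).to_csv(p2, index=False, float_format="%.17g")

    p3 = out / "curves.json"
    p3.write_text(json.dumps({
        "grid": {"shoulder": list(calib.grid.shoulder),
                 "elbow": list(calib.grid.elbow),
                 "stiffness_nm": list(calib.grid.stiffness_nm)},
        "electrode_ids": list(calib.electrode_ids),
        "spillover": calib.spillover.tolist(),
        "arm_scenario": calib.arm_scenario,
        "attribution": calib.attribution,
        "noise_sd": calib.noise_sd,
        "seed": calib.seed,
        "curve_u": calib.curve_u.tolist(),
        "curves": calib.curves.tolist()}))
    return [p1, p2, p3]


def load_calibration(out_dir) -> CalibrationData:
    out = Path(out_dir)
    meta = json.loads((out / "curves.json").read_text())
    grid = SamplingGrid(tuple(meta["grid"]["shoulder"]),
                        tuple(meta["grid"]["elbow"]),
                        tuple(meta["grid"]["stiffness_nm"]))
    sho = grid.shoulder_points()
    elb = grid.elbow_points()
    passive = pd.read_csv(out / "passive_torques.csv",
                          float_precision="round_trip")
    pf = np.stack([passive["pf_shoulder_nm"], passive["pf_elbow_nm"]],
                  axis=-1).reshape(sho.size, elb.size, 2)
    pe = np.stack([passive["pe_shoulder_nm"], passive["pe_elbow_nm"]],
                  axis=-1).reshape(sho.size, elb.size, 2)
    curves = np.array(meta["curves"])
    amax = np.argmax(np.abs(curves), axis=1)
    max_t = np.take_along_axis(curves, amax[:, None], axis=1)[:, 0]
    return CalibrationData(
        grid, sho, elb, pf, pe, np.array(meta["curve_u"]), curves,
        np.moveaxis(max_t, 0, 2), tuple(meta["electrode_ids"]),
        np.array(meta["spillover"], dtype=bool), meta["arm_scenario"],
        meta["attribution"], meta["noise_sd"], meta["seed"])


# -------------------------------------------------------------- lookup table
def save_table(table: LookupTable, out_dir, stem: str = "lookup_table"):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Ns, Ne, Nk, m = table.stims.shape
    nodes = table.node_configs()[:, :, None, :]
    nodes = np.broadcast_to(nodes, (Ns, Ne, Nk, 2)).reshape(-1, 2)
    S = np.broadcast_to(table.stiffness_nm[None, None, :],
                        (Ns, Ne, Nk)).reshape(-1)
    df = pd.DataFrame({"shoulder_deg": nodes[:, 0],
                       "elbow_deg": nodes[:, 1], "stiffness_nm": S})
    for i, eid in enumerate(table.electrode_ids):
        df[f"u_{eid}"] = table.stims[..., i].reshape(-1)
    for i, eid in enumerate(table.electrode_ids):
        df[f"c_{eid}"] = table.scales[..., i].reshape(-1)
    df["feasible"] = table.feasible.reshape(-1)
    df["residual_norm_nm"] = table.residual_norm.reshape(-1)
    df["provenance"] = table.provenance.reshape(-1)
    if table.achieved is not None:
        df["achieved_shoulder_deg"] = table.achieved[..., 0].reshape(-1)
        df["achieved_elbow_deg"] = table.achieved[..., 1].reshape(-1)
        df["achieved_ok"] = table.achieved_ok.reshape(-1)
    p1 = out / f"{stem}.csv"
    df.to_csv(p1, index=False, float_format="%.17g")
    meta = {k: v for k, v in table.metadata.items()
            if not isinstance(v, np.ndarray)}
    p2 = out / f"{stem}.json"
    p2.write_text(json.dumps({
        "shoulder_deg": table.sho_angles.tolist(),
        "elbow_deg": table.elb_angles.tolist(),
        "stiffness_nm": table.stiffness_nm.tolist(),
        "electrode_ids": list(table.electrode_ids),
        "metadata": meta}))
    return [p1, p2]


def load_table(out_dir, stem: str = "lookup_table") -> LookupTable:
    out = Path(out_dir)
    meta = json.loads((out / f"{stem}.json").read_text())
    sho = np.array(meta["shoulder_deg"])
    elb = np.array(meta["elbow_deg"])
    S = np.array(meta["stiffness_nm"])
    eids = tuple(meta["electrode_ids"])
    df = pd.read_csv(out / f"{stem}.csv", float_precision="round_trip")
    shape = (sho.size, elb.size, S.size)
    stims = np.stack([df[f"u_{e}"].to_numpy().reshape(shape) for e in eids],
                     axis=-1)
    scales = np.stack([df[f"c_{e}"].to_numpy().reshape(shape) for e in eids],
                      axis=-1)
    achieved = achieved_ok = None
    if "achieved_shoulder_deg" in df:
        achieved = np.stack(
            [df["achieved_shoulder_deg"].to_numpy().reshape(shape),
             df["achieved_elbow_deg"].to_numpy().reshape(shape)], axis=-1)
        achieved_ok = df["achieved_ok"].to_numpy().reshape(shape)
    return LookupTable(sho, elb, S, stims, scales,
                       df["feasible"].to_numpy().reshape(shape),
                       df["residual_norm_nm"].to_numpy().reshape(shape),
                       df["provenance"].to_numpy().reshape(shape),
                       eids, meta["metadata"], achieved, achieved_ok)


def write_manifest(out_dir, paths) -> Path:
    out = Path(out_dir)
    entries = []
    for p in paths:
        p = Path(p)
        entries.append({"file": str(p.relative_to(out)),
                        "bytes": p.stat().st_size,
                        "sha256": hashlib.sha256(p.read_bytes()).hexdigest()})
    mp = out / "manifest.json"
    mp.write_text(json.dumps({"files": entries}, indent=1))
    return mp
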