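"""Pipeline orchestration: synth -> simulate -> decompose -> report, and
synth -> unfold -> stats, under a single YAML configuration.

Every stage's outputs are listed in a JSON run manifest with SHA-256
checksums; all randomness flows from one root seed expanded per stage, so
re-running from the same configuration reproduces every checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .wall_kinematics import TubeGeometry, two_chamber_preset, load_config as load_motion
from .heart_simulator import (SimulationConfig, run as run_simulation,
                              save_records, concentration_profile)
from .shear_decomposition import DecompositionResult, spatial_profiles, gradient_tau1
from .synthetic_data import PhantomSpec, SignalSpec, write_phantom, write_signal
from .avc_unfold import fit_centerline, unfold, measure_L, shortening, read_stack
from .group_stats import compare_groups, summarize

__all__ = ["run_pipeline", "report_directions", "RunManifest"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    root_seed: int
    stage_seeds: dict
    version: str
    outputs: dict                  # path -> sha256
    stages_run: list
    failed_stage: Optional[str]
    started: float
    finished: float

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(root_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def report_directions(result: DecompositionResult, geometry: TubeGeometry,
                      mean_flux: float, side: str = "upper") -> dict:
    """Directional summary of the shear-stress pattern around the AVC.

    Emits, for one wall side, the signs of the time-average stress tau0 on
    the atrial and ventricular flanks of the AVC, the signs of the tau1
    spatial gradient on each flank, the sign of the mean flux, and three
    derived flags: whether tau0 points away from the AVC on both flanks,
    whether the tau1 gradient points toward the AVC center from both
    flanks, and whether the mean flow is unidirectional atrium->ventricle.
    """
    mask = result.side_mask(side)
    x = result.station_x[mask]
    sm = geometry.smoothing
    za = (x > geometry.avc[0] - sm) & (x < geometry.avc[0])
    zv = (x > geometry.avc[1]) & (x < geometry.avc[1] + sm)
    if not za.any() or not zv.any():
        raise ValueError("stations do not cover the AVC flanks")
    tau0 = result.tau0[mask]
    t0a, t0v = float(tau0[za].mean()), float(tau0[zv].mean())
    xg, grad = gradient_tau1(result, side)
    ga = float(np.interp(geometry.avc[0] - sm / 2, xg, grad))
    gv = float(np.interp(geometry.avc[1] + sm / 2, xg, grad))

    def sgn(v):
        return 0 if v == 0 else (1 if v > 0 else -1)

    return {
        "side": side,
        "tau0_sign_atrial_flank": sgn(t0a),
        "tau0_sign_ventricular_flank": sgn(t0v),
        "grad_tau1_sign_atrial_flank": sgn(ga),
        "grad_tau1_sign_ventricular_flank": sgn(gv),
        "mean_flux_sign": sgn(mean_flux),
        "tau0_points_away_from_avc": bool(t0a < 0 < t0v),
        "grad_tau1_points_toward_avc": bool(ga > 0 > gv),
        "mean_flow_unidirectional": bool(mean_flux > 0),
    }


def run_pipeline(config: dict | str | Path, outdir=None) -> RunManifest:
    """Execute the configured stages in dependency order.

    ``config`` is a dict or a path to a YAML file with a ``stages`` list
    and per-stage blocks.  On stage failure, partial outputs are retained
    and the manifest records the failed stage.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    started = time.time()
    outdir = Path(outdir or config.get("outdir", "valvemorph_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = int(config.get("seed", 0))
    stages = list(config.get("stages", []))
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()

    outputs: dict = {}
    stage_seeds: dict = {}
    failed = None
    ran = []
    state: dict = {}

    def add_output(path):
        outputs[str(path)] = _sha256(path)

    for stage in stages:
        seed = _stage_seed(root_seed, stage)
        stage_seeds[stage] = seed
        block = config.get(stage, {}) or {}
        try:
            if stage == "synth_phantom":
                spec = PhantomSpec(**{**block, "seed": seed})
                state["phantom_spec"] = spec
                res = write_phantom(outdir / "phantom", spec)
                for p in res["tiffs"] + [res["truth_csv"]]:
                    add_output(p)
                state["phantom"] = res
            elif stage == "synth_signal":
                spec = SignalSpec(**{**block, "seed": seed})
                path = outdir / "signal.csv"
                write_signal(path, spec)
                add_output(path)
                state["signal_csv"] = path
            elif stage == "simulate":
                sim = SimulationConfig(**{**block, "seed": seed})
                wss, traj, flux = run_simulation(sim)
                h5 = outdir / "simulation.h5"
                save_records(h5, wss, traj, flux, sim)
                add_output(h5)
                tau_csv = outdir / "tau_series.csv"
                pd.DataFrame(wss.tau, index=wss.times).to_csv(tau_csv)
                add_output(tau_csv)
                state.update(wss=wss, traj=traj, flux=flux, sim=sim)
            elif stage == "decompose":
                if "wss" not in state:
                    raise RuntimeError("dependency error: stage 'simulate' "
                                       "must run before 'decompose'")
                dec = spatial_profiles(state["wss"], block.get("harmonics", 3),
                                       block.get("bins", 64))
                csv = outdir / "decomposition.csv"
                dec.to_frame().to_csv(csv, index=False)
                add_output(csv)
                state["decomposition"] = dec
            elif stage == "report":
                if "decomposition" not in state:
                    raise RuntimeError("dependency error: stage 'decompose' "
                                       "must run before 'report'")
                mean_flux = float(state["flux"].flux[:, 1].mean())
                rep = {s: report_directions(state["decomposition"],
                                            state["sim"].geometry, mean_flux, s)
                       for s in ("upper", "lower")}
                path = outdir / "directions.json"
                with open(path, "w") as fh:
                    json.dump(rep, fh, indent=2)
                add_output(path)
            elif stage == "unfold":
                if "phantom" not in state and "t1" not in block:
                    raise RuntimeError("dependency error: stage 'synth_phantom' "
                                       "or explicit stack paths required")
                if "phantom" in state:
                    t1_path, t2_path = state["phantom"]["tiffs"]
                    spacing = state["phantom_spec"].voxel_spacing
                    seeds_pts = np.asarray(state["phantom_spec"].control_points)
                else:
                    t1_path, t2_path = block["t1"], block["t2"]
                    spacing = block["spacing"]
                    seeds_pts = np.asarray(block["seeds"])
                Ls = {}
                for name, path in (("t1", t1_path), ("t2", t2_path)):
                    stack = read_stack(path)
                    cl = fit_centerline(stack, seeds_pts, spacing)
                    unf = unfold(stack, cl, spacing)
                    Ls[name] = measure_L(unf)
                res = shortening(Ls["t1"], Ls["t2"],
                                 block.get("quadrant_offset", 0.0))
                csv = outdir / "shortening.csv"
                res.to_frame().to_csv(csv, index=False)
                add_output(csv)
                state["shortening"] = res
            elif stage == "stats":
                table = pd.read_csv(block["table"]) if "table" in block else \
                    state.get("group_table")
                if table is None:
                    raise RuntimeError("dependency error: stats needs a group table")
                groups = block.get("groups")
                if not groups or len(groups) != 2:
                    raise ValueError("stats stage needs exactly two group labels")
                out = compare_groups(table, groups[0], groups[1],
                                     welch=block.get("welch", False))
                csv = outdir / "stats.csv"
                out.to_csv(csv, index=False)
                add_output(csv)
                summ = outdir / "summary.csv"
                summarize(table).to_csv(summ, index=False)
                add_output(summ)
            else:
                raise ValueError(f"unknown stage {stage!r}")
            ran.append(stage)
        except Exception:
            failed = stage
            log.exception("stage %s failed; partial outputs retained", stage)
            break

    manifest = RunManifest(
        config_hash=cfg_hash, root_seed=root_seed, stage_seeds=stage_seeds,
        version=__version__, outputs=outputs, stages_run=ran,
        failed_stage=failed, started=started, finished=time.time(),
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
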