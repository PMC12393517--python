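"""Composable end-to-end workflows with config echo and JSON reports.

Three workflows mirror the analysis routes: ``traj`` (trajectory or synthetic
ensemble -> poloidal circular statistics), ``afm`` (height image or synthetic
scene -> blob table, scan counts, relative affinity), and ``series`` (two
positional series -> fixed-period fits, peak lag, phase shift in degrees).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import afm as afm_mod
from . import io as io_mod
from . import phase_fit as pf
from . import synthetic as syn
from .errors import ConfigError, MinicircError
from .poloidal import circular_stats, trajectory_angles, trajectory_displacements

_TOP_KEYS = {"workflow", "seed", "output_dir", "series", "afm", "traj"}
_SERIES_KEYS = {"period", "inputs", "synthetic"}
_AFM_KEYS = {"inputs", "synthetic", "threshold_nm", "area_range_nm2",
             "intensity_range_nm", "flatten_order", "connectivity"}
_TRAJ_KEYS = {"input", "atom_map", "synthetic", "ref_bp", "strand",
              "equilibration_fraction"}


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys in {where}: {sorted(unknown)}")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_workflow(config: dict) -> dict:
    """Execute the configured workflow and return (and optionally write) a
    JSON-serializable report; the failing stage is named on error."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    _reject_unknown(config, _TOP_KEYS, "top level")
    workflow = config.get("workflow")
    if workflow not in ("series", "afm", "traj"):
        raise ConfigError(f"workflow must be one of series/afm/traj, got {workflow!r}")
    seed = int(config.get("seed", 0))

    report: dict = {
        "workflow": workflow,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "status": "ok",
    }
    stage = "setup"
    try:
        if workflow == "series":
            stage = "series"
            report["result"] = _run_series(config.get("series", {}), seed)
        elif workflow == "afm":
            stage = "afm"
            report["result"] = _run_afm(config.get("afm", {}), seed)
        else:
            stage = "traj"
            report["result"] = _run_traj(config.get("traj", {}), seed)
    except ConfigError:
        raise  # invalid configs are caller errors, not stage failures
    except (MinicircError, OSError) as exc:
        report["status"] = "error"
        report["failed_stage"] = stage
        report["error"] = str(exc)

    outdir = config.get("output_dir")
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
        (outdir / "config.json").write_text(json.dumps(config, indent=1, default=str))
    return report


# ---------------------------------------------------------------------------

def _run_series(block: dict, seed: int) -> dict:
    _reject_unknown(block, _SERIES_KEYS, "series")
    period = float(block.get("period", pf.DEFAULT_PERIOD_BP))

    series_list = []
    names = []
    for path in block.get("inputs", []) or []:
        series_list.append(pf.read_series_csv(path))
        names.append(Path(path).stem)
    for k, spec in enumerate(block.get("synthetic", []) or []):
        series_list.append(syn.simulate_delta_series(
            peak_bp=float(spec["peak"]),
            amplitude_nm=float(spec.get("amplitude", 0.4)),
            offset_nm=float(spec.get("offset", 1.6)),
            noise_sd_nm=float(spec.get("noise_sd", 0.0)),
            positions_bp=spec.get("positions", (0, 2, 4, 6, 8, 10, 12)),
            n_per_pos=int(spec.get("n_per_pos", 30)),
            seed=seed + k,
            period_bp=period,
            center=spec.get("center", "median"),
        ))
        names.append(spec.get("name", f"synthetic_{k}"))
    if not series_list:
        return {"n_series": 0, "fits": []}

    fits = [pf.fit_sinusoid(s, period) for s in series_list]
    result: dict = {
        "n_series": len(fits),
        "fits": [{"name": n, **pf.fit_to_dict(f)} for n, f in zip(names, fits)],
    }
    if len(fits) >= 2:
        lag = pf.peak_lag(fits[0], fits[1])
        result["lag_bp"] = lag
        result["phase_deg"] = pf.lag_to_degrees(lag, period)
    return result


def _run_afm(block: dict, seed: int) -> dict:
    _reject_unknown(block, _AFM_KEYS, "afm")
    threshold = float(block.get("threshold_nm", 0.5))
    area_range = tuple(block.get("area_range_nm2", (30.0, 400.0)))
    intensity_range = tuple(block.get("intensity_range_nm", (1.2, 100.0)))
    flatten_order = block.get("flatten_order", 2)
    connectivity = int(block.get("connectivity", 2))

    images = []
    for spec in block.get("inputs", []) or []:
        images.append(afm_mod.read_afm_image(spec["path"],
                                             float(spec["pixel_size_nm"])))
    if block.get("synthetic"):
        spec = dict(block["synthetic"])
        spec.setdefault("seed", seed)
        images.append(syn.simulate_afm_scene(syn.SyntheticSceneConfig(**spec))[0])
    if not images:
        return {"n_images": 0, "particles": 0}

    per_image = []
    totals = {"dna": 0, "protein": 0, "complex": 0}
    deltas = []
    for img in images:
        blobs, counts, table = afm_mod.analyze_image(
            img, threshold, area_range, intensity_range,
            flatten_order=flatten_order, connectivity=connectivity)
        totals["dna"] += counts.n_dna
        totals["protein"] += counts.n_protein
        totals["complex"] += counts.n_complex
        deltas.extend(b.delta_nm for b in blobs if b.label == "complex")
        per_image.append({
            "n_dna": counts.n_dna, "n_protein": counts.n_protein,
            "n_complex": counts.n_complex, "n_blobs": len(blobs),
        })

    result: dict = {
        "n_images": len(images),
        "per_image": per_image,
        "counts": {"n_dna": totals["dna"], "n_protein": totals["protein"],
                   "n_complex": totals["complex"]},
        "particles": sum(p["n_blobs"] for p in per_image),
    }
    if deltas:
        result["delta_median_nm"] = float(np.median(deltas))
        result["delta_sd_nm"] = float(np.std(deltas, ddof=1)) if len(deltas) > 1 else 0.0
    if totals["dna"] > 0 and totals["protein"] > 0:
        counts_all = afm_mod.ScanCounts(totals["dna"], totals["protein"],
                                        totals["complex"])
        result["alpha"] = afm_mod.relative_affinity(counts_all).alpha
    return result


def _run_traj(block: dict, seed: int) -> dict:
    _reject_unknown(block, _TRAJ_KEYS, "traj")
    ref_bp = int(block.get("ref_bp", 0))
    strand = int(block.get("strand", 1))
    eq = block.get("equilibration_fraction")

    if block.get("input"):
        traj = io_mod.read_dump_trajectory(block["input"], block.get("atom_map"))
    elif block.get("synthetic"):
        spec = dict(block["synthetic"])
        spec.setdefault("seed", seed)
        traj = syn.simulate_poloidal_trajectory(syn.SyntheticTrajectoryConfig(**spec))
    else:
        raise ConfigError("traj workflow needs 'input' or 'synthetic'")

    angles = trajectory_angles(traj, ref_bp, strand, eq)
    stats = circular_stats(angles)
    disp = trajectory_displacements(traj, ref_bp, strand, eq)
    return {
        "n_frames": len(traj),
        "frames_used": len(angles),
        "mean_deg": stats.mean_deg,
        "std_deg": stats.std_deg,
        "resultant_length": stats.resultant_length,
        "x_mean_nm": disp.mean_nm,
        "x_sd_nm": disp.sd_nm,
    }
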