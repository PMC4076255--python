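"""Orchestration: run every enabled analysis over one trajectory window.

Stages run in dependency order (load -> leaflets -> analyses); each stage
logs one line with its frame count and timing, and any stage error aborts
the run naming the stage.  Outputs are CSV files plus ``summary.json`` --
the machine-readable analogue of a results table: area per lipid, lamellar
d-spacing, mean gauche fractions, tilt peaks, protruding fractions and the
correlation-time table.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .config import RunConfig
from .conformation import (
    classify_protruding,
    compute_chain_vectors,
    compute_gauche_profile,
    compute_tilt_distribution,
)
from .dynamics import correlation_time_profile
from .leaflets import assign_leaflets
from .model import AnalysisWindow
from .packing import (
    compute_area_per_lipid,
    compute_local_density_profile,
    extract_d_spacing,
    rdf_by_carbon,
)

__all__ = ["run_pipeline", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

log = logging.getLogger("lamtraj")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - re-raised with context
                raise StageError(name, err) from err
            log.info("stage %-10s done in %.2f s", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; write CSVs + summary.json; return summary."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.random.seed(cfg.seed % 2**31)

    traj = _stage("load")(lio.load_trajectory)(cfg.trajectory, cfg.format)
    role_map = _stage("role_map")(lio.load_role_map)(cfg.role_map)
    if role_map.n_atoms != traj.n_atoms:
        raise StageError(
            "role_map",
            ValueError(
                f"role map covers {role_map.n_atoms} atoms, trajectory has"
                f" {traj.n_atoms}"
            ),
        )
    if cfg.window.begin is not None or cfg.window.end is not None:
        window = AnalysisWindow(
            cfg.window.begin or 0,
            cfg.window.end or traj.n_frames,
            blocks=cfg.window.blocks,
        )
    else:
        window = AnalysisWindow.from_fraction(
            traj.n_frames, cfg.window.discard_fraction, blocks=cfg.window.blocks
        )
    window.check(traj.n_frames)
    log.info(
        "analysis window [%d, %d) of %d frames, %d blocks",
        window.first,
        window.last,
        traj.n_frames,
        window.blocks,
    )

    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "n_frames": traj.n_frames,
        "window": {
            "first": window.first,
            "last": window.last,
            "blocks": window.blocks,
        },
    }

    leaflets = _stage("leaflets")(assign_leaflets)(
        traj, role_map, frame=window.first, n_leaflets=cfg.n_leaflets
    )
    summary["leaflets"] = {
        "counts": {str(k): v for k, v in leaflets.counts.items()},
        "normals": leaflets.normals.tolist() if leaflets.normals is not None else None,
    }

    if cfg.area.enabled:
        npl = cfg.area.lipids_per_leaflet or max(leaflets.counts.values())
        area = _stage("area")(compute_area_per_lipid)(traj, npl, window)
        pd.DataFrame({"time_ps": area.times, "area_A2": area.area}).to_csv(
            out_dir / "area.csv", index=False
        )
        summary["area_per_lipid_A2"] = {"mean": area.mean, "se": area.se}

    if cfg.ldp.enabled:
        profile = _stage("ldp")(compute_local_density_profile)(
            traj, role_map, window, cfg.ldp.bin_width
        )
        rows = []
        for comp, blocks_arr in profile.block_profiles.items():
            for b in range(blocks_arr.shape[0]):
                for z, rho in zip(profile.z_centers, blocks_arr[b]):
                    rows.append(
                        {"component": comp, "block": b, "z_A": z, "density": rho}
                    )
        pd.DataFrame(rows).to_csv(out_dir / "ldp.csv", index=False)
        try:
            d = extract_d_spacing(profile)
            summary["d_spacing_A"] = d
        except ValueError as err:
            summary["d_spacing_A"] = None
            log.warning("d-spacing not extracted: %s", err)

    if cfg.rdf.enabled:
        rdf_rows = []
        summary["rdf_first_peak_A"] = {}
        for carbon in cfg.rdf.carbons:
            res = _stage(f"rdf[{carbon}]")(rdf_by_carbon)(
                traj,
                role_map,
                carbon,
                window,
                bin_width=cfg.rdf.bin_width,
                r_max=cfg.rdf.r_max,
                blocks=cfg.rdf.blocks,
                mode=cfg.rdf.mode,
            )
            for r, gval, sd in zip(res.r_centers, res.g, res.block_sd):
                rdf_rows.append(
                    {"carbon": carbon, "r_A": r, "g": gval, "block_sd": sd}
                )
            summary["rdf_first_peak_A"][carbon] = res.first_peak()
        pd.DataFrame(rdf_rows).to_csv(out_dir / "rdf.csv", index=False)

    if cfg.gauche.enabled:
        frames = []
        summary["gauche"] = {}
        for chain in cfg.gauche.chains:
            prof = _stage(f"gauche[{chain}]")(compute_gauche_profile)(
                traj, role_map, leaflets, window, chain
            )
            frames.append(prof.to_frame())
            summary["gauche"][chain] = {
                "chain_average": prof.chain_average(),
                "per_leaflet": {
                    str(leaf): prof.chain_average(leaf) for leaf in prof.leaflets
                },
            }
        pd.concat(frames).to_csv(out_dir / "gauche.csv", index=False)

    if cfg.tilt.enabled:
        tilt_frames = []
        peaks: dict = {}
        protrusion_rows = []
        summary["tilt_peaks_deg"] = {}
        summary["protruding_fraction"] = {}
        for chain in cfg.tilt.chains:
            vectors = _stage(f"tilt[{chain}]")(compute_chain_vectors)(
                traj, role_map, chain, window
            )
            dist = compute_tilt_distribution(vectors, leaflets, cfg.tilt.bin_width)
            df = dist.to_frame()
            df.insert(0, "chain", chain)
            tilt_frames.append(df)
            peaks[chain] = {str(k): v for k, v in dist.peaks.items()}
            frac = classify_protruding(
                vectors, leaflets, cfg.tilt.protrusion_lo, cfg.tilt.protrusion_hi
            )
            for leaf, f in frac.items():
                protrusion_rows.append(
                    {"chain": chain, "leaflet": leaf, "protruding_fraction": f}
                )
            summary["tilt_peaks_deg"][chain] = peaks[chain]
            summary["protruding_fraction"][chain] = {
                str(k): v for k, v in frac.items()
            }
        pd.concat(tilt_frames).to_csv(out_dir / "tilt.csv", index=False)
        (out_dir / "peaks.json").write_text(json.dumps(peaks, indent=1))
        pd.DataFrame(protrusion_rows).to_csv(out_dir / "protrusion.csv", index=False)

    if cfg.acf.enabled:
        tau = _stage("acf")(correlation_time_profile)(
            traj,
            role_map,
            window,
            max_lag=cfg.acf.max_lag,
            include_rings=cfg.acf.include_rings,
            chain=cfg.acf.chain,
        )
        tau.to_csv(out_dir / "tau.csv", index=False)
        summary["tau_ns"] = {
            row["label"]: {
                "tau_ns": row["tau_ns"],
                "sigma_tau_ns": row["sigma_tau_ns"],
                "flagged": bool(row["flagged"]),
            }
            for _, row in tau.iterrows()
        }

    _validate_summary(summary)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _validate_summary(summary: dict) -> None:
    """Minimal schema check before the summary is written."""
    if summary.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("summary schema version mismatch")
    for key in ("seed", "n_frames", "window", "leaflets"):
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
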