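"""End-to-end run orchestration: simulate → NNA → hotspot → assign → report.

A single YAML/JSON config drives the whole pipeline; every stage logs what
it does, all outputs land in one directory, and a machine-readable
manifest records inputs, parameters, seed and package versions so a run
can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import platform
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accessibility, hotspot, io, point_pattern, synthetic
from .types import StudyArea, ValidationError

__all__ = ["run_pipeline", "load_config"]

log = logging.getLogger("geoaccess")


def load_config(source) -> dict:
    """Load a config mapping from a dict, a YAML/JSON file path, or a string."""
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {source} did not parse to a mapping")
    return cfg


def _pkg_version(name: str) -> str:
    try:
        return version(name)
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(config, out_dir=None, seed: int | None = None) -> dict:
    """Run every configured stage and return the manifest.

    Config keys (all optional except one of ``simulate`` / ``inputs``):

    - ``seed``: base seed (overridden by the ``seed`` argument)
    - ``area_m2``: study area in m²; defaults to the simulated region's
      area, and is required when inputs are read from files
    - ``simulate``: SyntheticConfig fields for synthetic inputs
    - ``inputs``: {facilities: path, enrollees: path} for field data
    - ``nna``: {alpha}; ``hotspot``: {cell_size, band};
      ``assign``: {accredited_only}
    - ``out_dir``: output directory (overridden by the argument)

    Precedence: function arguments > config values > defaults.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    cfg.setdefault("seed", 0)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "geoaccess_out"))
    out.mkdir(parents=True, exist_ok=True)

    stage = "configure"
    try:
        if "simulate" in cfg:
            stage = "simulate"
            sim_cfg = dict(cfg["simulate"])
            sim_cfg.setdefault("seed", cfg["seed"])
            scfg = synthetic.SyntheticConfig.from_dict(sim_cfg)
            log.info("simulate: %d facilities (%s), %d enrollees, seed %d",
                     scfg.n_facilities, scfg.pattern, scfg.n_enrollees, scfg.seed)
            facilities, enrollees = synthetic.simulate(scfg)
            area = StudyArea(area=scfg.area.area, polygon=scfg.area.polygon)
        elif "inputs" in cfg:
            stage = "read inputs"
            paths = cfg["inputs"]
            facilities = io.read_facilities(paths["facilities"])
            enrollees = io.read_enrollees(paths["enrollees"])
            if "area_m2" not in cfg:
                raise ValidationError("area_m2 is required when reading field inputs")
            area = StudyArea.square(float(cfg["area_m2"]))
        else:
            raise ValidationError(
                "config needs either a 'simulate' block or an 'inputs' block"
            )
        if "area_m2" in cfg:
            area = StudyArea.square(float(cfg["area_m2"]))

        stage = "write inputs"
        io.write_facilities(facilities, out / "facilities.csv")
        io.write_enrollees(enrollees, out / "enrollees.csv")
        io.write_geojson(facilities, out / "facilities.geojson", kind="facility")

        stage = "nna"
        alpha = float(cfg.get("nna", {}).get("alpha", 0.05))
        nna = point_pattern.clark_evans(facilities, area.area, alpha=alpha)
        log.info("nna: Rn=%.4f z=%.3f pattern=%s", nna.rn, nna.z_score, nna.pattern)
        (out / "nna.json").write_text(json.dumps(nna.to_dict(), indent=2))

        stage = "hotspot"
        hs_cfg = cfg.get("hotspot", {})
        cells, gi_params = hotspot.hotspot_analysis(
            facilities,
            area,
            cell_size=hs_cfg.get("cell_size"),
            band=hs_cfg.get("band"),
        )
        log.info(
            "hotspot: %d cells, cell_size=%.1f m, band=%.1f m, %d significant",
            len(cells), gi_params.cell_size, gi_params.band, int((cells["bin"] != 0).sum()),
        )
        cells.to_csv(out / "hotspot_cells.csv", index=False)
        cell_feats = [
            {
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [float(r["center_x"]), float(r["center_y"])]},
                "properties": {
                    "cell_id": int(r["cell_id"]),
                    "count": int(r["count"]),
                    "gi_z": float(r["gi_z"]),
                    "p_raw": float(r["p_raw"]),
                    "p_adj": float(r["p_adj"]),
                    "bin": int(r["bin"]),
                },
            }
            for _, r in cells.iterrows()
        ]
        io.write_geojson(cell_feats, out / "hotspot_cells.geojson")

        stage = "assign"
        accredited_only = bool(cfg.get("assign", {}).get("accredited_only", True))
        assignments = accessibility.assign_nearest(
            enrollees, facilities, accredited_only=accredited_only
        )
        assignments.to_csv(out / "assignments.csv", index=False)
        for which in ("nearest", "used"):
            feats = accessibility.hub_lines(assignments, enrollees, facilities, which=which)
            io.write_geojson(feats, out / f"hub_lines_{which}.geojson")

        stage = "report"
        bypass = accessibility.bypass_table(assignments)
        bypass.to_csv(out / "bypass_table.csv", index=False)
        distances = accessibility.distance_summary(assignments)
        distances.to_csv(out / "distance_summary.csv", index=False)
        total = bypass.iloc[-1]
        log.info("report: overall bypass rate %.1f%% of %d enrollees",
                 total["pct_bypassed"], total["n_patrons"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": _jsonable_cfg(cfg),
        "seed": int(cfg["seed"]),
        "area_m2": float(area.area),
        "n_facilities": int(len(facilities)),
        "n_enrollees": int(len(enrollees)),
        "gi_params": {
            "cell_size_m": gi_params.cell_size,
            "band_m": gi_params.band,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "versions": {
            "python": platform.python_version(),
            "geoaccess": _pkg_version("geoaccess"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable_cfg(cfg: dict) -> dict:
    def conv(v):
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    return conv(cfg)
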