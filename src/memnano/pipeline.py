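"""Configurable multi-stage pipeline runner with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, spatial, synthgen
from .core import Region
from .io import read_points_csv, write_json, write_points_csv

logger = logging.getLogger("memnano")

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "region_nm",
    "n_points",
    "n_sheets",
    "n_clusters",
    "points_per_cluster",
    "cluster_sd_nm",
    "r_max_nm",
    "r_step_nm",
    "n_sims",
    "percentile",
    "points_csv",
}

STAGES = ("simulate", "kfunction", "envelope", "lmax")


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "memnano_out"
    region_nm: tuple[float, float] = (1000.0, 1000.0)
    n_points: int = 300
    n_sheets: int = 1
    n_clusters: int = 0
    points_per_cluster: tuple[int, int] = (4, 6)
    cluster_sd_nm: float = 20.0
    r_max_nm: float = 240.0
    r_step_nm: float = 1.0
    n_sims: int = 1000
    percentile: float = 99.0
    points_csv: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        for tup_field in ("region_nm", "points_per_cluster"):
            val = getattr(cfg, tup_field)
            setattr(cfg, tup_field, tuple(val))
        return cfg

    @property
    def region(self) -> Region:
        return Region(*self.region_nm)

    def radius_grid(self) -> spatial.RadiusGrid:
        return spatial.default_radius_grid(self.r_max_nm, self.r_step_nm)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, stages: list[str]) -> dict:
    """Execute the named stages in order, persisting intermediates.

    A manifest JSON records the config, seed, package version, and input
    checksums. A stage failure halts with the stage name; outputs of prior
    stages remain on disk.
    """
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"invalid stage(s) {bad}; valid stages: {list(STAGES)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {"patterns": None, "k": None, "l": None, "envelope": None}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "config": {k: getattr(config, k) for k in sorted(_KNOWN_KEYS)},
        "inputs": {},
    }
    results: dict = {}
    for stage in stages:
        try:
            if stage == "simulate":
                _stage_simulate(config, out, state)
            elif stage == "kfunction":
                _stage_kfunction(config, out, state)
            elif stage == "envelope":
                _stage_envelope(config, state)
            elif stage == "lmax":
                results["sheets"] = _stage_lmax(config, out, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    if config.points_csv:
        manifest["inputs"][config.points_csv] = _sha256(Path(config.points_csv))
    write_json(manifest, out / "manifest.json")
    results["manifest"] = str(out / "manifest.json")
    return results


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    patterns = []
    for s in range(config.n_sheets):
        if config.n_clusters > 0:
            model = synthgen.ClusterModel(
                n_clusters=config.n_clusters,
                points_per_cluster=config.points_per_cluster,
                cluster_sd=config.cluster_sd_nm,
                region=config.region,
            )
            pat, _ = synthgen.gen_cluster_pattern(
                model, seed=config.seed + s, sheet_id=f"sheet{s}"
            )
        else:
            pat = synthgen.gen_csr_pattern(
                config.n_points, config.region, seed=config.seed + s,
                sheet_id=f"sheet{s}",
            )
        patterns.append(pat)
    state["patterns"] = patterns
    write_points_csv(patterns, out / "points.csv")


def _load_patterns(config: RunConfig, state: dict) -> list:
    if state["patterns"] is None:
        if not config.points_csv:
            raise ValueError("no simulated patterns and no points_csv configured")
        state["patterns"] = read_points_csv(config.points_csv, config.region)
    return state["patterns"]


def _stage_envelope(config: RunConfig, state: dict) -> None:
    """One envelope per distinct observed n (or the configured n_points)."""
    if state["patterns"] is not None or config.points_csv:
        ns = sorted({p.n for p in _load_patterns(config, state)})
    else:
        ns = [config.n_points]
    state["envelope"] = {
        n: spatial.csr_envelope(
            n=n,
            region=config.region,
            radii=config.radius_grid(),
            n_sims=config.n_sims,
            percentile=config.percentile,
            seed=config.seed + 1,
        )
        for n in ns
    }


def _stage_kfunction(config: RunConfig, out: Path, state: dict) -> None:
    grid = config.radius_grid()
    curves = {}
    for pat in _load_patterns(config, state):
        curves[pat.sheet_id] = spatial.l_curve(spatial.ripley_k(pat, grid))
    state["l"] = curves


def _stage_lmax(config: RunConfig, out: Path, state: dict) -> list[dict]:
    if state["l"] is None:
        _stage_kfunction(config, out, state)
    if state["envelope"] is None:
        raise ValueError("lmax requires the envelope stage to have run")
    envs = state["envelope"]
    rows = []
    frames = []
    for pat in _load_patterns(config, state):
        lcur = state["l"][pat.sheet_id]
        norm = spatial.normalize_and_lmax(lcur, envs[pat.n])
        rows.append(
            {
                "sheet_id": pat.sheet_id,
                "n": pat.n,
                "density_um2": pat.n / (pat.region.area / 1e6),
                "l_max": norm.l_max,
                "r_at_max_nm": norm.r_at_max,
            }
        )
        frames.append(
            pd.DataFrame(
                {
                    "sheet_id": pat.sheet_id,
                    "r_nm": lcur.radii.radii,
                    "l_minus_r_nm": lcur.l_minus_r,
                    "normalized": np.interp(
                        lcur.radii.radii, norm.radii, norm.values, left=np.nan,
                        right=np.nan,
                    ),
                }
            )
        )
    pd.concat(frames).to_csv(out / "curves.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    return rows
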