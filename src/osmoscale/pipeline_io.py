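"""Table I/O with schema validation, run configuration, and the stage runner.

All interchange is plain text: CSV for tables, JSON for configurations and
manifests.  Schemas are declared per table kind; readers are tolerant of
column order and case and of extra columns, strict about missing or
unparsable ones.  ``run_pipeline`` chains generator and analysis stages
from a single seeded configuration and records a manifest (inputs, hashes,
per-stage summaries) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "TableSchema",
    "SCHEMAS",
    "read_table",
    "write_table",
    "RunConfig",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict[str, type]  # required column -> dtype

    def validate(self, df: pd.DataFrame, path: str = "<table>") -> pd.DataFrame:
        rename = {c: c.strip().lower() for c in df.columns}
        df = df.rename(columns=rename)
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        extra = [c for c in df.columns if c not in self.columns]
        if extra:
            logger.warning("%s: ignoring unknown column(s) %s", path, extra)
        errors = []
        for col, dtype in self.columns.items():
            if dtype in (float, int):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[coerced.isna() & df[col].notna()]
                for i in bad:
                    errors.append(f"{path}: row {i + 2}: cannot parse {col}={df.at[i, col]!r}")
                df[col] = coerced
            else:
                df[col] = df[col].astype(str)
        if errors:
            raise SchemaError("; ".join(errors[:20]))
        return df


SCHEMAS = {
    "shifts": TableSchema(
        "shifts",
        {
            "cell_id": str,
            "compartment": str,
            "group": str,
            "c_iso": float,
            "c_out": float,
            "conc_units": str,
            "v_iso_um3": float,
            "v_um3": float,
        },
    ),
    "tracks": TableSchema(
        "tracks",
        {"track_id": str, "frame": int, "t_s": float, "x_um": float, "y_um": float},
    ),
    "trajectories": TableSchema(
        "trajectories",
        {"cell_id": str, "t_min": float, "vc_um3": float, "vn_um3": float, "mitotic": int},
    ),
    "deff_conc": TableSchema("deff_conc", {"conc": float, "d_eff": float}),
    "deff_volume": TableSchema("deff_volume", {"volume_um3": float, "d_eff": float}),
}


def read_table(path: str | Path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate a CSV table against a declared schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    df = pd.read_csv(path)
    return schema.validate(df, str(path))


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV (no index column)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    ``stages`` run in order; each may carry a parameter block under its
    name in ``params``.  One seed fans out deterministically to every
    stage that draws random numbers.
    """

    stages: list[str]
    params: dict[str, dict] = field(default_factory=dict)
    seed: int = 0
    outdir: Path = Path("osmoscale_out")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            stages=raw.get("stages", []),
            params=raw.get("params", {}),
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "osmoscale_out")),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_synth_shifts(cfg: RunConfig, p: dict) -> dict:
    from .synthetic_data import GeneratorConfig, gen_shift_dataset

    df = gen_shift_dataset(GeneratorConfig(seed=cfg.seed), **p)
    out = write_table(df, cfg.outdir / "shifts.csv")
    return {"output": str(out), "sha256": _sha256(out), "n_records": len(df)}


def _stage_bvh_fit(cfg: RunConfig, p: dict) -> dict:
    from .bvh_analysis import fit_bvh_linear, normalize_shift_data

    shifts = read_table(p.pop("input", cfg.outdir / "shifts.csv"), "shifts")
    points = normalize_shift_data(shifts)
    rows = []
    for (grp, comp), sub in points.groupby(["group", "compartment"]):
        fit = fit_bvh_linear(sub, **p)
        rows.append(
            {
                "group": grp,
                "compartment": comp,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "se_slope": fit.stderr_slope,
                "se_intercept": fit.stderr_intercept,
                "r2": fit.r_squared,
                "lof_p": fit.lack_of_fit_p,
                "n": fit.n_points,
            }
        )
    out = write_table(pd.DataFrame(rows), cfg.outdir / "bvh_fits.csv")
    summary = {"output": str(out), "sha256": _sha256(out)}
    if rows:
        summary["intercept"] = rows[0]["intercept"]
    return summary


def _stage_synth_tracks(cfg: RunConfig, p: dict) -> dict:
    from .synthetic_data import GeneratorConfig, gen_brownian_tracks, gen_fbm_tracks

    kind = p.pop("kind", "brownian")
    gen = gen_brownian_tracks if kind == "brownian" else gen_fbm_tracks
    tracks = gen(GeneratorConfig(seed=cfg.seed), **p)
    out = write_table(tracks.data, cfg.outdir / "tracks.csv")
    return {"output": str(out), "sha256": _sha256(out), "n_tracks": tracks.n_tracks}


def _stage_gem_fit(cfg: RunConfig, p: dict) -> dict:
    from .gem_rheology import TrackSet, compute_msd, fit_alpha, fit_deff

    data = read_table(p.pop("input", cfg.outdir / "tracks.csv"), "tracks")
    tracks = TrackSet(data, dt=p.pop("dt", 0.01))
    msd = compute_msd(tracks, max_lag_frames=p.pop("max_lag_frames", 100))
    deff = fit_deff(msd, n_points=p.pop("n_points", 10))
    alpha = fit_alpha(msd)
    out = write_table(
        pd.DataFrame({"tau_s": msd.tau, "msd_um2": msd.msd, "n": msd.n_displacements}),
        cfg.outdir / "msd.csv",
    )
    return {
        "output": str(out),
        "sha256": _sha256(out),
        "d_eff": deff.D_eff,
        "alpha": alpha.alpha,
    }


def _stage_synth_population(cfg: RunConfig, p: dict) -> dict:
    from .growth_homeostasis import trajectories_to_frame
    from .synthetic_data import GeneratorConfig, gen_homeostasis_population

    trajs = gen_homeostasis_population(GeneratorConfig(seed=cfg.seed), **p)
    out = write_table(trajectories_to_frame(trajs), cfg.outdir / "trajectories.csv")
    return {"output": str(out), "sha256": _sha256(out), "n_cells": len(trajs)}


def _stage_homeostasis_fit(cfg: RunConfig, p: dict) -> dict:
    from .growth_homeostasis import fit_correction_rate, fit_growth_rate, frame_to_trajectories

    df = read_table(p.pop("input", cfg.outdir / "trajectories.csv"), "trajectories")
    trajs = frame_to_trajectories(df)
    growth = fit_growth_rate(trajs)
    homeo = fit_correction_rate(trajs)
    out_df = pd.DataFrame(
        [
            {
                "gamma_c": growth.gammaC,
                "se_gamma_c": growth.stderr,
                "gamma_nc": homeo.gammaNC,
                "se_gamma_nc": homeo.stderr_gammaNC,
                "f0_hat": homeo.f0_hat,
                "se_f0": homeo.stderr_f0,
                "n_cells": homeo.n_cells,
            }
        ]
    )
    out = write_table(out_df, cfg.outdir / "homeostasis_fit.csv")
    return {
        "output": str(out),
        "sha256": _sha256(out),
        "gamma_c": growth.gammaC,
        "gamma_nc": homeo.gammaNC,
        "f0_hat": homeo.f0_hat,
    }


_STAGES = {
    "synth-shifts": _stage_synth_shifts,
    "bvh-fit": _stage_bvh_fit,
    "synth-tracks": _stage_synth_tracks,
    "gem-fit": _stage_gem_fit,
    "synth-population": _stage_synth_population,
    "homeostasis-fit": _stage_homeostasis_fit,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run manifest.

    The manifest records the package version, seed, per-stage summaries and
    output hashes.  A stage failure aborts the run; the partial manifest is
    attached to the raised exception.
    """
    from . import __version__

    unknown = [s for s in config.stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; available: {sorted(_STAGES)}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    for stage in config.stages:
        params = dict(config.params.get(stage, {}))
        try:
            manifest["stages"][stage] = _STAGES[stage](config, params)
        except Exception as exc:
            manifest["stages"][stage] = {"error": str(exc)}
            (config.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (config.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
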