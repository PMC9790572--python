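"""Readers, writers and configuration handling.

Exchange format for curves is delimited text (comma-separated, '.'
decimal) with a ``time_s, aif, tissue`` header; ``#`` starts a comment
line.  Results are written as JSON keyed by a configuration hash so that
reruns with an identical configuration overwrite deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .curves import SampledCurve
from .kinetics import QuantConfig
from .synthetic_data import AIFParams, Realization, SimConfig

__all__ = [
    "read_curve_file",
    "write_curve_file",
    "write_realization",
    "load_run_config",
    "RunConfig",
    "config_hash",
    "write_results",
]

_CURVE_COLUMNS = ("time_s", "aif", "tissue")
_FLOAT_FMT = "%.10g"


def read_curve_file(path: str | Path) -> tuple[SampledCurve, SampledCurve]:
    """Read an AIF/tissue pair from a delimited text file.

    Expects columns ``time_s, aif, tissue``; non-uniform time vectors are
    accepted.  Raises ``ValueError`` with a row reference on non-monotone
    time stamps or missing values.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"expected header {_CURVE_COLUMNS}")
    if df[list(_CURVE_COLUMNS)].isna().any().any():
        bad = int(df[df[list(_CURVE_COLUMNS)].isna().any(axis=1)].index[0])
        raise ValueError(f"{path}: missing/NaN value at data row {bad}")
    t = df["time_s"].to_numpy(float)
    d = np.diff(t)
    if np.any(d <= 0):
        bad = int(np.nonzero(d <= 0)[0][0]) + 1
        raise ValueError(
            f"{path}: time column not strictly increasing at data row {bad} "
            f"(t={t[bad]:g} after t={t[bad - 1]:g})"
        )
    aif = SampledCurve(t, df["aif"].to_numpy(float), kind="aif")
    tissue = SampledCurve(t, df["tissue"].to_numpy(float), kind="tissue")
    return aif, tissue


def write_curve_file(
    path: str | Path, aif: SampledCurve, tissue: SampledCurve,
    header_comment: str | None = None,
) -> None:
    """Write an AIF/tissue pair as delimited text (10 significant digits)."""
    if len(aif) != len(tissue) or not np.allclose(aif.times, tissue.times):
        raise ValueError("AIF and tissue must share a time base")
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(",".join(_CURVE_COLUMNS) + "\n")
        for t, a, c in zip(aif.times, aif.values, tissue.values):
            fh.write(f"{t:.10g},{a:.10g},{c:.10g}\n")


def write_realization(out_dir: str | Path, rz: Realization) -> dict:
    """Write one realization (curve file + JSON sidecar); returns its manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"realization_{rz.realization_id:06d}"
    curve_path = out_dir / f"{stem}.csv"
    write_curve_file(curve_path, rz.aif, rz.tissue)
    sidecar = {
        "realization_id": rz.realization_id,
        "truth": {"mbf": rz.truth.mbf, "vb": rz.truth.vb,
                  "mtt": rz.truth.mtt, "density": rz.truth.density},
        "acquisition": {
            "input_hr": rz.acquisition.input_hr,
            "jitter_limit_s": rz.acquisition.jitter_limit,
            "noise_sigma": rz.acquisition.noise_sigma,
            "seed": rz.acquisition.seed,
        },
    }
    sidecar_path = out_dir / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return {"curves": curve_path.name, "sidecar": sidecar_path.name,
            **sidecar}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration for a full experiment run."""

    simulation: SimConfig
    analysis: tuple[QuantConfig, ...]
    sweep_hr_grid: tuple[float, ...] = (60.0, 120.0, 240.0, 360.0, 600.0, 900.0)
    sweep_thresholds: tuple[float, ...] = (10.0, 5.0)
    log_level: str = "INFO"


def _build(cls, data: dict, context: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}; "
                         f"allowed: {sorted(names)}")
    return cls(**data)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML/JSON run configuration.

    Sections: ``simulation`` (grid, seeds, noise, AIF parameters),
    ``analysis`` (list of quantification configurations), ``sweep``
    (hr_grid + thresholds).  Unknown keys anywhere are rejected.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known_top = {"simulation", "analysis", "sweep", "log_level"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s) {sorted(unknown)}")

    sim_raw = dict(raw.get("simulation", {}))
    for key in ("mbf_list", "hr_list"):
        if key in sim_raw:
            sim_raw[key] = tuple(float(x) for x in sim_raw[key])
    if "aif" in sim_raw:
        sim_raw["aif"] = _build(AIFParams, dict(sim_raw["aif"]), f"{path}:simulation.aif")
        if isinstance(sim_raw["aif"].rates, list):
            sim_raw["aif"] = dataclasses.replace(
                sim_raw["aif"], rates=tuple(sim_raw["aif"].rates))
    sim = _build(SimConfig, sim_raw, f"{path}:simulation")

    analysis_raw = raw.get("analysis", [{}])
    analysis = tuple(
        _build(QuantConfig, dict(entry), f"{path}:analysis[{i}]")
        for i, entry in enumerate(analysis_raw)
    )

    sweep_raw = dict(raw.get("sweep", {}))
    unknown = set(sweep_raw) - {"hr_grid", "thresholds"}
    if unknown:
        raise ValueError(f"{path}:sweep: unknown key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if "hr_grid" in sweep_raw:
        kwargs["sweep_hr_grid"] = tuple(float(x) for x in sweep_raw["hr_grid"])
    if "thresholds" in sweep_raw:
        kwargs["sweep_thresholds"] = tuple(float(x) for x in sweep_raw["thresholds"])
    return RunConfig(simulation=sim, analysis=analysis,
                     log_level=str(raw.get("log_level", "INFO")), **kwargs)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config: Any) -> str:
    """Short stable hash of a configuration object (dataclass or dict)."""
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_results(
    results: list[tuple[Any, pd.DataFrame | dict]],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Persist (config, result) pairs plus a manifest; returns the manifest.

    Each result is written under a name keyed by its configuration hash;
    rerunning with an identical configuration overwrites the same file.
    DataFrames become CSV, everything else JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for config, result in results:
        h = config_hash(config)
        if isinstance(result, pd.DataFrame):
            fname = f"result_{h}.csv"
            result.to_csv(out_dir / fname, index=False, float_format=_FLOAT_FMT)
        else:
            fname = f"result_{h}.json"
            (out_dir / fname).write_text(
                json.dumps(_jsonable(result), indent=1, sort_keys=True))
        entries.append({"file": fname, "config_hash": h,
                        "config": _jsonable(config)})
    manifest = {"seed": seed, "n_results": len(entries), "results": entries}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:12]
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
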