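"""Configuration handling, table I/O, VTK field export, run manifests.

CSV payloads are UTF-8 with a header row, '.' decimal separator and floats
at 10 significant digits, so repeated runs diff byte-identically.  3D
fields are exported as legacy ASCII VTK structured points (uniform x
spacing is guaranteed by the voxelizer).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import (FilmGeometry, GeometryError, OcclusionSpec,
                       VoxelDomain)
from .packing import PackingCurve, PackingEstimate

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_curve_csv",
    "read_curve_csv",
    "write_estimate_csv",
    "write_rejection_csv",
    "read_rejection_csv",
    "write_flux_csv",
    "read_flux_csv",
    "write_vtk_structured_points",
    "write_manifest",
    "fmt",
]

FLOAT_FMT = "%.10g"


def fmt(x: float) -> str:
    return FLOAT_FMT % x


class ConfigError(ValueError):
    pass


_GEOMETRY_KEYS = {"pore_diameter", "lattice_spacing", "coverage",
                  "film_thickness", "reservoir_depth", "n_pores_y",
                  "n_pores_z"}
_OCCLUSION_KEYS = {"mode", "cap_fraction", "disk_radius", "patch_side",
                   "occlusion_thickness", "placement_seed"}
_SOLVER_KEYS = {"voxel_size", "tolerance", "separation"}
_SWEEP_KEYS = {"mode", "fractions"}
_SYNTH_KEYS = {"true_capping", "flux_scale", "noise_sd_rel", "n_replicates",
               "rejection_midpoint_nm", "rejection_steepness",
               "rejection_noise_sd_pct"}
_CHARACTERIZE_KEYS = {"threshold_pct", "rejection_csv"}
_TOP_KEYS = {"geometry", "occlusion", "solver", "sweep", "synth",
             "characterize", "paths", "seed", "log_level"}
_PATH_KEYS = {"out_dir"}


def _check_keys(block: dict, allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in "
                          f"'{name}' block")


@dataclass(frozen=True)
class RunConfig:
    geometry: FilmGeometry
    occlusion: OcclusionSpec
    voxel_size: float = 0.25
    tolerance: float = 1e-10
    separation: str = "film"
    sweep_mode: str = "pore_cap"
    sweep_fractions: tuple[float, ...] = tuple(
        np.round(np.arange(0.0, 1.01, 0.1), 10)) + (0.64,)
    synth: dict = field(default_factory=dict)
    threshold_pct: float = 90.0
    rejection_csv: str | None = None
    out_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()


def _build_geometry(block: dict) -> FilmGeometry:
    _check_keys(block, _GEOMETRY_KEYS, "geometry")
    block = dict(block)
    coverage = block.pop("coverage", None)
    if coverage is not None:
        if "lattice_spacing" in block:
            raise ConfigError(
                "give either 'coverage' or 'lattice_spacing', not both")
        return FilmGeometry.from_coverage(coverage, **block)
    return FilmGeometry(**block)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Every block validates against its module's invariants before any
    compute; unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "top-level")

    try:
        geom = _build_geometry(raw.get("geometry", {}) or {})
        occ_block = dict(raw.get("occlusion", {}) or {})
        _check_keys(occ_block, _OCCLUSION_KEYS, "occlusion")
        occ = OcclusionSpec(**occ_block) if occ_block else OcclusionSpec.none()
    except (GeometryError, TypeError) as exc:
        raise ConfigError(f"invalid geometry/occlusion config: {exc}") from exc

    sol = dict(raw.get("solver", {}) or {})
    _check_keys(sol, _SOLVER_KEYS, "solver")
    if sol.get("separation", "film") not in ("film", "domain"):
        raise ConfigError("solver.separation must be 'film' or 'domain'")
    if not float(sol.get("tolerance", 1e-10)) > 0:
        raise ConfigError("solver.tolerance must be positive")

    sw = dict(raw.get("sweep", {}) or {})
    _check_keys(sw, _SWEEP_KEYS, "sweep")
    syn = dict(raw.get("synth", {}) or {})
    _check_keys(syn, _SYNTH_KEYS, "synth")
    ch = dict(raw.get("characterize", {}) or {})
    _check_keys(ch, _CHARACTERIZE_KEYS, "characterize")
    paths = dict(raw.get("paths", {}) or {})
    _check_keys(paths, _PATH_KEYS, "paths")

    kwargs = {}
    if "voxel_size" in sol:
        kwargs["voxel_size"] = float(sol["voxel_size"])
    if "tolerance" in sol:
        kwargs["tolerance"] = float(sol["tolerance"])
    if "separation" in sol:
        kwargs["separation"] = sol["separation"]
    if "mode" in sw:
        kwargs["sweep_mode"] = sw["mode"]
    if "fractions" in sw:
        kwargs["sweep_fractions"] = tuple(float(f) for f in sw["fractions"])
    if "threshold_pct" in ch:
        kwargs["threshold_pct"] = float(ch["threshold_pct"])
    if "rejection_csv" in ch:
        kwargs["rejection_csv"] = ch["rejection_csv"]
    if "out_dir" in paths:
        kwargs["out_dir"] = str(paths["out_dir"])
    return RunConfig(geometry=geom, occlusion=occ, synth=syn,
                     seed=int(raw.get("seed", 0)),
                     log_level=str(raw.get("log_level", "INFO")),
                     raw=raw, **kwargs)


# ---------------------------------------------------------------- tables

def _write_df(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_curve_csv(curve: PackingCurve, path: str | Path) -> None:
    df = pd.DataFrame({
        "model": curve.model,
        "definition": curve.definition.value,
        "f": curve.fractions,
        "de_ratio": curve.de_ratios,
    })
    _write_df(df, path)


def read_curve_csv(path: str | Path) -> PackingCurve:
    df = pd.read_csv(path)
    from .geometry import PackingDefinition
    return PackingCurve(model=str(df["model"].iloc[0]),
                        fractions=tuple(df["f"]),
                        de_ratios=tuple(df["de_ratio"]),
                        definition=PackingDefinition(
                            df["definition"].iloc[0]),
                        geometry_hash="", voxel_size=float("nan"))


def write_estimate_csv(est: PackingEstimate, path: str | Path) -> None:
    df = pd.DataFrame([{
        "model": est.model,
        "definition": est.estimate.definition.value,
        "estimate": est.estimate.value,
        "measured_de_ratio": est.measured_ratio,
        "lo": est.bracket[0],
        "hi": est.bracket[1],
    }])
    _write_df(df, path)


def write_rejection_csv(df: pd.DataFrame, path: str | Path) -> None:
    _write_df(df, path)


def read_rejection_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"solute", "rejection_pct"}
    if not need <= set(df.columns):
        raise ConfigError(f"rejection table must carry columns {need}")
    return df


def write_flux_csv(df: pd.DataFrame, path: str | Path) -> None:
    _write_df(df, path)


def read_flux_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"membrane_variant", "flux"}
    if not need <= set(df.columns):
        raise ConfigError(f"flux table must carry columns {need}")
    return df


# ------------------------------------------------------------- 3D export

def write_vtk_structured_points(path: str | Path, dom: VoxelDomain,
                                fields: dict[str, np.ndarray]) -> None:
    """Legacy ASCII VTK structured-points export of per-voxel scalars.

    Cell-centred data written as point data on the voxel-centre lattice;
    NaNs (solid voxels in concentration fields) are written as -1.
    """
    nx, ny, nz = dom.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "aqpflux voxel field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {fmt(dom.dx / 2)} {fmt(dom.hy / 2)} {fmt(dom.hz / 2)}",
        f"SPACING {fmt(dom.dx)} {fmt(dom.hy)} {fmt(dom.hz)}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in fields.items():
        if arr.shape != dom.shape:
            raise ValueError(f"field {name!r} has shape {arr.shape}, "
                             f"expected {dom.shape}")
        data = np.nan_to_num(arr.astype(float), nan=-1.0)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x fastest: transpose to (z, y, x) before ravel
        flat = data.transpose(2, 1, 0).ravel()
        for i in range(0, flat.size, 9):
            lines.append(" ".join(fmt(v) for v in flat[i:i + 9]))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path: str | Path, config: RunConfig,
                   extra: dict | None = None) -> None:
    try:
        pkg_version = version("aqpflux")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "package": "aqpflux",
        "version": pkg_version,
        "numpy": np.__version__,
        "config_sha256": config.content_hash(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True)
                          + "\n")
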