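"""Configuration, file dialects and end-to-end pipeline runs.

User-facing units follow the reporting conventions of the measurement:
geometry in mm, displacements and thicknesses in um, moduli in kPa and
forces in nN.  Displacement fields travel as CSV with columns
``x_mm, y_mm, ux_um, uy_um[, sd_ux_um, sd_uy_um]`` (NaN marks invalid
sites); meshes as TSV triplets; configurations as YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .fields import DisplacementGrid, Lattice, default_lattice
from .forward import (
    DEFAULT_MODULI_PA,
    GeometryError,
    MaterialParams,
    Mesh,
    PlaneStressOperator,
    PointLoad,
    RegionGeometry,
    build_default_geometry,
    generate_mesh,
    midline_load,
    pellucida_load,
)
from .inference import LoadCase, FitResult, fit_moduli, normalize_and_average
from .piv import PivConfig
from .synthetic import NoiseSpec, synth_measurement_set

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "load_config",
    "save_config",
    "read_field",
    "write_field",
    "write_mesh",
    "read_mesh",
    "fit_result_to_dict",
    "run_pipeline",
]

log = logging.getLogger("embryoelast")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated pipeline configuration with full defaults.

    Blocks (all optional in the file): ``geometry`` (semi-axes mm,
    thicknesses um, n_regions), ``materials`` (moduli kPa, nu), ``piv``,
    ``noise``, ``fit`` (init/bounds kPa), ``loads`` (positions mm, forces
    nN), ``paths`` and a top-level ``seed``.
    """

    geometry: dict = field(default_factory=dict)
    materials: dict = field(default_factory=dict)
    piv: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    loads: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    seed: int = 0

    _GEOMETRY_KEYS = {
        "n_regions", "midline_semi_axes", "intermediate_semi_axes",
        "pellucida_semi_axes", "outer_radius", "thicknesses",
        "intermediate_offset",
    }
    _MATERIAL_KEYS = {"youngs_moduli_kpa", "poisson_ratio"}
    _PIV_KEYS = {"window_size", "overlap", "subpixel_method", "min_contrast",
                 "outlier_filter", "median_threshold_px", "pixel_scale_um"}
    _NOISE_KEYS = {"per_measurement_snr", "ensemble_relative_variance",
                   "replicates_per_load", "n_embryos"}
    _FIT_KEYS = {"init_kpa", "bounds_kpa", "tol", "max_iter", "target_nodes"}
    _LOAD_KEYS = {"midline_force_nN", "pellucida_force_nN",
                  "midline_position", "pellucida_position"}

    def __post_init__(self):
        for block, allowed in (
            (self.geometry, self._GEOMETRY_KEYS),
            (self.materials, self._MATERIAL_KEYS),
            (self.piv, self._PIV_KEYS),
            (self.noise, self._NOISE_KEYS),
            (self.fit, self._FIT_KEYS),
            (self.loads, self._LOAD_KEYS),
        ):
            unknown = set(block) - allowed
            if unknown:
                raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        # fail early on invalid geometry
        self.region_geometry()

    # -- converters ----------------------------------------------------

    def region_geometry(self) -> RegionGeometry:
        g = dict(self.geometry)
        n = int(g.pop("n_regions", 4))
        return build_default_geometry(n, g)

    def material_params(self) -> MaterialParams:
        moduli_kpa = self.materials.get("youngs_moduli_kpa")
        geom = self.region_geometry()
        if moduli_kpa is None:
            moduli = {r: DEFAULT_MODULI_PA[r] for r in geom.region_names}
        else:
            moduli = {r: float(moduli_kpa[r]) * 1e3 for r in moduli_kpa}
        nu = float(self.materials.get("poisson_ratio", 0.3))
        return MaterialParams(youngs_moduli=moduli, poisson_ratio=nu)

    def piv_config(self) -> PivConfig:
        kw = {k: v for k, v in self.piv.items() if k != "pixel_scale_um"}
        return PivConfig(**kw)

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(seed=self.seed, **self.noise)

    def load_cases(self) -> List[PointLoad]:
        l = self.loads
        out = [
            midline_load(
                float(l.get("midline_force_nN", 190.0)),
                tuple(l.get("midline_position", (0.0, 0.0))),
            ),
            pellucida_load(
                float(l.get("pellucida_force_nN", 200.0)),
                tuple(l.get("pellucida_position", (0.665, 0.0))),
            ),
        ]
        return out

    def fit_kwargs(self) -> dict:
        f = self.fit
        kw = {}
        if "init_kpa" in f:
            kw["init"] = {r: float(v) * 1e3 for r, v in f["init_kpa"].items()}
        if "bounds_kpa" in f:
            lo, hi = f["bounds_kpa"]
            kw["bounds"] = (float(lo) * 1e3, float(hi) * 1e3)
        if "tol" in f:
            kw["tol"] = float(f["tol"])
        if "max_iter" in f:
            kw["max_iter"] = int(f["max_iter"])
        return kw

    @property
    def target_nodes(self) -> int:
        return int(self.fit.get("target_nodes", 3000))

    # -- (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Read a YAML or JSON configuration file; empty files give defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"could not parse {path}: {err}") from err
    try:
        return PipelineConfig.from_dict(data or {})
    except GeometryError as err:
        raise ConfigError(str(err)) from err


def save_config(config: PipelineConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# displacement-field CSV dialect
# ---------------------------------------------------------------------------

_FIELD_COLS = ["x_mm", "y_mm", "ux_um", "uy_um"]
_SD_COLS = ["sd_ux_um", "sd_uy_um"]


def write_field(path: Union[str, Path], grid: DisplacementGrid) -> None:
    """Write a displacement lattice as CSV (row-major, NaN at invalid sites)."""
    pts = grid.points()
    u = np.where(grid.valid[..., None], grid.u, np.nan).reshape(-1, 2)
    data = {
        "x_mm": pts[:, 0],
        "y_mm": pts[:, 1],
        "ux_um": u[:, 0],
        "uy_um": u[:, 1],
    }
    if grid.sd is not None:
        sd = grid.sd.reshape(-1, 2)
        data["sd_ux_um"] = sd[:, 0]
        data["sd_uy_um"] = sd[:, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_field(path: Union[str, Path], frame: str = "model") -> DisplacementGrid:
    """Read a displacement lattice CSV written by :func:`write_field`."""
    df = pd.read_csv(path)
    missing = [c for c in _FIELD_COLS if c not in df.columns]
    if missing:
        raise ConfigError(f"field file {path} lacks required columns: {missing}")
    x = np.unique(df["x_mm"].to_numpy())
    y = np.unique(df["y_mm"].to_numpy())
    ny, nx = len(y), len(x)
    if ny * nx != len(df):
        raise ConfigError(f"field file {path} is not a complete rectilinear lattice")
    order = np.lexsort((df["x_mm"].to_numpy(), df["y_mm"].to_numpy()))
    u = df[["ux_um", "uy_um"]].to_numpy()[order].reshape(ny, nx, 2)
    sd = None
    if all(c in df.columns for c in _SD_COLS):
        sd = df[_SD_COLS].to_numpy()[order].reshape(ny, nx, 2)
    valid = np.all(np.isfinite(u), axis=-1)
    return DisplacementGrid(x=x, y=y, u=u, sd=sd, valid=valid, frame=frame)


# ---------------------------------------------------------------------------
# mesh TSV triplet
# ---------------------------------------------------------------------------

def write_mesh(prefix: Union[str, Path], mesh: Mesh) -> List[Path]:
    """Write ``<prefix>.nodes.tsv``, ``.triangles.tsv`` and ``.regions.tsv``."""
    prefix = Path(prefix)
    bset = set(mesh.boundary_nodes.tolist())
    nodes = pd.DataFrame({
        "x_mm": mesh.nodes[:, 0],
        "y_mm": mesh.nodes[:, 1],
        "boundary": [int(i in bset) for i in range(mesh.n_nodes)],
    })
    tris = pd.DataFrame(mesh.triangles, columns=["n0", "n1", "n2"])
    regions = pd.DataFrame({"region": mesh.element_region})
    paths = [
        Path(f"{prefix}.nodes.tsv"),
        Path(f"{prefix}.triangles.tsv"),
        Path(f"{prefix}.regions.tsv"),
    ]
    nodes.to_csv(paths[0], sep="\t", index=False)
    tris.to_csv(paths[1], sep="\t", index=False)
    regions.to_csv(paths[2], sep="\t", index=False)
    return paths


def read_mesh(prefix: Union[str, Path]) -> Mesh:
    prefix = Path(prefix)
    nodes = pd.read_csv(f"{prefix}.nodes.tsv", sep="\t")
    tris = pd.read_csv(f"{prefix}.triangles.tsv", sep="\t")
    regions = pd.read_csv(f"{prefix}.regions.tsv", sep="\t")
    return Mesh(
        nodes=nodes[["x_mm", "y_mm"]].to_numpy(),
        triangles=tris.to_numpy(),
        element_region=regions["region"].to_numpy(dtype=object),
        boundary_nodes=np.flatnonzero(nodes["boundary"].to_numpy()),
    )


# ---------------------------------------------------------------------------
# fit serialisation and pipeline
# ---------------------------------------------------------------------------

def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "youngs_moduli_kpa": {r: v / 1e3 for r, v in fit.youngs_moduli.items()},
        "uncertainties_kpa": {r: v / 1e3 for r, v in fit.uncertainties.items()},
        "error_trace_um2": [float(e) for e in fit.error_trace],
        "n_iterations": fit.n_iterations,
        "converged": fit.converged,
        "residual_rms_um": fit.residual_rms_um,
        "n_sites": fit.n_sites,
        "meta": {k: v for k, v in fit.meta.items() if isinstance(
            v, (int, float, str, bool, list, tuple))},
    }


def _manifest(config: PipelineConfig, mode: str, outputs: Sequence[Path]) -> dict:
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    out = {
        "version": _version,
        "mode": mode,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {},
    }
    for p in outputs:
        p = Path(p)
        if p.exists():
            out["outputs"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def run_pipeline(
    config: PipelineConfig,
    mode: str,
    out_dir: Union[str, Path],
    image_pairs: Optional[Sequence] = None,
) -> dict:
    """Run an end-to-end pass and write its artifacts plus a manifest.

    Modes: ``simulate+fit`` (generate synthetic ensembles, average, fit),
    ``piv+fit`` (run PIV on supplied image pairs, fit), ``forward-only``
    (solve and export the forward fields).  Returns a summary dict; all
    artifacts (fields CSV, fit JSON, manifest JSON) land in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = config.region_geometry()
    mats = config.material_params()
    loads = config.load_cases()
    outputs: List[Path] = []
    summary: dict = {"mode": mode}

    if mode == "forward-only":
        for load in loads:
            mesh = generate_mesh(geom, config.target_nodes, [load.position])
            op = PlaneStressOperator(mesh, geom, mats.poisson_ratio, load,
                                     lattice=default_lattice(center=load.position))
            grid = op.solve_grid(mats.youngs_moduli)
            p = out_dir / f"forward_{load.label}.csv"
            write_field(p, grid)
            outputs.append(p)
            log.info("forward %s: rms %.3f um", load.label, grid.rms())
        summary["fields"] = [str(p) for p in outputs]
    elif mode == "simulate+fit":
        exp = synth_measurement_set(
            mats, geom, loads, config.noise_spec(), config.target_nodes
        )
        cases = []
        for c in exp.cases:
            for i, rep in enumerate(c.replicates):
                p = out_dir / f"replicate_{c.load.label}_{i:02d}.csv"
                write_field(p, rep)
                outputs.append(p)
            ens = normalize_and_average(c.replicates, c.forces_n)
            cases.append(LoadCase(load=c.load, measured=ens, mesh=c.mesh))
        fit = _logged_fit(cases, geom, mats, config)
        p = out_dir / "fit.json"
        p.write_text(json.dumps(fit_result_to_dict(fit), indent=2))
        outputs.append(p)
        truth_path = out_dir / "truth.json"
        truth_path.write_text(json.dumps({
            "youngs_moduli_kpa": {r: v / 1e3 for r, v in mats.youngs_moduli.items()},
            "poisson_ratio": mats.poisson_ratio,
            "seed": config.seed,
        }, indent=2))
        outputs.append(truth_path)
        summary["fit"] = fit_result_to_dict(fit)
    elif mode == "piv+fit":
        from .piv import compute_piv_field

        if not image_pairs or len(image_pairs) != len(loads):
            raise ConfigError("piv+fit requires one image pair per load case")
        cases = []
        for load, pair in zip(loads, image_pairs):
            grid = compute_piv_field(pair, config.piv_config())
            grid = grid.to_model_frame(center=load.position)
            p = out_dir / f"piv_{load.label}.csv"
            write_field(p, grid)
            outputs.append(p)
            mesh = generate_mesh(geom, config.target_nodes, [load.position])
            cases.append(LoadCase(load=load, measured=grid, mesh=mesh))
        fit = _logged_fit(cases, geom, mats, config)
        p = out_dir / "fit.json"
        p.write_text(json.dumps(fit_result_to_dict(fit), indent=2))
        outputs.append(p)
        summary["fit"] = fit_result_to_dict(fit)
    else:
        raise ConfigError(
            f"unknown mode {mode!r}; expected simulate+fit | piv+fit | forward-only"
        )

    manifest = _manifest(config, mode, outputs)
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    summary["manifest"] = manifest
    return summary


def _logged_fit(cases, geom, mats, config: PipelineConfig) -> FitResult:
    fit = fit_moduli(cases, geom, nu=mats.poisson_ratio, **config.fit_kwargs())
    for i, e in enumerate(fit.error_trace):
        log.info("fit iteration %d: error %.4g um^2", i, e)
    log.info(
        "fit %s after %d iterations; moduli (kPa): %s; rms %.3f um/site",
        "converged" if fit.converged else "did not converge",
        fit.n_iterations,
        {r: round(v / 1e3, 2) for r, v in fit.youngs_moduli.items()},
        fit.residual_rms_um,
    )
    return fit
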