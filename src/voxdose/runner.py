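"""Run configuration, orchestration, and dose-output containers.

A run is fully described by a YAML configuration file::

    library: toy.h5            # cross-section container (makelib writes one)
    phantom: {preset: cube-with-tumor, scale: 0.5}   # or {file: phantom.h5}
    source:
      particles: [{type: neutron, prob: 1.0}]
      spatial: {type: disc, center: [-1, 3, 3], radius: 2.0, normal: [1, 0, 0]}
      angular: {type: monodirectional, direction: [1, 0, 0]}
      energy:
        neutron: {groups: [[1.0e-2, 1.0, 0.01], [1.0, 1.0e5, 0.98], [1.0e5, 2.0e7, 0.01]]}
    histories: 10000
    seed: 1
    tally_mode: fragment       # or history
    optimizations: {hash_search: true, xs_cache: true}
    workers: 1

The output container holds /dose/<component>/{mean, rel_error}, the lattice,
the ROI masks and the run metadata, and round-trips losslessly.  Output is a
pure function of (config, seed): worker count and batching never change a
byte of the dose arrays.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .lattice import Phantom, VoxelLattice, make_phantom, read_phantom
from .nuclear_data import Library, read_library
from .source import SourceSpec, source_from_dict
from .tally import COMPONENTS, DoseResult
from .transport import Engine

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "run_simulation",
    "write_dose_output",
    "read_dose_output",
    "export_dose_csv",
]

log = logging.getLogger("voxdose")

DOSE_FORMAT_VERSION = "voxdose-dose-1"


class ConfigError(ValueError):
    """A structured configuration problem, reported before any history runs."""


@dataclass
class RunConfig:
    library_path: str
    phantom_preset: str | None
    phantom_scale: float
    phantom_file: str | None
    source: SourceSpec
    histories: int
    seed: int
    tally_mode: str = "fragment"
    hash_search: bool = True
    xs_cache: bool = True
    neutron_cutoff_ev: float = 1e-5
    photon_cutoff_ev: float = 1e3
    workers: int = 1
    raw: dict = field(default_factory=dict, repr=False)


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ConfigError(f"{where}: missing required key {key!r}")
    return d[key]


def load_config(path) -> RunConfig:
    """Parse and schema-validate a YAML run configuration."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}")
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(raw, where=str(path))


def config_from_dict(raw: dict, where: str = "config") -> RunConfig:
    library = _require(raw, "library", where)
    phantom = _require(raw, "phantom", where)
    if not isinstance(phantom, dict) or not ({"preset", "file"} & set(phantom)):
        raise ConfigError(f"{where}.phantom: needs 'preset' or 'file'")
    histories = int(_require(raw, "histories", where))
    if histories < 1:
        raise ConfigError(f"{where}.histories: must be >= 1, got {histories}")
    seed = int(raw.get("seed", 0))
    tally_mode = raw.get("tally_mode", "fragment")
    if tally_mode not in ("fragment", "history"):
        raise ConfigError(f"{where}.tally_mode: must be 'fragment' or 'history'")
    opts = raw.get("optimizations", {}) or {}
    cutoffs = raw.get("cutoffs", {}) or {}
    workers = int(raw.get("workers", 1))
    if workers < 1:
        raise ConfigError(f"{where}.workers: must be >= 1")
    try:
        source = source_from_dict(_require(raw, "source", where))
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"{where}.source: {exc}")
    return RunConfig(
        library_path=str(library),
        phantom_preset=phantom.get("preset"),
        phantom_scale=float(phantom.get("scale", 1.0)),
        phantom_file=phantom.get("file"),
        source=source,
        histories=histories,
        seed=seed,
        tally_mode=tally_mode,
        hash_search=bool(opts.get("hash_search", True)),
        xs_cache=bool(opts.get("xs_cache", True)),
        neutron_cutoff_ev=float(cutoffs.get("neutron", 1e-5)),
        photon_cutoff_ev=float(cutoffs.get("photon", 1e3)),
        workers=workers,
        raw=raw,
    )


def _build(config: RunConfig) -> tuple[Phantom, Library, Engine]:
    if not Path(config.library_path).exists():
        raise ConfigError(f"library file not found: {config.library_path}")
    library = read_library(config.library_path)
    if config.phantom_file:
        phantom = read_phantom(config.phantom_file)
    else:
        try:
            phantom = make_phantom(config.phantom_preset, config.phantom_scale)
        except ValueError as exc:
            raise ConfigError(str(exc))
    try:
        engine = Engine(
            phantom, library, config.source,
            tally_mode=config.tally_mode,
            use_hash=config.hash_search,
            use_cache=config.xs_cache,
            neutron_cutoff_ev=config.neutron_cutoff_ev,
            photon_cutoff_ev=config.photon_cutoff_ev,
        )
    except ValueError as exc:
        raise ConfigError(str(exc))
    return phantom, library, engine


def run_simulation(config: RunConfig, out_path) -> Path:
    """Initialize, transport all histories, finalize, write the output file."""
    phantom, library, engine = _build(config)
    log.info("run: %d histories, seed %d, phantom %s (%s voxels), tally %s",
             config.histories, config.seed, phantom.name,
             "x".join(map(str, phantom.lattice.dims)), config.tally_mode)
    t0 = time.perf_counter()
    tally = engine.run(config.histories, config.seed, workers=config.workers)
    elapsed = time.perf_counter() - t0
    result = tally.finalize() if config.histories >= 2 else _single_history_result(tally)
    log.info("run: %.2f s (%.0f histories/s); counters %s",
             elapsed, config.histories / max(elapsed, 1e-9), engine.counters)
    out_path = Path(out_path)
    write_dose_output(out_path, result, phantom,
                      meta={"seed": config.seed, "histories": config.histories,
                            "config": yaml.safe_dump(config.raw, sort_keys=True),
                            "elapsed_s": elapsed, **engine.counters})
    return out_path


def _single_history_result(tally) -> DoseResult:
    # N=1 runs (smoke tests) report the bare mean with zero error
    shape = (3, *tally.dims)
    mean = (tally.sum_t / max(tally.n_histories, 1)).reshape(shape)
    return DoseResult(mean, np.zeros(shape), tally.n_histories)


# ---------------------------------------------------------------------------
# dose output container


def write_dose_output(path, result: DoseResult, phantom: Phantom, meta: dict) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = DOSE_FORMAT_VERSION
        g = f.create_group("dose")
        for ci, comp in enumerate(COMPONENTS):
            gc = g.create_group(comp)
            gc.create_dataset("mean", data=result.mean[ci])
            gc.create_dataset("rel_error", data=result.rel_error_pct[ci])
        lat = phantom.lattice
        gl = f.create_group("lattice")
        gl.create_dataset("origin", data=np.asarray(lat.origin))
        gl.create_dataset("spacing", data=np.asarray(lat.spacing))
        gl.create_dataset("dims", data=np.asarray(lat.dims))
        gl.create_dataset("material_id", data=lat.material_id)
        gr = f.create_group("roi")
        for name, mask in phantom.rois.items():
            gr.create_dataset(name, data=mask.astype(np.uint8))
        gm = f.create_group("meta")
        for key, val in meta.items():
            gm.attrs[key] = val


@dataclass
class DoseOutput:
    result: DoseResult
    lattice: VoxelLattice
    rois: dict[str, np.ndarray]
    meta: dict


def read_dose_output(path) -> DoseOutput:
    with h5py.File(path, "r") as f:
        if f.attrs.get("version") != DOSE_FORMAT_VERSION:
            raise ValueError(f"{path}: missing or unsupported dose-output version tag")
        mean = np.stack([f["dose"][c]["mean"][()] for c in COMPONENTS])
        rel = np.stack([f["dose"][c]["rel_error"][()] for c in COMPONENTS])
        gl = f["lattice"]
        lat = VoxelLattice(origin=tuple(gl["origin"][()]),
                           spacing=tuple(gl["spacing"][()]),
                           material_id=gl["material_id"][()])
        rois = {name: f["roi"][name][()].astype(bool) for name in f.get("roi", [])}
        meta = dict(f["meta"].attrs)
        n = int(meta.get("histories", 0))
        return DoseOutput(DoseResult(mean, rel, n), lat, rois, meta)


def export_dose_csv(output: DoseOutput, path) -> int:
    """Flat CSV export: one (i, j, k, component, mean, rel_error) row per
    voxel and component.  Returns the row count."""
    nx, ny, nz = output.lattice.dims
    rows = 0
    with open(path, "w") as fh:
        fh.write("i,j,k,component,mean_mev_per_g,rel_error_pct\n")
        for ci, comp in enumerate(COMPONENTS):
            mean = output.result.mean[ci]
            rel = output.result.rel_error_pct[ci]
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        fh.write(f"{i},{j},{k},{comp},{mean[i, j, k]!r},{rel[i, j, k]!r}\n")
                        rows += 1
    return rows
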