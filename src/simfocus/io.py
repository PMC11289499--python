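"""File formats: float32 TIFF stacks, complex TIFF volumes, TF libraries,
plain key/value configs and JSON run manifests.

Raw stacks are multi-page 32-bit-float TIFFs with phase-fastest page order:
``(z0, φ0..φ4), (z1, φ0..φ4), ...`` matching the acquisition loop that
collects all phase copies of a z plane before stepping the stage.  Complex
data (transfer functions) interleave real and imaginary planes.  Every image
file carries a JSON sidecar (``<file>.json``) with calibration metadata; a
transfer-function library is a directory with a ``manifest.json`` and one
complex TIFF per (offset, order).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .errors import ConfigurationError, SimfocusError
from .forward import RawSIMStack, TFLibrary, TransferFunctionSet
from .optics import OpticalConfig, make_lattice_geometry

__all__ = [
    "read_raw_stack",
    "write_raw_stack",
    "write_complex_volume",
    "read_complex_volume",
    "write_tf_library",
    "read_tf_library",
    "read_config",
    "write_config",
    "RunManifest",
]

PAGE_ORDER = "phase-fastest"  # (z0,p0..p4),(z1,p0..p4),...


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_raw_stack(stack: RawSIMStack, path) -> Path:
    """Write a stack as float32 TIFF (phase-fastest pages) plus JSON sidecar."""
    path = Path(path)
    n_phases, nz, ny, nx = stack.values.shape
    pages = np.ascontiguousarray(
        np.swapaxes(stack.values, 0, 1).reshape(nz * n_phases, ny, nx).astype(np.float32)
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "kind": "raw_sim_stack",
        "page_order": PAGE_ORDER,
        "n_phases": int(n_phases),
        "shape_zyx": [int(nz), int(ny), int(nx)],
        "voxel_xy": stack.voxel_xy,
        "voxel_z": stack.voxel_z,
        "meta": _jsonable(stack.meta),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_raw_stack(
    path, n_phases: Optional[int] = None, assume_order: Optional[str] = None
) -> RawSIMStack:
    """Read a phase-stepped stack; ordering comes from the sidecar or a flag."""
    path = Path(path)
    pages = tifffile.imread(path)
    side = _sidecar(path)
    meta: dict = {}
    voxel_xy = voxel_z = None
    if side.exists():
        info = json.loads(side.read_text())
        n_phases = n_phases or info.get("n_phases")
        voxel_xy = info.get("voxel_xy")
        voxel_z = info.get("voxel_z")
        meta = info.get("meta", {})
        order = info.get("page_order", PAGE_ORDER)
    elif assume_order is not None:
        import warnings

        warnings.warn("no sidecar metadata; trusting --assume-order and defaults")
        order = assume_order
    else:
        raise SimfocusError(
            f"missing sidecar {side}; cannot determine page order, n_phases "
            "and voxel sizes (pass n_phases and assume_order to override)"
        )
    if n_phases is None:
        raise SimfocusError("n_phases unknown: not in sidecar and not provided")
    if order not in (PAGE_ORDER, "pzyx"):
        raise SimfocusError(f"unsupported page order {order!r}")
    if pages.ndim == 2:
        pages = pages[None]
    total = pages.shape[0]
    if total % n_phases:
        raise SimfocusError(
            f"page count {total} is not divisible by n_phases={n_phases}"
        )
    nz = total // n_phases
    values = np.swapaxes(pages.reshape(nz, n_phases, *pages.shape[1:]), 0, 1)
    return RawSIMStack(
        np.ascontiguousarray(values),
        voxel_xy if voxel_xy is not None else 0.1,
        voxel_z if voxel_z is not None else 0.1,
        meta=meta,
    )


def write_complex_volume(arr: np.ndarray, path, extra_meta: Optional[dict] = None) -> Path:
    """Complex 3D array as TIFF with interleaved real/imag float32 pages."""
    path = Path(path)
    nz = arr.shape[0]
    pages = np.empty((2 * nz,) + arr.shape[1:], dtype=np.float32)
    pages[0::2] = arr.real
    pages[1::2] = arr.imag
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {"kind": "complex_volume", "interleave": "real,imag", "shape_zyx": list(arr.shape)}
    if extra_meta:
        meta.update(_jsonable(extra_meta))
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_complex_volume(path) -> np.ndarray:
    pages = tifffile.imread(Path(path))
    if pages.shape[0] % 2:
        raise SimfocusError("complex volume must have an even page count")
    return pages[0::2].astype(np.float64) + 1j * pages[1::2].astype(np.float64)


def write_tf_library(lib: TFLibrary, directory, cfg: OpticalConfig) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, entry in enumerate(lib.entries):
        files = {}
        for m, arr in entry.otfs.items():
            name = f"tf_{i:03d}_m{m}.tif"
            write_complex_volume(arr, directory / name, {"dz_um": entry.dz_um, "order": m})
            files[str(m)] = name
        entries.append(
            {"dz_um": entry.dz_um, "dz_pi": entry.dz_pi, "files": files}
        )
    manifest = {
        "kind": "tf_library",
        "config_hash": lib.config_hash,
        "config": cfg.to_dict(),
        "entries": entries,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_tf_library(directory) -> tuple[TFLibrary, OpticalConfig]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg = OpticalConfig.from_dict(manifest["config"])
    geom = make_lattice_geometry(cfg)
    entries = []
    for e in manifest["entries"]:
        otfs = {int(m): read_complex_volume(directory / fn) for m, fn in e["files"].items()}
        entries.append(
            TransferFunctionSet(
                otfs=otfs,
                dz_um=e["dz_um"],
                dz_pi=e["dz_pi"],
                config_hash=manifest["config_hash"],
            )
        )
    return TFLibrary(entries, manifest["config_hash"], geom), cfg


# ------------------------------------------------------------------- config files

_CONFIG_KEYS = {
    "lambda_exc": float,
    "lambda_det": float,
    "n_medium": float,
    "na_det": float,
    "na_ann_max": float,
    "na_ann_min": float,
    "pattern": str,
    "nx": int,
    "ny": int,
    "nz": int,
    "voxel_xy": float,
    "voxel_z": float,
    "upsample": int,
    "pupil_line_sigma": float,
}


def read_config(path) -> OpticalConfig:
    """Parse a flat ``key = value`` text file into an :class:`OpticalConfig`."""
    values = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = _CONFIG_KEYS[key](val)
    kwargs = {k: v for k, v in values.items() if k not in ("nx", "ny", "nz")}
    if any(k in values for k in ("nx", "ny", "nz")):
        default = OpticalConfig().grid_shape
        kwargs["grid_shape"] = (
            values.get("nx", default[0]),
            values.get("ny", default[1]),
            values.get("nz", default[2]),
        )
    return OpticalConfig(**kwargs)


def write_config(cfg: OpticalConfig, path) -> Path:
    path = Path(path)
    d = cfg.to_dict()
    nx, ny, nz = d.pop("grid_shape")
    lines = [f"{k} = {v}" for k, v in sorted(d.items())]
    lines += [f"nx = {nx}", f"ny = {ny}", f"nz = {nz}"]
    path.write_text("\n".join(lines) + "\n")
    return path


# ------------------------------------------------------------------- manifests

@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    config_hash: str
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    package_version: str = ""
    timings_s: dict = field(default_factory=dict)
    started: str = ""

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(_jsonable(asdict(self)), indent=2))
        return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def now_iso() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")
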