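"""Stack I/O, configuration and waveform/table serialisation.

Stacks travel as multi-page TIFF (with a JSON metadata sidecar) or HDF5
(metadata in attributes).  Axis order is normalised project-wide to
``(t, z, y, x)`` for 4-D data and ``(z, y, x)`` for 3-D; lengths are um,
time is s, and CSV headers carry units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .scan import ScanSpec, Waveform

__all__ = [
    "StackMeta",
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_waveform_csv",
    "write_waveform_csv",
    "load_config",
]

_CANONICAL_3D = "zyx"
_CANONICAL_4D = "tzyx"
REQUIRED_KEYS = ("voxel_size_um", "axes")


@dataclass(frozen=True)
class StackMeta:
    """Voxel geometry and timing metadata of a stack."""

    voxel_size_um: tuple  # (z, y, x)
    axes: str  # canonical: 'zyx' or 'tzyx'
    frame_rate_hz: float | None = None

    def to_dict(self) -> dict:
        d = {"voxel_size_um": list(self.voxel_size_um), "axes": self.axes}
        if self.frame_rate_hz is not None:
            d["frame_rate_hz"] = self.frame_rate_hz
        return d


@dataclass
class RunConfig:
    """Validated run configuration assembled from YAML/JSON."""

    scan: ScanSpec
    seed: int = 0
    camera_bias: float = 100.0
    pixel_size_um: float = 0.65
    extras: dict = field(default_factory=dict)


def _normalise(array: np.ndarray, axes: str) -> tuple[np.ndarray, str]:
    axes = axes.lower()
    if array.ndim == 3:
        canonical = _CANONICAL_3D
    elif array.ndim == 4:
        canonical = _CANONICAL_4D
    else:
        raise ValueError("stacks must be 3-D or 4-D")
    if sorted(axes) != sorted(canonical):
        raise ValueError(f"axes {axes!r} cannot be normalised to {canonical!r}")
    order = [axes.index(a) for a in canonical]
    return np.transpose(array, order), canonical


def read_stack(path) -> tuple[np.ndarray, StackMeta]:
    """Read a TIFF (+ JSON sidecar) or HDF5 stack with its metadata.

    Raises a :class:`ValueError` naming the missing keys if metadata is
    absent; axis order is normalised to ``(t, z, y, x)``/``(z, y, x)``.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            data = f["stack"][()]
            meta_raw = dict(f["stack"].attrs)
            if "voxel_size_um" in meta_raw:
                meta_raw["voxel_size_um"] = list(np.atleast_1d(meta_raw["voxel_size_um"]))
    else:
        data = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(
                f"missing metadata sidecar {sidecar.name}; required keys: "
                f"{', '.join(REQUIRED_KEYS)}"
            )
        meta_raw = json.loads(sidecar.read_text())
    missing = [k for k in REQUIRED_KEYS if k not in meta_raw]
    if missing:
        raise ValueError(f"stack metadata missing required keys: {', '.join(missing)}")
    data, axes = _normalise(np.asarray(data), str(meta_raw["axes"]))
    meta = StackMeta(
        voxel_size_um=tuple(float(v) for v in meta_raw["voxel_size_um"]),
        axes=axes,
        frame_rate_hz=(
            float(meta_raw["frame_rate_hz"]) if meta_raw.get("frame_rate_hz") else None
        ),
    )
    return data, meta


def write_stack(
    array: np.ndarray, meta: StackMeta, path, overwrite: bool = False, compress: bool = False
) -> Path:
    """Write a stack losslessly with its metadata (TIFF sidecar or HDF5)."""
    path = Path(path)
    array = np.asarray(array)
    if array.ndim > 4:
        raise ValueError("stacks must have at most 4 dimensions")
    if array.dtype.kind not in "uif":
        raise ValueError(f"unsupported dtype {array.dtype}")
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(
                "stack", data=array, compression="gzip" if compress else None
            )
            for k, v in meta.to_dict().items():
                ds.attrs[k] = v
    else:
        tifffile.imwrite(
            path,
            array,
            photometric="minisblack",
            compression="zlib" if compress else None,
        )
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta.to_dict(), indent=1))
    return path


def write_waveform_csv(waveform: Waveform, path) -> Path:
    path = Path(path)
    waveform.to_frame().to_csv(path, index=False)
    return path


def read_waveform_csv(path, period_samples: int | None = None) -> Waveform:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    pos = df["position_um"].to_numpy()
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("waveform samples must be uniformly spaced")
    rate = 1.0 / dt[0]
    return Waveform(pos, rate, period_samples or pos.size)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "scan" not in raw:
        raise ValueError("config must be a mapping with a 'scan' section")
    scan_raw = dict(raw["scan"])
    scan = ScanSpec(
        z_min=float(scan_raw["z_min_um"]),
        z_max=float(scan_raw["z_max_um"]),
        cycle_frequency=float(scan_raw["cycle_frequency_hz"]),
        sample_rate=float(scan_raw.get("sample_rate_hz", 1e5)),
        slice_spacing=float(scan_raw["slice_spacing_um"]),
    )
    known = {"scan", "seed", "camera_bias", "pixel_size_um"}
    return RunConfig(
        scan=scan,
        seed=int(raw.get("seed", 0)),
        camera_bias=float(raw.get("camera_bias", 100.0)),
        pixel_size_um=float(raw.get("pixel_size_um", 0.65)),
        extras={k: v for k, v in raw.items() if k not in known},
    )
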