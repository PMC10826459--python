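"""Readers, writers and configuration for the pipeline.

Stacks are multi-page TIFFs (tifffile "shaped" format) with pixel size,
frame interval and channel labels stored in the embedded JSON metadata, so
a write/read round trip is lossless. Gridded fields (flow, concentration)
go into deterministic ``.npz`` containers (fixed zip timestamps, so files
are byte-reproducible from config + seed). Tables are plain CSV.

Run configuration is TOML with blocks [geometry], [medium], [bc],
[transport], [analysis], [synth], [output]; unknown keys are rejected
before any computation. Pressures are given in mbar (``*_mbar`` keys) and
converted to Pa internally; lengths are um, imaging times hours, transport
times minutes.
"""

from __future__ import annotations

import io as _io
import json
import tomllib
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import TimeLapseStack

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_config",
    "read_stack",
    "write_stack",
    "write_table",
    "save_fields",
    "load_fields",
]


class ConfigError(ValueError):
    """Raised when a run configuration violates the schema."""


_SCHEMA: dict[str, set[str]] = {
    "geometry": {
        "width_um", "span_um", "spheroid_radius_um", "spheroid_center_um",
        "grid_spacing_um", "pillar_side_um", "channel_height_um",
    },
    "medium": {
        "permeability_m2", "permeability_ratio", "viscosity_pa_s",
        "effective_viscosity_pa_s",
    },
    "bc": {"p1_mbar", "p2_mbar"},
    "transport": {
        "diffusivity_m2_s", "diffusivity_ratio", "inlet_concentration_ng_ml",
        "duration_min", "output_interval_min", "dt_s", "saturation_fraction",
    },
    "analysis": {
        "channels", "pixel_size_um", "frame_interval_h", "background",
        "intensity_mode", "n_theta", "motility_band_um", "endpoint_h",
    },
    "synth": {
        "image_size_px", "pixel_size_um", "spheroid_radius_um", "n_frames",
        "frame_interval_h", "amplitude", "tau_h", "kinetics", "asymmetry",
        "noise_gaussian", "poisson_scale", "background", "motile", "jitter_px",
        "amplitude_cv", "conditions",
    },
    "output": {"directory", "seed", "log_level"},
}


@dataclass
class RunConfig:
    """Validated run configuration; missing blocks fall back to defaults."""

    geometry: dict = field(default_factory=dict)
    medium: dict = field(default_factory=dict)
    bc: dict = field(default_factory=dict)
    transport: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    @property
    def out_dir(self) -> Path:
        return Path(self.output.get("directory", "results"))

    @property
    def seed(self) -> int:
        return int(self.output.get("seed", 0))


def read_config(path: str | Path) -> RunConfig:
    """Parse and schema-validate a TOML run configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    blocks = {}
    for name, content in raw.items():
        if name not in _SCHEMA:
            raise ConfigError(f"unknown config block [{name}]")
        if not isinstance(content, dict):
            raise ConfigError(f"[{name}] must be a table")
        for key in content:
            if key not in _SCHEMA[name]:
                raise ConfigError(f"unknown key {name}.{key}")
        blocks[name] = content
    return RunConfig(**blocks)


def write_stack(stack: TimeLapseStack, path: str | Path) -> None:
    """Write a stack as a shaped TIFF with calibration metadata."""
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=1).astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        metadata={
            "axes": "TCYX",
            "channel_names": names,
            "pixel_size_um": stack.pixel_size,
            "frame_interval_h": stack.frame_interval,
        },
    )


def read_stack(
    path: str | Path,
    channel_map: list[str] | None = None,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> TimeLapseStack:
    """Read a TIFF time-lapse; metadata fallbacks apply with a warning.

    Accepts (T, C, H, W) or single-channel (T, H, W) arrays. ``channel_map``
    overrides the stored channel labels (one label per channel axis entry).
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
    if data.ndim == 3:
        data = data[:, None]
    if data.ndim != 4:
        raise ValueError(f"expected (T, C, H, W) or (T, H, W) data, got {data.shape}")
    names = channel_map or meta.get("channel_names")
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[1])]
        warnings.warn("no channel labels stored; using generic names")
    if len(names) != data.shape[1]:
        raise ValueError(f"{len(names)} channel labels for {data.shape[1]} channels")
    px = pixel_size or meta.get("pixel_size_um")
    if px is None:
        px = 1.0
        warnings.warn("no pixel size stored; defaulting to 1 um/px")
    dt = frame_interval or meta.get("frame_interval_h")
    if dt is None:
        dt = 1.0
        warnings.warn("no frame interval stored; defaulting to 1 h")
    channels = {n: data[:, i].astype(float) for i, n in enumerate(names)}
    return TimeLapseStack(channels=channels, pixel_size=float(px), frame_interval=float(dt))


def write_table(records, path: str | Path) -> pd.DataFrame:
    """Write records (DataFrame or list of dicts) as CSV; returns the frame."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, index=False)
    return df


def save_fields(path: str | Path, **arrays) -> None:
    """Deterministic .npz writer (fixed zip timestamps, no compression)."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[name]))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_fields(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable parameter object."""
    import hashlib

    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
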