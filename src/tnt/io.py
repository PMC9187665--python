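"""Movie readers/writers and pipeline configuration.

Movies are multi-page TIFFs in T,Z,C,Y,X order with a plain-text key:value
sidecar (``<movie>.meta.txt``) carrying pixel size, z step, channel names
and per-channel sample times, so outputs stay inspectable with standard
tools.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from tnt.config import KineticsConfig, SimulationConfig
from tnt.detect import DetectionParams
from tnt.quantify import CropGeometry
from tnt.stack import ImageStack


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.txt")


def write_stack(stack: ImageStack, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    lines = [
        f"shape_tzcyx: {' '.join(str(s) for s in stack.data.shape)}",
        f"dtype: {stack.data.dtype}",
        f"pixel_size_nm: {stack.pixel_size_nm}",
        f"z_step_nm: {stack.z_step_nm}",
        f"channels: {','.join(stack.channels)}",
        f"frame_times_s: {','.join(repr(float(t)) for t in stack.frame_times_s)}",
    ]
    for c in stack.channels:
        ts = ','.join(repr(float(t)) for t in stack.channel_times_s[c])
        lines.append(f"channel_times_s[{c}]: {ts}")
    _sidecar_path(path).write_text("\n".join(lines) + "\n")


def read_stack(path) -> ImageStack:
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse TIFF file {path}: {exc}") from exc

    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        for n, line in enumerate(sidecar.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            if ":" not in line:
                raise ValueError(f"{sidecar}:{n}: expected 'key: value'")
            key, val = line.split(":", 1)
            meta[key.strip()] = val.strip()

    # promote lower-dimensional images: a 2-D frame becomes T=Z=C=1
    while data.ndim < 5:
        data = data[None]
    if "shape_tzcyx" in meta:
        declared = tuple(int(s) for s in meta["shape_tzcyx"].split())
        if declared != data.shape:
            raise ValueError(
                f"{path}: TIFF shape {data.shape} does not match sidecar "
                f"declaration {declared}"
            )

    channels = tuple(meta["channels"].split(",")) if "channels" in meta else None
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(data.shape[2]))
    frame_times = None
    if "frame_times_s" in meta:
        frame_times = np.array([float(x) for x in meta["frame_times_s"].split(",")])
    channel_times = {}
    for c in channels:
        key = f"channel_times_s[{c}]"
        if key in meta:
            channel_times[c] = np.array([float(x) for x in meta[key].split(",")])
    return ImageStack(
        data=data,
        pixel_size_nm=float(meta.get("pixel_size_nm", 130.0)),
        z_step_nm=float(meta.get("z_step_nm", 500.0)),
        channels=channels,
        frame_times_s=frame_times,
        channel_times_s=channel_times,
    )


# ---------------------------------------------------------------------------
# pipeline configuration

_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "kinetics": KineticsConfig,
    "detection": DetectionParams,
}
_SCALAR_SECTIONS = {
    "tracking": {"max_step_px": 10.0, "min_track_len": 5},
    "quantification": {"geometry": "hilo_bestz", "classify_k_sd": 3.0},
    "runoff": {"enabled": "auto", "L_aa": 1885.0, "n_fit_points": 30,
               "baseline_window_min": [40.0, 60.0]},
    "metrics": {"correlation_min_points": 10},
}


class PipelineConfig:
    """Validated nested configuration for the full pipeline.

    Unknown sections or keys are rejected; all defaults serialize and
    round-trip through YAML.
    """

    def __init__(self, raw: Optional[dict] = None):
        raw = dict(raw or {})
        known = set(_SECTION_TYPES) | set(_SCALAR_SECTIONS)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        self.sections: dict = {}
        for name, cls in _SECTION_TYPES.items():
            sub = dict(raw.get(name, {}))
            valid = {f.name for f in dataclasses.fields(cls)}
            bad = set(sub) - valid
            if bad:
                raise ValueError(f"unknown key(s) in [{name}]: {sorted(bad)}")
            if name == "simulation" and "field_size_px" in sub:
                sub["field_size_px"] = tuple(sub["field_size_px"])
            self.sections[name] = cls(**sub)
        for name, defaults in _SCALAR_SECTIONS.items():
            sub = dict(raw.get(name, {}))
            bad = set(sub) - set(defaults)
            if bad:
                raise ValueError(f"unknown key(s) in [{name}]: {sorted(bad)}")
            merged = {**defaults, **sub}
            self.sections[name] = merged

    def __getitem__(self, name):
        return self.sections[name]

    def geometry(self) -> CropGeometry:
        name = self.sections["quantification"]["geometry"]
        factory = {
            "hilo_maxz": CropGeometry.hilo_maxz,
            "hilo_bestz": CropGeometry.hilo_bestz,
            "confocal": CropGeometry.confocal,
        }.get(name)
        if factory is None:
            raise ValueError(f"unknown quantification geometry {name!r}")
        return factory()

    def to_dict(self) -> dict:
        out = {}
        for name, val in self.sections.items():
            if dataclasses.is_dataclass(val):
                out[name] = dataclasses.asdict(val)
            else:
                out[name] = dict(val)
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(clean(self.to_dict()), fh, sort_keys=True)
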