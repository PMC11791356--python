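"""TIFF / CSV / JSON / YAML I/O and the run configuration.

Movies travel as multi-page TIFF with a JSON sidecar (same path, ``.json``
extension) holding geometry, protocol and, for synthetic movies, the ground
truth.  dF/F0 stacks are written as 32-bit float TIFF plus a validity mask.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .dff import BaselineParams, DffStack
from .hotspots import DetectionParams, Hotspot
from .movie import MovieGeometry, MovieStack, StimulusProtocol
from .sensor import SensorParams


class MovieReadError(ValueError):
    """Raised for corrupt or inconsistent movie files."""


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_movie(path, stack: MovieStack, truth=None,
                dtype: str = "uint16") -> Path:
    """Write a movie as multi-page TIFF plus a JSON sidecar; returns the
    sidecar path.  ``dtype='uint16'`` rounds and clips to the camera range;
    ``'float32'`` keeps fractional intensities."""
    path = Path(path)
    if dtype == "uint16":
        frames = np.clip(np.rint(stack.frames), 0, np.iinfo(np.uint16).max)
        frames = frames.astype(np.uint16)
    elif dtype == "float32":
        frames = stack.frames.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, frames)

    meta: dict[str, Any] = {
        "geometry": dataclasses.asdict(stack.geometry),
        "protocol": dataclasses.asdict(stack.protocol) if stack.protocol else None,
    }
    if truth is not None:
        meta["ground_truth"] = truth.to_dict()
    side = _sidecar_path(path)
    side.write_text(json.dumps(meta, indent=1))
    return side


def read_movie(path, pixel_size_um: Optional[float] = None,
               frame_rate_hz: Optional[float] = None) -> MovieStack:
    """Read a multi-page TIFF movie, taking metadata from the JSON sidecar
    when present; explicit arguments override, missing metadata falls back to
    the documented defaults."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = [p.shape for p in tif.pages]
            if len(set(shapes)) > 1:
                bad = next(i for i, s in enumerate(shapes) if s != shapes[0])
                raise MovieReadError(
                    f"inconsistent page shapes in {path.name}: page {bad} is "
                    f"{shapes[bad]}, expected {shapes[0]}")
            frames = tif.asarray()
    except MovieReadError:
        raise
    except Exception as exc:  # tifffile raises various types on corruption
        raise MovieReadError(f"cannot read {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise MovieReadError(f"{path.name} is not a 2-D time series")

    geometry = None
    protocol = None
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        g = meta.get("geometry")
        if g:
            geometry = MovieGeometry(**g)
        p = meta.get("protocol")
        if p:
            protocol = StimulusProtocol(**p)
    if geometry is None:
        geometry = MovieGeometry(height=frames.shape[1], width=frames.shape[2],
                                 n_frames=frames.shape[0])
    if pixel_size_um is not None or frame_rate_hz is not None:
        geometry = dataclasses.replace(
            geometry,
            pixel_size_um=pixel_size_um or geometry.pixel_size_um,
            frame_rate_hz=frame_rate_hz or geometry.frame_rate_hz)
    return MovieStack(frames.astype(np.float64), geometry, protocol)


def read_ground_truth(movie_path) -> Optional[dict]:
    side = _sidecar_path(movie_path)
    if not side.exists():
        return None
    return json.loads(side.read_text()).get("ground_truth")


def write_dff(path, stack: DffStack) -> None:
    """dF/F0 as float32 TIFF; the validity mask goes to ``<stem>_mask.tif``."""
    path = Path(path)
    tifffile.imwrite(path, np.nan_to_num(stack.dff, nan=0.0).astype(np.float32))
    tifffile.imwrite(path.with_name(path.stem + "_mask.tif"),
                     stack.valid.astype(np.uint8))


def hotspots_to_frame(hotspots: list[Hotspot]) -> pd.DataFrame:
    cols = ["id", "row", "col", "area_um2", "n_pixels", "peak_dff",
            "peak_time_s", "fwhm_s", "fwhm_one_sided", "variation_ok",
            "size_ok", "noise_ok", "accepted", "rejection_reason"]
    if not hotspots:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([h.to_row() for h in hotspots])[cols]


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# run configuration


def _from_mapping(cls, data: dict, where: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclasses.dataclass
class RunConfig:
    """Full parameter set of a pipeline run; round-trips through YAML."""

    seed: int = 0
    log_level: str = "INFO"
    sensor: SensorParams = dataclasses.field(default_factory=SensorParams)
    baseline: BaselineParams = dataclasses.field(default_factory=BaselineParams)
    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    geometry: Optional[MovieGeometry] = None
    protocol: StimulusProtocol = dataclasses.field(default_factory=StimulusProtocol)
    simulation: dict = dataclasses.field(default_factory=dict)

    _SECTIONS = {"sensor": SensorParams, "baseline": BaselineParams,
                 "detection": DetectionParams, "geometry": MovieGeometry,
                 "protocol": StimulusProtocol}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"seed", "log_level", "simulation", *cls._SECTIONS}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {
            "seed": data.get("seed", 0),
            "log_level": data.get("log_level", "INFO"),
            "simulation": data.get("simulation", {}) or {},
        }
        for name, section_cls in cls._SECTIONS.items():
            if name in data and data[name] is not None:
                kwargs[name] = _from_mapping(section_cls, data[name], name)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out: dict[str, Any] = {"seed": self.seed, "log_level": self.log_level,
                               "simulation": self.simulation}
        for name in self._SECTIONS:
            value = getattr(self, name)
            out[name] = dataclasses.asdict(value) if value is not None else None
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
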