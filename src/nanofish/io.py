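"""TIFF, TSV and YAML-config I/O, with provenance headers on every table."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import FrameGeometry, Image, NoiseModel, OpticsModel

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_tiff",
    "read_tiff",
    "write_table",
    "read_table",
]


class ConfigError(ValueError):
    """A required configuration field is missing or invalid."""


@dataclass
class RunConfig:
    """Run-wide parameters: optics per channel, frame, camera, thresholds."""

    frame: FrameGeometry
    optics: dict[str, OpticsModel]
    noise: NoiseModel
    photons: float = 5000.0
    qc_snr: float = 3.0
    qc_gaussian_likeness: float = 0.7
    qc_local_contrast: float = 5.0
    fit_method: str = "lsq"
    fit_tol: float = 1e-4
    fit_max_iterations: int = 100
    registration_k: int = 20
    registration_grid_pitch_px: int = 8
    pairing_gate_nm: float = 200.0
    histogram_bin_width_nm: float = 30.0
    seed: int = 0
    raw: dict = field(default_factory=dict)

    def fingerprint(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(mapping: dict, key: str, context: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"missing required field '{context}.{key}'"
                          if context else f"missing required field '{key}'")
    return mapping[key]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a flat YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    f = _require(raw, "frame", "")
    frame = FrameGeometry(
        width_px=int(_require(f, "width_px", "frame")),
        height_px=int(_require(f, "height_px", "frame")),
        pixel_size_nm=float(_require(f, "pixel_size_nm", "frame")),
    )
    o = _require(raw, "optics", "")
    optics = {}
    for ch, spec in o.items():
        optics[ch] = OpticsModel(
            wavelength_nm=float(_require(spec, "wavelength_nm", f"optics.{ch}")),
            numerical_aperture=float(_require(spec, "numerical_aperture", f"optics.{ch}")),
        )
    n = raw.get("noise", {})
    noise = NoiseModel(
        background_photons_per_px=float(n.get("background_photons_per_px", 0.0)),
        read_noise_e=float(n.get("read_noise_e", 0.0)),
        gain_counts_per_photon=float(n.get("gain_counts_per_photon", 1.0)),
    )
    cfg = RunConfig(frame=frame, optics=optics, noise=noise, raw=raw)
    for key in ("photons", "qc_snr", "qc_gaussian_likeness", "qc_local_contrast",
                "fit_tol", "pairing_gate_nm", "histogram_bin_width_nm"):
        if key in raw:
            setattr(cfg, key, float(raw[key]))
    for key in ("fit_max_iterations", "registration_k",
                "registration_grid_pitch_px", "seed"):
        if key in raw:
            setattr(cfg, key, int(raw[key]))
    if "fit_method" in raw:
        if raw["fit_method"] not in ("lsq", "centroid", "mle"):
            raise ConfigError("fit_method must be one of lsq|centroid|mle")
        cfg.fit_method = raw["fit_method"]
    return cfg


def write_tiff(image: Image, path: str | Path) -> None:
    """Write counts as 16-bit TIFF with acquisition metadata in the header."""
    meta = {
        "pixel_size_nm": image.frame.pixel_size_nm,
        "wavelength_nm": image.optics.wavelength_nm,
        "numerical_aperture": image.optics.numerical_aperture,
        "gain_counts_per_photon": image.camera.gain_counts_per_photon,
        "channel_id": image.channel_id,
    }
    data = np.clip(np.rint(image.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, metadata=meta)


def read_tiff(path: str | Path,
              optics: Optional[OpticsModel] = None,
              pixel_size_nm: Optional[float] = None,
              gain: Optional[float] = None,
              channel_id: Optional[str] = None) -> Image:
    """Read a 16-bit TIFF back into an Image; explicit arguments override
    any metadata stored in the file."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    px = pixel_size_nm if pixel_size_nm is not None else float(meta.get("pixel_size_nm", 0) or 0)
    if px <= 0:
        raise ConfigError("pixel_size_nm not in TIFF metadata; pass it explicitly")
    if optics is None:
        wl = meta.get("wavelength_nm")
        na = meta.get("numerical_aperture")
        if wl is None or na is None:
            raise ConfigError("optics not in TIFF metadata; pass them explicitly")
        optics = OpticsModel(float(wl), float(na))
    g = gain if gain is not None else float(meta.get("gain_counts_per_photon", 1.0))
    frame = FrameGeometry(width_px=data.shape[1], height_px=data.shape[0],
                          pixel_size_nm=px)
    cam = NoiseModel(gain_counts_per_photon=g)
    ch = channel_id if channel_id is not None else str(meta.get("channel_id", "A"))
    return Image(data=data, frame=frame, optics=optics, camera=cam, channel_id=ch)


def write_table(df: pd.DataFrame, path: str | Path,
                config: Optional[RunConfig] = None,
                extra_meta: Optional[dict] = None) -> None:
    """TSV with '#'-prefixed provenance header lines."""
    lines = []
    if config is not None:
        lines.append(f"# config_fingerprint\t{config.fingerprint()}")
        lines.append(f"# seed\t{config.seed}")
        lines.append(f"# qc_thresholds\tsnr={config.qc_snr} "
                     f"gaussian_likeness={config.qc_gaussian_likeness} "
                     f"local_contrast={config.qc_local_contrast}")
        lines.append(f"# fit\tmethod={config.fit_method} tol={config.fit_tol} "
                     f"max_iterations={config.fit_max_iterations}")
        lines.append(f"# registration\tk={config.registration_k} "
                     f"grid_pitch_px={config.registration_grid_pitch_px}")
        lines.append(f"# pairing_gate_nm\t{config.pairing_gate_nm}")
        lines.append(f"# histogram_bin_width_nm\t{config.histogram_bin_width_nm}")
    for k, v in (extra_meta or {}).items():
        lines.append(f"# {k}\t{v}")
    header = "\n".join(lines)
    body = df.to_csv(sep="\t", index=False)
    Path(path).write_text((header + "\n" if header else "") + body)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
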