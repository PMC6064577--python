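"""File I/O: photographs and scenes as PNG with JSON sidecars.

8-bit greyscale PNG is the canonical lossless image format; every image
carries a ``<name>.json`` sidecar with its acquisition metadata so a
photograph can be reloaded for analysis without its scene.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from canopyhp.camera import CameraConfig, Photograph, circular_mask
from canopyhp.image_analysis import MisclassificationMap
from canopyhp.model_canopy import SceneRaster

__all__ = [
    "save_photograph",
    "load_photograph",
    "save_scene",
    "load_scene",
    "save_misclassification_png",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_photograph(photo: Photograph, path: str | Path) -> None:
    path = Path(path)
    iio.imwrite(path, photo.dn)
    meta = {
        "exposure": photo.exposure,
        "blur_sigma": photo.blur_sigma,
        "mask_diameter": _mask_diameter(photo),
        "camera": dataclasses.asdict(photo.config),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def _mask_diameter(photo: Photograph) -> int:
    if photo.config.mask_diameter is not None:
        return int(photo.config.mask_diameter)
    return int(min(photo.shape))


def load_photograph(path: str | Path) -> Photograph:
    path = Path(path)
    dn = np.asarray(iio.imread(path))
    if dn.ndim == 3:  # collapse an RGB image to greyscale
        dn = dn.mean(axis=-1)
    dn = np.clip(np.rint(dn), 0, 255).astype(np.uint8)
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        config = CameraConfig(**meta.get("camera", {}))
        exposure = float(meta.get("exposure", 0.0))
        blur_sigma = float(meta.get("blur_sigma", config.blur_sigma))
        diameter = meta.get("mask_diameter") or min(dn.shape)
    else:
        config = CameraConfig()
        exposure, blur_sigma, diameter = 0.0, config.blur_sigma, min(dn.shape)
    mask = circular_mask(dn.shape, min(diameter, min(dn.shape)))
    return Photograph(
        dn=dn, mask=mask, exposure=exposure, blur_sigma=blur_sigma, config=config
    )


def save_scene(scene: SceneRaster, path: str | Path) -> None:
    """Scene occupancy as 16-bit PNG plus ground truth in the sidecar."""
    path = Path(path)
    iio.imwrite(path, np.round(scene.occupancy * 65535).astype(np.uint16))
    meta = {
        "pixel_scale": scene.pixel_scale,
        "true_gap_fraction": scene.true_gap_fraction,
        "true_border_length": scene.true_border_length,
        "spec": None
        if scene.spec is None
        else {
            "side_length": scene.spec.side_length,
            "separation": scene.spec.separation,
            "sheet_width": scene.spec.sheet_width,
            "sheet_height": scene.spec.sheet_height,
        },
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_scene(path: str | Path) -> SceneRaster:
    path = Path(path)
    occupancy = np.asarray(iio.imread(path), dtype=float) / 65535.0
    meta = json.loads(_sidecar(path).read_text())
    spec = None
    if meta.get("spec"):
        from canopyhp.model_canopy import CanopySpec

        spec = CanopySpec(**meta["spec"])
    return SceneRaster(
        occupancy=occupancy,
        pixel_scale=float(meta["pixel_scale"]),
        spec=spec,
        true_border_length=meta.get("true_border_length"),
    )


def save_misclassification_png(mmap: MisclassificationMap, path: str | Path) -> None:
    """Write the white/black/red/blue misclassification map as RGB PNG."""
    iio.imwrite(Path(path), mmap.to_rgb())
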