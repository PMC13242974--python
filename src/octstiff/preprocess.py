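"""B-scan series container, image conditioning, and series I/O.

The conditioning chain mirrors what is done to raw OCT exports before
segmentation: grayscale conversion, a centred square crop (997 x 997 px at
the device's native raster), and mild Gaussian smoothing. Series travel as
multi-page TIFF stacks (or numbered PNG directories) with a JSON metadata
sidecar carrying frame rate and pixel pitch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "BScanSeries", "FormatError", "to_grayscale", "crop_center",
    "gaussian_denoise", "preprocess_series", "load_series", "save_series",
    "save_mask_stack", "load_mask_stack",
]

_LUMA = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Malformed series on disk or an unsupported raster layout."""


@dataclass
class BScanSeries:
    """Time-ordered stack of grayscale B-scans plus acquisition metadata."""

    frames: np.ndarray  # (n, H, W) float32 in [0, 1]
    fps: float
    axial_pitch_um: float
    lateral_pitch_um: float
    source_id: str = "unnamed"
    protocol: dict = field(default=None, repr=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (n_frames, H, W) stack")
        if self.fps <= 0 or self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise FormatError("fps and pixel pitches must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Reduce a channels-last RGB raster to luminance; pass 2-D through."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] == 1:
        return frame[..., 0]
    if frame.ndim == 3 and frame.shape[-1] == 3:
        return (frame @ _LUMA).astype(frame.dtype)
    raise FormatError(f"expected 2-D or 3-channel raster, got shape {frame.shape}")


def crop_center(frame: np.ndarray, size_px: int) -> np.ndarray:
    """Centred size_px x size_px window; odd remainders drop the bottom/right."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise FormatError("crop_center expects a 2-D raster")
    h, w = frame.shape
    if h < size_px or w < size_px:
        raise FormatError(f"frame {h}x{w} smaller than crop size {size_px}")
    top = (h - size_px) // 2
    left = (w - size_px) // 2
    return frame[top : top + size_px, left : left + size_px]


def gaussian_denoise(frame: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian smoothing with reflective boundaries; sigma 0 is the identity."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    frame = np.asarray(frame, dtype=np.float32)
    if sigma_px == 0:
        return frame
    return ndimage.gaussian_filter(frame, sigma=sigma_px, mode="reflect")


def preprocess_series(series: BScanSeries, crop_px: int | None = None,
                      sigma_px: float = 1.0) -> BScanSeries:
    """Grayscale -> optional centre crop -> Gaussian smoothing, per frame."""
    out = []
    for f in series.frames:
        g = to_grayscale(f)
        if crop_px is not None:
            g = crop_center(g, crop_px)
        out.append(gaussian_denoise(g, sigma_px))
    return BScanSeries(frames=np.stack(out), fps=series.fps,
                       axial_pitch_um=series.axial_pitch_um,
                       lateral_pitch_um=series.lateral_pitch_um,
                       source_id=series.source_id, protocol=series.protocol)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF (or PNG directory) + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json") if path.suffix else path / "series.json"


def save_series(series: BScanSeries, path: str | Path, bit_depth: int = 16,
                protocol=None) -> None:
    """Write frames as a multi-page TIFF (``.tif``/``.tiff``) or a numbered
    PNG directory (any other path), plus a JSON metadata sidecar."""
    path = Path(path)
    if bit_depth not in (8, 16):
        raise FormatError("bit_depth must be 8 or 16")
    scale = 2 ** bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    q = np.round(np.clip(series.frames, 0, 1) * scale).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, q, photometric="minisblack")
    else:
        import imageio.v3 as iio
        path.mkdir(parents=True, exist_ok=True)
        for i, f in enumerate(q):
            iio.imwrite(path / f"frame_{i:05d}.png", f)
    meta = {
        "fps": series.fps,
        "axial_pitch_um": series.axial_pitch_um,
        "lateral_pitch_um": series.lateral_pitch_um,
        "source_id": series.source_id,
        "bit_depth": bit_depth,
    }
    proto = protocol if protocol is not None else series.protocol
    if proto is not None:
        meta["protocol"] = proto if isinstance(proto, dict) else vars(proto)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_series(path: str | Path) -> BScanSeries:
    """Load a TIFF stack or PNG directory written by :func:`save_series`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar {sidecar} missing")
    meta = json.loads(sidecar.read_text())
    for key in ("fps", "axial_pitch_um", "lateral_pitch_um"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field {key!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
    else:
        import imageio.v3 as iio
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FormatError(f"no frame_*.png files in {path}")
        arrays = [iio.imread(f) for f in files]
        shapes = {a.shape for a in arrays}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent frame shapes: {sorted(shapes)}")
        stack = np.stack(arrays)
    bit_depth = meta.get("bit_depth", 16 if stack.dtype == np.uint16 else 8)
    frames = stack.astype(np.float32) / (2 ** bit_depth - 1)
    return BScanSeries(frames=frames, fps=meta["fps"],
                       axial_pitch_um=meta["axial_pitch_um"],
                       lateral_pitch_um=meta["lateral_pitch_um"],
                       source_id=meta.get("source_id", path.stem),
                       protocol=meta.get("protocol"))


def save_mask_stack(masks: np.ndarray, path: str | Path) -> None:
    """Write a (n, H, W) {0,1} mask stack as a byte TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(masks, dtype=np.uint8),
                     photometric="minisblack")


def load_mask_stack(path: str | Path) -> np.ndarray:
    masks = tifffile.imread(Path(path))
    if masks.ndim == 2:
        masks = masks[None]
    return (masks > 0).astype(np.uint8)
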