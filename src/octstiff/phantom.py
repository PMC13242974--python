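"""Synthetic OCT B-scan phantoms with known layer geometry and stiffness.

The phantom emulates what the air-jet indentation experiment records: a
time-resolved stack of speckled, depth-attenuated B-scans in which a bright
stratum-corneum (SC) band sits over deeper, dimmer layers, and the whole layer
stack is pressed downward during the on-window of the 5 s / 5 s / 5 s air-jet
protocol. Because the dent amplitude is constructed as delta_max = F / K_true,
the phantom carries an exact ground-truth stiffness against which the full
segmentation + biomechanics chain can be validated.

Depth convention (used throughout the package): row 0 is the shallowest
sample, depth grows with the row index, and indentation increases depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .biomech import AirJetProtocol, force
from .preprocess import BScanSeries, save_series, save_mask_stack


class PhantomError(ValueError):
    """Invalid phantom configuration (e.g. dent exceeds the depth budget)."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optics and mechanics of a synthetic layered B-scan series.

    Intensities are in [0, 1]. ``layer_contrasts`` lists the mean reflectance
    of the SC band first, then each deeper layer (length 1 + n_deeper_layers).
    ``speckle_contrast`` is the std/mean ratio of the multiplicative
    unit-mean gamma speckle; ``attenuation_per_mm`` the exponential intensity
    decay with depth below the tissue surface. ``k_true_n_per_mm`` is the
    ground-truth structural stiffness: the dent amplitude under a protocol is
    force(protocol) / k_true.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    axial_pitch_um: float = 7.5
    lateral_pitch_um: float = 10.0
    fps: float = 10.0
    sc_top_depth_mm: float = 0.4
    sc_thickness_mm: float = 0.25
    n_deeper_layers: int = 2
    layer_contrasts: tuple[float, ...] = (0.85, 0.45, 0.30)
    deeper_layer_thickness_mm: float = 0.6
    air_floor: float = 0.03
    speckle_contrast: float = 0.35
    attenuation_per_mm: float = 0.8
    indent_sigma_mm: float = 0.8
    k_true_n_per_mm: float = 1.0
    ramp_s: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise PhantomError("image dimensions must be positive")
        for name in ("axial_pitch_um", "lateral_pitch_um", "fps",
                     "sc_thickness_mm", "indent_sigma_mm", "k_true_n_per_mm"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be positive")
        if self.sc_top_depth_mm < 0 or self.attenuation_per_mm < 0:
            raise PhantomError("sc_top_depth_mm and attenuation must be >= 0")
        if not 0 <= self.speckle_contrast <= 1:
            raise PhantomError("speckle_contrast must be in [0, 1]")
        if len(self.layer_contrasts) != 1 + self.n_deeper_layers:
            raise PhantomError("layer_contrasts must have 1 + n_deeper_layers entries")
        if not all(0 <= c <= 1 for c in self.layer_contrasts):
            raise PhantomError("layer contrasts must lie in [0, 1]")
        if self.sc_top_depth_mm + self.sc_thickness_mm >= self.depth_mm:
            raise PhantomError("SC band does not fit in the image depth")

    @property
    def depth_mm(self) -> float:
        return self.image_height_px * self.axial_pitch_um / 1000.0


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated series.

    ``boundary_depth_mm`` is the analytic depth of the SC upper boundary at
    the central A-scan per frame; ``masks`` the exact rasterised SC masks;
    ``delta_d_true_mm`` the analytic displacement max(on) - mean(pre).
    """

    boundary_depth_mm: np.ndarray
    masks: np.ndarray  # (n_frames, H, W) uint8 in {0, 1}
    delta_d_true_mm: float
    k_true_n_per_mm: float
    delta_max_mm: float = 0.0
    t_s: np.ndarray = field(default=None, repr=False)


def _smoothstep(u: np.ndarray | float) -> np.ndarray | float:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def displacement_waveform(t_s: float, protocol: AirJetProtocol,
                          delta_max_mm: float, ramp_s: float = 0.5) -> float:
    """Analytic dent depth (mm) at time ``t_s`` under the air-jet protocol.

    Zero during the pre window, a smoothstep ramp (duration ``ramp_s``) to a
    plateau of ``delta_max_mm`` during the on window, and a symmetric
    smoothstep release back to zero in the post window.
    """
    if delta_max_mm < 0:
        raise ValueError("delta_max_mm must be >= 0")
    total = protocol.pre_s + protocol.on_s + protocol.post_s
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0) or np.any(t > total):
        raise ValueError(f"t_s must lie in [0, {total}] s")
    ramp = min(ramp_s, protocol.on_s, protocol.post_s)
    t_on = protocol.pre_s
    t_off = protocol.pre_s + protocol.on_s
    up = _smoothstep((t - t_on) / ramp) if ramp > 0 else (t >= t_on).astype(float)
    down = _smoothstep((t - t_off) / ramp) if ramp > 0 else (t >= t_off).astype(float)
    out = delta_max_mm * (up - down)
    return float(out) if np.isscalar(t_s) else out


def _rasterize_frame(config: PhantomConfig, boundary_mm: np.ndarray,
                     rng: np.random.Generator):
    """Render one frame given the per-column SC top depth; returns (img, mask)."""
    h, w = config.image_height_px, config.image_width_px
    z = (np.arange(h, dtype=np.float64) + 0.5) * config.axial_pitch_um / 1000.0
    rel = z[:, None] - boundary_mm[None, :]  # depth below the tissue surface
    # layer index: 0 = air, 1 = SC, 2.. = deeper layers
    edges = np.concatenate([[0.0],
                            np.cumsum([config.sc_thickness_mm] +
                                      [config.deeper_layer_thickness_mm] *
                                      config.n_deeper_layers)])
    idx = np.searchsorted(edges, rel, side="right")
    intensities = np.array((config.air_floor,) + tuple(config.layer_contrasts) +
                           (config.layer_contrasts[-1],))
    base = intensities[np.minimum(idx, len(intensities) - 1)]
    tissue = idx > 0
    base = base * np.where(tissue, np.exp(-config.attenuation_per_mm *
                                          np.maximum(rel, 0.0)), 1.0)
    if config.speckle_contrast > 0:
        shape = 1.0 / config.speckle_contrast ** 2
        speckle = rng.gamma(shape, 1.0 / shape, size=(h, w))
        base = base * speckle
    img = np.clip(base, 0.0, 1.0).astype(np.float32)
    mask = (idx == 1).astype(np.uint8)
    return img, mask


def generate_series(config: PhantomConfig,
                    protocol: AirJetProtocol) -> tuple[BScanSeries, PhantomTruth]:
    """Simulate a deforming B-scan series; returns the series and its truth.

    The dent amplitude is F(protocol) / k_true; the whole layer stack is
    translated downward by the waveform times a Gaussian lateral envelope
    centred on the image. The same config + seed is bit-reproducible.
    """
    f_n = force(protocol)
    delta_max = f_n / config.k_true_n_per_mm
    deepest = config.sc_top_depth_mm + config.sc_thickness_mm + delta_max
    if deepest >= config.depth_mm:
        raise PhantomError(
            f"dent of {delta_max:.3f} mm pushes the SC band below the "
            f"{config.depth_mm:.3f} mm image depth")
    n_frames = int(np.floor(config.fps * (protocol.pre_s + protocol.on_s +
                                          protocol.post_s)))
    t = np.arange(n_frames) / config.fps
    w_px = config.image_width_px
    x_mm = (np.arange(w_px) - (w_px - 1) / 2.0) * config.lateral_pitch_um / 1000.0
    envelope = np.exp(-x_mm ** 2 / (2.0 * config.indent_sigma_mm ** 2))
    center_col = w_px // 2 if w_px % 2 else w_px // 2 - 1

    rng = np.random.default_rng(config.seed)
    frames = np.empty((n_frames, config.image_height_px, w_px), dtype=np.float32)
    masks = np.empty((n_frames, config.image_height_px, w_px), dtype=np.uint8)
    boundary_center = np.empty(n_frames)
    for i, ti in enumerate(t):
        dent = displacement_waveform(ti, protocol, delta_max, config.ramp_s)
        boundary = config.sc_top_depth_mm + dent * envelope
        frames[i], masks[i] = _rasterize_frame(config, boundary, rng)
        boundary_center[i] = boundary[center_col]

    pre = t < protocol.pre_s
    on = (t >= protocol.pre_s) & (t < protocol.pre_s + protocol.on_s)
    delta_d_true = float(boundary_center[on].max() - boundary_center[pre].mean())
    series = BScanSeries(frames=frames, fps=config.fps,
                         axial_pitch_um=config.axial_pitch_um,
                         lateral_pitch_um=config.lateral_pitch_um,
                         source_id=f"phantom-k{config.k_true_n_per_mm}-s{config.seed}")
    truth = PhantomTruth(boundary_depth_mm=boundary_center, masks=masks,
                         delta_d_true_mm=delta_d_true,
                         k_true_n_per_mm=config.k_true_n_per_mm,
                         delta_max_mm=delta_max, t_s=t)
    return series, truth


def make_segmentation_dataset(n_images: int, image_size_px: int = 96,
                              axial_pitch_um: float = 15.0, seed: int = 0,
                              frames_per_phantom: int = 4):
    """Build a varied phantom frame/mask dataset for segmentation training.

    Each "patient" is one phantom with its own randomly drawn layer geometry,
    contrast, speckle level and stiffness; ``frames_per_phantom`` frames are
    sampled across its indentation time course so both resting and displaced
    anatomy are represented. Returns ``(images, masks, patient_of)`` where
    ``patient_of`` maps image index -> phantom id (for patient-level splits).
    """
    rng = np.random.default_rng(seed)
    n_phantoms = int(np.ceil(n_images / frames_per_phantom))
    images, masks, patient_of = [], [], {}
    depth_mm = image_size_px * axial_pitch_um / 1000.0
    protocol = AirJetProtocol(pre_s=1.0, on_s=1.0, post_s=1.0, pressure_pa=80_000.0)
    f_n = force(protocol)
    for p in range(n_phantoms):
        # geometry drawn relative to the depth budget so any raster works
        sc_top = rng.uniform(0.12, 0.25) * depth_mm
        thickness = rng.uniform(0.10, 0.20) * depth_mm
        headroom = depth_mm - sc_top - thickness - 0.1 * depth_mm
        k_min = f_n / headroom
        k_true = max(rng.uniform(0.6, 2.5), k_min * 1.01)
        cfg = PhantomConfig(
            image_height_px=image_size_px, image_width_px=image_size_px,
            axial_pitch_um=axial_pitch_um,
            fps=frames_per_phantom / 3.0,  # spread frames over the protocol
            sc_top_depth_mm=sc_top,
            sc_thickness_mm=thickness,
            layer_contrasts=(rng.uniform(0.7, 0.95), rng.uniform(0.35, 0.55),
                             rng.uniform(0.2, 0.4)),
            speckle_contrast=rng.uniform(0.25, 0.45),
            attenuation_per_mm=rng.uniform(0.5, 1.2),
            indent_sigma_mm=rng.uniform(0.5, 1.0),
            k_true_n_per_mm=k_true,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        series, truth = generate_series(cfg, protocol)
        for j in range(min(frames_per_phantom, len(series.frames))):
            images.append(series.frames[j])
            masks.append(truth.masks[j])
            patient_of[len(images) - 1] = p
    images = np.stack(images[:n_images])
    masks = np.stack(masks[:n_images])
    patient_of = {i: patient_of[i] for i in range(n_images)}
    return images, masks, patient_of


def save_phantom(out_dir: str | Path, series: BScanSeries, truth: PhantomTruth,
                 protocol: AirJetProtocol) -> None:
    """Write frames + sidecar, truth masks, and truth scalars under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_series(series, out / "series.tiff", protocol=protocol)
    save_mask_stack(truth.masks, out / "truth_masks.tiff")
    scalars = {
        "delta_d_true_mm": truth.delta_d_true_mm,
        "k_true_n_per_mm": truth.k_true_n_per_mm,
        "delta_max_mm": truth.delta_max_mm,
        "boundary_depth_mm": truth.boundary_depth_mm.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(scalars, indent=1))
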