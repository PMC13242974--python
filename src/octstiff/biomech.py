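"""Air-jet indentation biomechanics: from segmented B-scans to stiffness.

The structural stiffness coefficient is K = F / delta_d (N/mm), with F the
air-jet force (gauge pressure times nozzle bore area) and delta_d the
indentation depth of the tracked stratum-corneum landmark: the difference
between its mean depth over the 5 s pre-pressure baseline and its maximum
depth while the jet is on. K folds in the sample's geometry, which is what
makes it robust on layered, irregular tissue where a Young's modulus fit
would require homogeneity assumptions the tissue does not satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AirJetProtocol", "DepthTrace", "StiffnessResult", "TrackingError",
    "extract_centerline", "composite_profile", "track_depth",
    "displacement", "force", "stiffness", "quantify_series",
]


class TrackingError(RuntimeError):
    """A frame's mask is unusable for landmark tracking."""


class UndefinedStiffnessError(ValueError):
    """delta_d <= 0: stiffness is not defined (rather than infinite)."""


@dataclass(frozen=True)
class AirJetProtocol:
    """Timing and loading of one air-jet run.

    Defaults follow the measurement timeline: 5 s baseline, 5 s with the jet
    on, 5 s recovery, through a 2 mm positive-pressure port. ``pressure_pa``
    is the gauge pressure at the nozzle; devices of this class regulate it
    with a proportional valve (0-0.5 MPa range), so it is a free parameter.
    """

    pre_s: float = 5.0
    on_s: float = 5.0
    post_s: float = 5.0
    pressure_pa: float = 150_000.0
    nozzle_diameter_mm: float = 2.0

    def __post_init__(self):
        if min(self.pre_s, self.on_s, self.post_s) <= 0:
            raise ValueError("protocol window durations must be positive")
        if self.pressure_pa < 0:
            raise ValueError("gauge pressure must be >= 0")
        if self.nozzle_diameter_mm <= 0:
            raise ValueError("nozzle diameter must be positive")

    @property
    def total_s(self) -> float:
        return self.pre_s + self.on_s + self.post_s


@dataclass
class DepthTrace:
    """Per-frame depth (mm) of the tracked SC landmark."""

    t_s: np.ndarray
    depth_mm: np.ndarray
    landmark: str = "mask_centroid"

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        if self.t_s.shape != self.depth_mm.shape:
            raise ValueError("t_s and depth_mm must have equal length")


@dataclass(frozen=True)
class StiffnessResult:
    """All symbols of K = F / delta_d, plus the depths they came from."""

    force_n: float
    delta_d_mm: float
    k_n_per_mm: float
    baseline_depth_mm: float = float("nan")
    max_depth_mm: float = float("nan")


def extract_centerline(frame: np.ndarray) -> np.ndarray:
    """Central A-scan of a B-scan: the middle column (width//2 - 1 if even)."""
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D raster")
    w = frame.shape[1]
    col = w // 2 if w % 2 else w // 2 - 1
    return frame[:, col]


def composite_profile(series, frame_window=None) -> np.ndarray:
    """Mean of the centreline profiles over a frame window (default: all)."""
    frames = series.frames if hasattr(series, "frames") else np.asarray(series)
    window = list(range(len(frames)) if frame_window is None else frame_window)
    if not window:
        raise ValueError("frame window must be non-empty")
    return np.mean([extract_centerline(frames[i]) for i in window], axis=0)


def track_depth(series, masks: np.ndarray, landmark: str = "mask_centroid",
                central_band_frac: float = 0.1) -> DepthTrace:
    """Track the SC landmark depth per frame within a central lateral band.

    ``mask_centroid``: mean mask-pixel row in the central band (sub-pixel).
    ``top_boundary``: minimum mask row in the band. Depths are rows times the
    axial pitch. Raises :class:`TrackingError` naming the first frame whose
    central band contains no mask pixels.
    """
    if landmark not in ("mask_centroid", "top_boundary"):
        raise ValueError(f"unknown landmark {landmark!r}")
    masks = np.asarray(masks)
    frames = series.frames
    if len(masks) != len(frames):
        raise ValueError("need exactly one mask per frame")
    w = frames.shape[2]
    half = max(1, int(round(w * central_band_frac))) // 2
    center = w // 2 if w % 2 else w // 2 - 1
    lo, hi = max(0, center - half), min(w, center + half + 1)
    pitch_mm = series.axial_pitch_um / 1000.0
    depths = np.empty(len(frames))
    for i, m in enumerate(masks):
        band = m[:, lo:hi]
        rows = np.nonzero(band)[0]
        if rows.size == 0:
            raise TrackingError(f"frame {i}: empty SC mask in the central band")
        row = rows.mean() if landmark == "mask_centroid" else rows.min()
        depths[i] = (row + 0.5) * pitch_mm
    return DepthTrace(t_s=series.t_s, depth_mm=depths, landmark=landmark)


def displacement(trace: DepthTrace, protocol: AirJetProtocol,
                 median_filter: bool = False):
    """(baseline_mm, max_mm, delta_d_mm) from a trace under a protocol.

    Baseline is the mean depth over the pre window; the maximum is taken over
    the on window (optionally after a 3-frame running median to suppress
    single-frame outliers); delta_d = max - baseline, floored at 0.
    """
    t, d = trace.t_s, trace.depth_mm
    if t.size == 0 or t[-1] < protocol.pre_s + protocol.on_s - 1e-9:
        raise ValueError("trace does not span the pre + on windows")
    if median_filter:
        from scipy.ndimage import median_filter as mf
        d = mf(d, size=3, mode="nearest")
    pre = t < protocol.pre_s
    on = (t >= protocol.pre_s) & (t < protocol.pre_s + protocol.on_s)
    if not pre.any() or not on.any():
        raise ValueError("protocol windows contain no frames")
    baseline = float(d[pre].mean())
    peak = float(d[on].max())
    return baseline, peak, max(0.0, peak - baseline)


def force(protocol: AirJetProtocol) -> float:
    """Air-jet force in newtons: gauge pressure times nozzle bore area."""
    if protocol.pressure_pa < 0:
        raise ValueError("gauge pressure must be >= 0")
    radius_m = protocol.nozzle_diameter_mm / 2000.0
    return protocol.pressure_pa * np.pi * radius_m ** 2


def stiffness(force_n: float, delta_d_mm: float,
              baseline_depth_mm: float = float("nan"),
              max_depth_mm: float = float("nan")) -> StiffnessResult:
    """K = F / delta_d in N/mm; refuses delta_d <= 0."""
    if force_n < 0:
        raise ValueError("force must be >= 0")
    if delta_d_mm <= 0:
        raise UndefinedStiffnessError(
            f"stiffness undefined for delta_d = {delta_d_mm} mm")
    return StiffnessResult(force_n=force_n, delta_d_mm=delta_d_mm,
                           k_n_per_mm=force_n / delta_d_mm,
                           baseline_depth_mm=baseline_depth_mm,
                           max_depth_mm=max_depth_mm)


def quantify_series(series, masks: np.ndarray, protocol: AirJetProtocol,
                    landmark: str = "mask_centroid") -> StiffnessResult:
    """Full chain: track landmark -> displacement -> K = F / delta_d."""
    trace = track_depth(series, masks, landmark=landmark)
    baseline, peak, delta_d = displacement(trace, protocol)
    return stiffness(force(protocol), delta_d, baseline, peak)
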