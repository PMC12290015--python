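"""Collapse of 2D fluorescence images onto a curved proximo-distal axis.

The limb's PD axis is a user-traced polyline; at each point along it the
local tangent is estimated from nearby points, and the pixels above an
intensity threshold along the orthogonal line (bounded by the region of
interest) are counted and assigned to that arc-length position.  The
result is a 1D normalized cell-density profile ρ_i = f_i / f_max.

Coordinate convention: axis points are (x, y) = (column, row) in pixel
units; rasters are indexed ``raster[row, col]``.  x = 0 of the profile is
the proximal end of the traced axis; re-referencing to the amputation
plane landmark is an explicit option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .profiles import DensityProfile

__all__ = [
    "LimbScene",
    "PDAxis",
    "arc_length",
    "resample_axis",
    "local_tangents",
    "collapse",
    "rereference_to_landmark",
]

logger = logging.getLogger(__name__)


@dataclass
class LimbScene:
    """Paired brightfield/fluorescence rasters with masks and metadata."""

    brightfield: np.ndarray
    fluorescence: np.ndarray
    roi_mask: np.ndarray
    exclusion_masks: list[np.ndarray] = field(default_factory=list)
    pixel_size: float = 1.0  # μm / px
    timepoint: float = 0.0   # dpe
    landmarks: dict[str, float] | None = None  # name -> arc-length μm

    def __post_init__(self) -> None:
        self.brightfield = np.asarray(self.brightfield)
        self.fluorescence = np.asarray(self.fluorescence)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        self.exclusion_masks = [np.asarray(m, dtype=bool)
                                for m in self.exclusion_masks]
        shape = self.brightfield.shape
        for name in ("fluorescence", "roi_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} "
                                 f"does not match brightfield {shape}")
        for m in self.exclusion_masks:
            if m.shape != shape:
                raise ValueError("exclusion mask shape mismatch")
        if not self.roi_mask.any():
            raise ValueError("roi_mask is empty")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class PDAxis:
    """Ordered polyline of the PD axis, proximal → distal.

    ``points`` are (x, y) pixel coordinates; ``arc_positions`` are the
    cumulative arc lengths in μm from the proximal first point.
    """

    points: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def arc_positions(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)]) * self.pixel_size

    def __len__(self) -> int:
        return len(self.points)


def arc_length(axis: PDAxis) -> float:
    """Total arc length Σ√(Δx² + Δy²) · pixel_size, in μm."""
    if len(axis) < 2:
        raise ValueError("need at least 2 points for an arc length")
    return float(axis.arc_positions[-1])


def resample_axis(axis: PDAxis, step: float) -> PDAxis:
    """Resample the polyline at uniform arc-length spacing ``step`` (μm).

    Points are linearly interpolated along segments; both endpoints are
    preserved (the final spacing may be shorter than ``step``).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    total = arc_length(axis)
    if step > total:
        raise ValueError(f"step {step} exceeds total arc length {total}")
    s = axis.arc_positions
    targets = np.arange(0.0, total + step / 2, step)
    if total - targets[-1] > 1e-9 * max(total, 1.0):
        targets = np.append(targets, total)
    else:
        targets[-1] = total
    pts = np.column_stack([np.interp(targets, s, axis.points[:, 0]),
                           np.interp(targets, s, axis.points[:, 1])])
    return PDAxis(points=pts, pixel_size=axis.pixel_size)


def local_tangents(axis: PDAxis, window: int = 2) -> np.ndarray:
    """Unit tangent per axis point by central difference over ±window.

    One-sided (clamped) differences at the endpoints.  Assumes the axis
    was resampled to uniform spacing; raises on degenerate (repeated)
    points.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(axis)
    if n < 2:
        raise ValueError("need at least 2 points")
    idx = np.arange(n)
    lo = np.clip(idx - window, 0, n - 1)
    hi = np.clip(idx + window, 0, n - 1)
    vec = axis.points[hi] - axis.points[lo]
    norm = np.linalg.norm(vec, axis=1)
    if np.any(norm == 0):
        raise ValueError("degenerate axis: repeated points give a zero tangent")
    return vec / norm[:, None]


def _estimate_cap_px(scene: LimbScene, n_axis: int) -> float:
    # hard cap on the orthogonal march: 2x the half-width estimated from
    # ROI area / axis length, guarding against mask leaks
    half_width_est = scene.roi_mask.sum() / (2.0 * max(n_axis, 1))
    return max(2.0 * half_width_est, 8.0)


def collapse(scene: LimbScene, axis: PDAxis, threshold: float,
             window: int = 2, step: float | None = None,
             strict_greater: bool = True,
             max_extent_px: float | None = None,
             normalize: bool = True) -> DensityProfile:
    """Collapse the fluorescence channel onto the PD axis.

    At each (resampled) axis point the orthogonal to the local tangent is
    marched in both directions at 0.5 px steps until it leaves the ROI
    (or hits the extent cap); distinct pixels with intensity above
    ``threshold`` and outside every exclusion mask are counted as f_i,
    and ρ = f / max(f) (all-zero f gives an all-zero profile).

    Parameters
    ----------
    threshold : intensity; "above" is strictly greater by default
        (``strict_greater=False`` switches to ≥).
    step : axis resampling step in μm (default: one pixel).
    window : tangent estimation half-window in points.
    normalize : if False, return the raw pixel counts f_i instead of ρ.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    step = scene.pixel_size if step is None else step
    rax = resample_axis(axis, step)
    tangents = local_tangents(rax, window=window)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    H, W = scene.roi_mask.shape
    cap = max_extent_px if max_extent_px is not None else \
        _estimate_cap_px(scene, len(rax))
    excluded = None
    if scene.exclusion_masks:
        excluded = np.zeros_like(scene.roi_mask)
        for m in scene.exclusion_masks:
            excluded |= m
    fluor = scene.fluorescence
    roi = scene.roi_mask
    counts = np.zeros(len(rax))
    offsets = np.arange(0.5, cap + 1e-9, 0.5)
    for i, (p, nrm) in enumerate(zip(rax.points, normals)):
        cx = int(np.floor(p[0] + 0.5))
        cy = int(np.floor(p[1] + 0.5))
        if not (0 <= cy < H and 0 <= cx < W) or not roi[cy, cx]:
            logger.warning("axis point %d at (%.1f, %.1f) is outside the ROI; "
                           "position contributes 0", i, p[0], p[1])
            continue
        visited: set[tuple[int, int]] = set()
        f = 0
        # s = 0: the axis point's own pixel
        visited.add((cy, cx))
        if _qualifies(fluor[cy, cx], threshold, strict_greater) and \
                not (excluded is not None and excluded[cy, cx]):
            f += 1
        for direction in (1.0, -1.0):
            for s in offsets:
                q = p + direction * s * nrm
                px = int(np.floor(q[0] + 0.5))
                py = int(np.floor(q[1] + 0.5))
                if not (0 <= py < H and 0 <= px < W) or not roi[py, px]:
                    break
                key = (py, px)
                if key in visited:
                    continue
                visited.add(key)
                if excluded is not None and excluded[py, px]:
                    continue
                if _qualifies(fluor[py, px], threshold, strict_greater):
                    f += 1
        counts[i] = f
    fmax = counts.max()
    rho = counts / fmax if (normalize and fmax > 0) else counts
    return DensityProfile(x=rax.arc_positions, rho=rho,
                          timepoint=scene.timepoint, L=float(rax.arc_positions[-1]))


def _qualifies(value: float, threshold: float, strict: bool) -> bool:
    return value > threshold if strict else value >= threshold


def rereference_to_landmark(profile: DensityProfile, landmarks: dict[str, float],
                            landmark: str = "amputation_plane") -> DensityProfile:
    """Shift profile positions so x = 0 sits at the named landmark.

    Landmarks are arc-length positions in μm on the same axis as the
    profile.  The shift is logged; positions proximal to the landmark
    become negative.
    """
    if landmark not in landmarks:
        raise KeyError(f"landmark {landmark!r} not present")
    shift = landmarks[landmark]
    logger.info("re-referencing profile: x=0 moved to landmark %r at %.1f μm",
                landmark, shift)
    return replace(profile, x=profile.x - shift, rho=profile.rho.copy())
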