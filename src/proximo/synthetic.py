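"""Synthetic data with known ground truth.

Two generators make every downstream stage testable without any
experimental download:

* :func:`make_profile_series` — noisy density-profile time series from
  the RDA forward model: a distal Gaussian initial condition at the
  first timepoint, evolved under known parameters on the exponentially
  growing domain, with additive i.i.d. Normal observation noise (clipped
  at zero, since normalized pixel counts cannot be negative).
* :func:`make_limb_scene` — a limb-like image pair (brightfield +
  fluorescence) with cells rendered as above-threshold disks inside a
  curved band around a Bézier PD axis, positions sampled from a given
  density; the true arc-length histogram is returned for comparison.

Determinism: a single master seed; per-timepoint noise streams are
spawned from ``np.random.SeedSequence(seed)`` by index, so adding later
timepoints never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .axis import LimbScene, PDAxis, resample_axis
from .profiles import DensityProfile
from .rda import ModelParams, SimGrid, evolve_nodes

__all__ = ["GroundTruth", "SceneSpec", "make_profile_series",
           "make_limb_scene", "bezier_axis"]

DEFAULT_TIMEPOINTS = (1.0, 6.0, 12.0, 18.0, 24.0)


@dataclass(frozen=True)
class GroundTruth:
    """Known truth behind a synthetic profile series.

    The initial condition is a Gaussian centred at ``ic_mean`` (default
    0.9·L0, the distal electroporation site) with sd ``ic_sd`` (default
    0.05·L0) and area ``ic_area`` = ∫ρ dδ on the unit domain (default:
    chosen so the peak density is 1, matching a max-normalized measured
    profile).  ``noise_sigma`` is the sd of the additive observation
    noise in density units; 0 means noiseless.  ``clip_noise`` controls
    whether noisy densities are clipped at 0 (the default: normalized
    pixel counts cannot be negative); the unclipped variant is the pure
    additive-Normal observation model, under which the Gaussian
    likelihood of the inference stage is exactly specified.
    """

    params: ModelParams
    noise_sigma: float = 0.005
    ic_mean: float | None = None   # μm; default 0.9·L0
    ic_sd: float | None = None     # μm; default 0.05·L0
    ic_area: float | None = None   # ∫ρ dδ; default sets peak to 1
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    seed: int = 0
    clip_noise: bool = True

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        L0 = self.params.L0
        if self.ic_mean is None:
            object.__setattr__(self, "ic_mean", 0.9 * L0)
        if self.ic_sd is None:
            object.__setattr__(self, "ic_sd", 0.05 * L0)
        if self.ic_sd <= 0:
            raise ValueError("ic_sd must be > 0")
        if not 0 <= self.ic_mean <= L0:
            raise ValueError("ic_mean must lie in [0, L0]")
        if self.ic_area is None:
            object.__setattr__(
                self, "ic_area",
                (self.ic_sd / L0) * math.sqrt(2 * math.pi))
        if self.ic_area <= 0:
            raise ValueError("ic_area must be > 0")
        tps = np.asarray(self.timepoints, dtype=float)
        if len(tps) < 1 or np.any(np.diff(tps) <= 0):
            raise ValueError("timepoints must be strictly increasing")

    def ic_nodes(self, grid: SimGrid) -> np.ndarray:
        """Initial Gaussian evaluated at the δ-grid cell centres."""
        delta = grid.delta
        mu = self.ic_mean / self.params.L0
        sd = self.ic_sd / self.params.L0
        return self.ic_area / (sd * math.sqrt(2 * math.pi)) * \
            np.exp(-0.5 * ((delta - mu) / sd) ** 2)


def make_profile_series(gt: GroundTruth, grid: SimGrid | None = None,
                        condition: str = "synthetic", replicate: str = "r1",
                        return_noiseless: bool = False,
                        noise_on_ic: bool = True):
    """Noisy forward-model density profiles at the ground-truth timepoints.

    The Gaussian IC at the first timepoint is evolved under ``gt.params``;
    each output (including the first timepoint, which downstream inference
    uses as its initial condition) receives additive N(0, σ²) noise,
    clipped at 0 when ``gt.clip_noise``.  Profiles are returned on the
    moving lab grid x = δ·L(t).

    ``noise_on_ic=False`` leaves the first-timepoint profile noiseless
    (used by calibration studies where the inference conditions on the IC
    as exact).  With ``return_noiseless=True`` returns
    ``(noisy, noiseless)``.
    """
    grid = grid or SimGrid()
    params = gt.params
    tps = np.asarray(gt.timepoints, dtype=float)
    thetas = tps - tps[0]
    rho0 = gt.ic_nodes(grid)
    states = evolve_nodes(params, rho0, thetas, grid)
    streams = np.random.SeedSequence(gt.seed).spawn(len(tps))
    noisy: list[DensityProfile] = []
    clean: list[DensityProfile] = []
    for j, tp in enumerate(tps):
        L = params.L0 * math.exp(params.a * thetas[j])
        x = grid.delta * L
        mu = states[j]
        clean.append(DensityProfile(x=x, rho=mu, timepoint=tp,
                                    condition=condition, replicate=replicate,
                                    L=L))
        if gt.noise_sigma > 0 and (noise_on_ic or j > 0):
            rng = np.random.default_rng(streams[j])
            y = mu + rng.normal(0.0, gt.noise_sigma, size=mu.shape)
            if gt.clip_noise:
                y = np.clip(y, 0.0, None)
        else:
            y = mu.copy()
        noisy.append(DensityProfile(x=x.copy(), rho=y, timepoint=tp,
                                    condition=condition, replicate=replicate,
                                    L=L))
    if return_noiseless:
        return noisy, clean
    return noisy


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and rendering parameters of a synthetic limb scene."""

    axis_control_points: tuple = ((30.0, 45.0), (100.0, 45.0), (170.0, 45.0))
    limb_half_width: float = 20.0   # px
    cell_count: int = 300
    cell_radius_px: float = 1.5
    background_level: int = 100     # fluorescence background intensity
    pixel_size: float = 1.0         # μm / px

    def __post_init__(self) -> None:
        if len(self.axis_control_points) < 3:
            raise ValueError("need at least 3 axis control points")
        if self.limb_half_width <= self.cell_radius_px:
            raise ValueError("limb_half_width must exceed cell_radius_px")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.cell_count < 0:
            raise ValueError("cell_count must be >= 0")


def bezier_axis(control_points, pixel_size: float = 1.0,
                step_px: float = 1.0) -> PDAxis:
    """Smooth axis through control points, sampled at uniform arc steps.

    Three control points give the interpolating quadratic Bézier (the
    curve passes through all three); more points give a quadratic spline
    through the endpoints with segments guided by the interior points.
    """
    pts = np.asarray(control_points, dtype=float)
    if len(pts) == 3:
        # inner control chosen so the curve passes through the middle point
        q = 2.0 * pts[1] - 0.5 * (pts[0] + pts[2])
        u = np.linspace(0.0, 1.0, 512)[:, None]
        curve = ((1 - u) ** 2 * pts[0] + 2 * u * (1 - u) * q + u**2 * pts[2])
    else:
        # quadratic spline: segments between consecutive midpoints with the
        # interior points as Bézier controls; straight caps at the ends
        mids = 0.5 * (pts[:-1] + pts[1:])
        pieces = [np.linspace(pts[0], mids[0], 32)]
        u = np.linspace(0.0, 1.0, 64)[:, None]
        for i in range(1, len(pts) - 1):
            p0, c, p1 = mids[i - 1], pts[i], mids[i]
            pieces.append((1 - u) ** 2 * p0 + 2 * u * (1 - u) * c + u**2 * p1)
        pieces.append(np.linspace(mids[-1], pts[-1], 32))
        curve = np.vstack(pieces)
    axis = PDAxis(points=curve, pixel_size=pixel_size)
    return resample_axis(axis, step_px * pixel_size)


def make_limb_scene(spec: SceneSpec, density: DensityProfile, seed: int = 0):
    """Render a limb-like scene with cells placed along the axis ∝ density.

    ``density`` is defined on the axis arc length (μm).  Cells are disks
    of radius ``cell_radius_px`` at arc positions sampled from the
    density, offset orthogonally within the band; the fluorescence value
    inside a cell is well above ``background_level``.

    Returns ``(scene, truth_hist, axis)`` where ``truth_hist`` counts the
    sampled cell arc positions per (1 px resampled) axis point —
    the ground truth that :func:`proximo.axis.collapse` should recover.
    """
    rng = np.random.default_rng(seed)
    axis = bezier_axis(spec.axis_control_points, spec.pixel_size)
    pts = axis.points
    n_axis = len(pts)
    # canvas bounds from the axis extent plus the band and a margin
    margin = spec.limb_half_width + spec.cell_radius_px + 3
    xmin, ymin = pts.min(axis=0) - margin
    xmax, ymax = pts.max(axis=0) + margin
    if xmin < 0 or ymin < 0:
        raise ValueError("axis control points leave no room for the band; "
                         "shift them away from the origin")
    H, W = int(np.ceil(ymax)) + 1, int(np.ceil(xmax)) + 1

    yy, xx = np.mgrid[0:H, 0:W]
    # ROI: distance to the (densely sampled) axis within the half-width
    d2 = np.full((H, W), np.inf)
    for p in pts:
        d2 = np.minimum(d2, (xx - p[0]) ** 2 + (yy - p[1]) ** 2)
    roi = d2 <= spec.limb_half_width**2

    brightfield = np.where(roi, 200, 30).astype(np.uint8)
    fluor = np.full((H, W), spec.background_level, dtype=np.uint16)

    # tangents/normals for the orthogonal offsets of the cell centres
    vec = np.gradient(pts, axis=0)
    vec /= np.linalg.norm(vec, axis=1)[:, None]
    normals = np.column_stack([-vec[:, 1], vec[:, 0]])

    weights = density.interp(axis.arc_positions)
    truth_hist = np.zeros(n_axis)
    if spec.cell_count > 0:
        if weights.sum() <= 0:
            raise ValueError("density is zero everywhere on the axis")
        prob = weights / weights.sum()
        idx = rng.choice(n_axis, size=spec.cell_count, p=prob)
        offs = rng.uniform(-(spec.limb_half_width - spec.cell_radius_px),
                           spec.limb_half_width - spec.cell_radius_px,
                           size=spec.cell_count)
        np.add.at(truth_hist, idx, 1)
        r2 = spec.cell_radius_px**2
        for i, off in zip(idx, offs):
            c = pts[i] + off * normals[i]
            x0, x1 = int(c[0] - spec.cell_radius_px) - 1, int(c[0] + spec.cell_radius_px) + 2
            y0, y1 = int(c[1] - spec.cell_radius_px) - 1, int(c[1] + spec.cell_radius_px) + 2
            sub = (xx[y0:y1, x0:x1] - c[0]) ** 2 + (yy[y0:y1, x0:x1] - c[1]) ** 2 <= r2
            patch = fluor[y0:y1, x0:x1]
            patch[sub] = np.maximum(patch[sub], spec.background_level + 1000)

    scene = LimbScene(brightfield=brightfield, fluorescence=fluor,
                      roi_mask=roi, pixel_size=spec.pixel_size)
    return scene, truth_hist, axis
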