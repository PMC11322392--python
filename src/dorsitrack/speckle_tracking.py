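"""ROI speckle tracking: pyramidal Lucas-Kanade points + linear strain fit.

The tracked quantity is the length of a 15 mm region of interest placed
longitudinally to the muscle fibers. A set of measuring points on the ROI
segment is tracked frame to frame with windowed gradient-descent optical
flow (the Lucas-Kanade / Tomasi family), their displacements are projected
onto the ROI axis, and a least-squares fit of a linear strain model
(displacement = translation + strain * position) yields the frame-to-frame
strain increment. ROI length accumulates multiplicatively, so the product
of (1 + increment) over frames is exactly length_n / length_0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ConfigError, FrameSequence

logger = logging.getLogger(__name__)


class TrackingError(RuntimeError):
    """Tracking could not be started or was irrecoverably lost."""


@dataclass(frozen=True)
class TrackingConfig:
    """Tunables of the point tracker and strain fit.

    The study does not report window, pyramid, or robustness settings;
    these defaults are package choices, all overridable. The residual
    threshold is mean squared intensity error per pixel on [0, 1] frames.
    """

    window_halfsize_px: int = 8
    pyramid_levels: int = 3
    max_iterations: int = 30
    convergence_tol_px: float = 0.01
    min_valid_fraction: float = 0.5
    robust_fit: bool = False
    trim_fraction: float = 0.2
    residual_threshold: float = 0.01
    max_invalid_run: int = 25
    min_gradient_det: float = 1e-6

    def __post_init__(self) -> None:
        if self.window_halfsize_px < 2:
            raise ConfigError("window_halfsize_px must be >= 2")
        if not 0 < self.min_valid_fraction <= 1:
            raise ConfigError("min_valid_fraction must be in (0, 1]")
        if self.pyramid_levels < 1:
            raise ConfigError("pyramid_levels must be >= 1")


@dataclass
class RegionOfInterest:
    """A straight measuring segment along a muscle's fiber direction.

    Endpoints are frame-0 coordinates in mm, (row, col) = (axial,
    lateral). ``n_points`` measuring points are evenly spaced from
    ``endpoint_a`` to ``endpoint_b`` inclusive.
    """

    muscle: str
    endpoint_a: tuple[float, float]
    endpoint_b: tuple[float, float]
    n_points: int = 15

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        if self.nominal_length_mm <= 0:
            raise ConfigError("ROI endpoints must be distinct")

    @property
    def nominal_length_mm(self) -> float:
        a = np.asarray(self.endpoint_a, dtype=float)
        b = np.asarray(self.endpoint_b, dtype=float)
        return float(np.linalg.norm(b - a))

    @property
    def points_mm(self) -> np.ndarray:
        """(n_points, 2) evenly spaced points including both endpoints."""
        a = np.asarray(self.endpoint_a, dtype=float)
        b = np.asarray(self.endpoint_b, dtype=float)
        t = np.linspace(0.0, 1.0, self.n_points)[:, None]
        return a + t * (b - a)

    @property
    def axis_unit(self) -> np.ndarray:
        a = np.asarray(self.endpoint_a, dtype=float)
        b = np.asarray(self.endpoint_b, dtype=float)
        return (b - a) / np.linalg.norm(b - a)


def place_roi(sequence: FrameSequence, muscle: str,
              endpoint_a: tuple[float, float], endpoint_b: tuple[float, float],
              n_points: int = 15,
              config: TrackingConfig | None = None) -> RegionOfInterest:
    """Place an ROI in the first frame, checking it sits inside the image
    with enough margin for the tracking window."""
    config = config or TrackingConfig()
    rows, cols = sequence.shape
    sp = sequence.pixel_spacing_mm
    margin_mm = (config.window_halfsize_px * sp[0],
                 config.window_halfsize_px * sp[1])
    for name, p in (("endpoint_a", endpoint_a), ("endpoint_b", endpoint_b)):
        if not (margin_mm[0] <= p[0] <= (rows - 1) * sp[0] - margin_mm[0]
                and margin_mm[1] <= p[1] <= (cols - 1) * sp[1] - margin_mm[1]):
            raise ConfigError(
                f"{name} {p} is outside the frame or too close to the "
                f"border (margin {margin_mm} mm)")
    return RegionOfInterest(muscle, tuple(endpoint_a), tuple(endpoint_b),
                            n_points=n_points)


@dataclass
class TrackedROI:
    """Per-frame tracking result for one ROI.

    ``strain_increments[k]`` (k >= 1) is the fitted frame (k-1) -> k
    increment, so ``lengths_mm[k] = lengths_mm[k-1] * (1 +
    strain_increments[k])``; entry 0 is 0 by convention.
    """

    roi: RegionOfInterest
    points_mm: np.ndarray  # (n_frames, n_points, 2)
    lengths_mm: np.ndarray  # (n_frames,)
    strain_increments: np.ndarray  # (n_frames,)
    residuals: np.ndarray  # (n_frames,) mean SSD per pixel of valid points
    valid: np.ndarray  # (n_frames,) bool
    frame_interval_s: float = 0.02

    @property
    def n_frames(self) -> int:
        return len(self.lengths_mm)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


# --------------------------------------------------------------------------
# pyramidal Lucas-Kanade point stage
# --------------------------------------------------------------------------

def build_pyramid(image: np.ndarray, levels: int) -> list[np.ndarray]:
    """Gaussian pyramid, level 0 = full resolution."""
    pyr = [np.asarray(image, dtype=np.float64)]
    for _ in range(levels - 1):
        blurred = ndimage.gaussian_filter(pyr[-1], 1.0, mode="nearest")
        pyr.append(blurred[::2, ::2])
    return pyr


def _sample_windows(image: np.ndarray, centers: np.ndarray,
                    offsets: np.ndarray) -> np.ndarray:
    """Bilinear window samples around each center; (n_pts, win, win)."""
    coords = centers[:, None, None, :] + offsets  # (n, w, w, 2)
    flat = coords.reshape(-1, 2).T
    vals = ndimage.map_coordinates(image, flat, order=1, mode="nearest")
    return vals.reshape(coords.shape[:3])


def track_pair(frame_k: np.ndarray, frame_k1: np.ndarray,
               points_px: np.ndarray, config: TrackingConfig | None = None):
    """Track points from ``frame_k`` to ``frame_k1``.

    Returns (displacements_px (n, 2), valid (n,), residuals (n,)). A point
    is invalid if its window has (near-)singular gradient structure, the
    iteration diverges out of the image, or the final mean squared
    intensity residual per pixel exceeds the threshold.
    """
    config = config or TrackingConfig()
    points_px = np.atleast_2d(np.asarray(points_px, dtype=np.float64))
    n = len(points_px)
    w = config.window_halfsize_px
    grid = np.arange(-w, w + 1, dtype=np.float64)
    offsets = np.stack(np.meshgrid(grid, grid, indexing="ij"), axis=-1)
    n_win = (2 * w + 1) ** 2

    pyr_k = build_pyramid(frame_k, config.pyramid_levels)
    pyr_k1 = build_pyramid(frame_k1, config.pyramid_levels)

    disp = np.zeros((n, 2))
    valid = np.ones(n, dtype=bool)

    for level in range(config.pyramid_levels - 1, -1, -1):
        scale = 2.0 ** level
        img_k, img_k1 = pyr_k[level], pyr_k1[level]
        centers = points_px / scale
        d = disp / scale

        tmpl = _sample_windows(img_k, centers, offsets)
        gr = _sample_windows(ndimage.sobel(img_k, axis=0, mode="nearest") / 8.0,
                             centers, offsets)
        gc = _sample_windows(ndimage.sobel(img_k, axis=1, mode="nearest") / 8.0,
                             centers, offsets)
        g_rr = np.einsum("nij,nij->n", gr, gr)
        g_cc = np.einsum("nij,nij->n", gc, gc)
        g_rc = np.einsum("nij,nij->n", gr, gc)
        det = g_rr * g_cc - g_rc**2
        ok = det > config.min_gradient_det * n_win**2
        if level == 0:
            # gate texture only at full resolution; coarse levels merely
            # initialize and lose contrast to the pyramid blur
            valid &= ok
        det_safe = np.where(ok, det, 1.0)

        active = valid & ok
        for _ in range(config.max_iterations):
            if not active.any():
                break
            win = _sample_windows(img_k1, centers[active] + d[active],
                                  offsets)
            err = tmpl[active] - win
            b_r = np.einsum("nij,nij->n", gr[active], err)
            b_c = np.einsum("nij,nij->n", gc[active], err)
            da = np.empty((active.sum(), 2))
            da[:, 0] = (g_cc[active] * b_r - g_rc[active] * b_c) / det_safe[active]
            da[:, 1] = (g_rr[active] * b_c - g_rc[active] * b_r) / det_safe[active]
            d[active] += da
            conv = np.abs(da).max(axis=1) < config.convergence_tol_px
            idx = np.flatnonzero(active)
            active[idx[conv]] = False
        # points pushed far outside the image are lost
        rows, cols = img_k1.shape
        pos = centers + d
        inside = ((pos[:, 0] > -w) & (pos[:, 0] < rows - 1 + w)
                  & (pos[:, 1] > -w) & (pos[:, 1] < cols - 1 + w))
        valid &= inside
        disp = d * scale

    # final residual at full resolution
    win = _sample_windows(pyr_k1[0], points_px + disp, offsets)
    tmpl = _sample_windows(pyr_k[0], points_px, offsets)
    residuals = np.mean((tmpl - win) ** 2, axis=(1, 2))
    valid &= residuals < config.residual_threshold
    return disp, valid, residuals


# --------------------------------------------------------------------------
# linear strain fit
# --------------------------------------------------------------------------

def fit_linear_strain(positions, displacements, robust: bool = False,
                      trim_fraction: float = 0.2) -> tuple[float, float]:
    """Least-squares fit of displacement = translation + strain * (x - xbar).

    ``positions`` and ``displacements`` are 1-D along-axis quantities in
    consistent units; the returned slope is the dimensionless
    frame-to-frame strain increment. With ``robust`` on, a single trimmed
    pass drops the ``trim_fraction`` largest absolute residuals and
    refits.
    """
    x = np.asarray(positions, dtype=float)
    u = np.asarray(displacements, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise TrackingError("need >= 2 valid points with distinct positions")

    def ols(x, u):
        xc = x - x.mean()
        slope = float(xc @ u / (xc @ xc))
        return float(u.mean()), slope, x.mean()

    translation, slope, x0 = ols(x, u)
    if robust and len(x) >= 4:
        resid = np.abs(u - (translation + slope * (x - x0)))
        keep = resid.argsort()[: max(2, int(np.ceil(len(x) * (1 - trim_fraction))))]
        if np.ptp(x[keep]) > 0:
            translation, slope, x0 = ols(x[keep], u[keep])
    return translation, slope


# --------------------------------------------------------------------------
# sequence tracking
# --------------------------------------------------------------------------

def track_sequence(sequence: FrameSequence, roi: RegionOfInterest,
                   config: TrackingConfig | None = None) -> TrackedROI:
    """Chain point tracking and strain fitting over the whole video.

    Each step, displacements of valid points are projected on the ROI
    axis, a linear strain model is fitted, all points are advected by the
    *fitted* map (not their raw displacements), and the ROI length is
    updated multiplicatively. On an invalid frame the length is carried
    forward and the frame flagged; a run of invalid frames longer than
    ``max_invalid_run`` raises :class:`TrackingError`.
    """
    config = config or TrackingConfig()
    sp = np.asarray(sequence.pixel_spacing_mm)
    n_frames = sequence.n_frames
    n_pts = roi.n_points
    axis = roi.axis_unit
    normal = np.array([-axis[1], axis[0]])

    pts0 = roi.points_mm
    rows, cols = sequence.shape
    if (pts0 / sp).min() < 0 or (pts0[:, 0] / sp[0]).max() > rows - 1 \
            or (pts0[:, 1] / sp[1]).max() > cols - 1:
        raise TrackingError("ROI points outside the first frame")

    points = np.empty((n_frames, n_pts, 2))
    lengths = np.empty(n_frames)
    increments = np.zeros(n_frames)
    residuals = np.zeros(n_frames)
    valid = np.ones(n_frames, dtype=bool)

    points[0] = pts0
    lengths[0] = roi.nominal_length_mm

    cur = pts0.copy()
    cur_len = roi.nominal_length_mm
    invalid_run = 0
    prev = sequence.frame_as_float(0)
    for k in range(1, n_frames):
        nxt = sequence.frame_as_float(k)
        disp_px, ok, res = track_pair(prev, nxt, cur / sp, config)
        frame_ok = ok.mean() >= config.min_valid_fraction
        if frame_ok:
            disp_mm = disp_px * sp
            x_along = (cur[ok] - pts0[0]) @ axis
            u_along = disp_mm[ok] @ axis
            try:
                translation, inc = fit_linear_strain(
                    x_along, u_along, robust=config.robust_fit,
                    trim_fraction=config.trim_fraction)
            except TrackingError:
                frame_ok = False
        if frame_ok:
            u_lat = float(np.mean(disp_mm[ok] @ normal))
            x_all = (cur - pts0[0]) @ axis
            fitted = translation + inc * (x_all - x_along.mean())
            cur = cur + fitted[:, None] * axis + u_lat * normal
            cur_len = cur_len * (1.0 + inc)
            increments[k] = inc
            residuals[k] = float(res[ok].mean())
            invalid_run = 0
        else:
            valid[k] = False
            residuals[k] = float(res.mean())
            invalid_run += 1
            if invalid_run > config.max_invalid_run:
                raise TrackingError(
                    f"tracking lost: {invalid_run} consecutive invalid "
                    f"frames ending at frame {k} (muscle {roi.muscle})")
            logger.warning("frame %d invalid for ROI %s (%.0f%% points ok)",
                           k, roi.muscle, 100 * ok.mean())
        points[k] = cur
        lengths[k] = cur_len
        prev = nxt

    return TrackedROI(roi=roi, points_mm=points, lengths_mm=lengths,
                      strain_increments=increments, residuals=residuals,
                      valid=valid, frame_interval_s=sequence.frame_interval_s)
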