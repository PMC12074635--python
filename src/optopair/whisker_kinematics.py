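"""Synthetic whisker videos, frame-wise angle tracking, and Z-score / AUC
response scoring.

The generator renders each whisker as an anti-aliased bright line segment
rotating about a fixed pivot on a dark background, at a default 750
frames/s, and returns the ground-truth angles alongside the stack.  The
tracker thresholds each ROI at the Otsu level, skeletonizes, keeps the
largest straight consensus set (RANSAC, 1-px inlier distance) and fits the
line by total least squares; the fitted direction, as an angle in
(-90, 90] degrees, is the whisker angle.

Scoring follows the behavioral convention: per whisker the absolute
angular deviation d(t) = |theta(t) - mu_baseline| is standardized against
the baseline mean and SD of d, whisker Z-traces are averaged, and the
response statistic is AUC = Z * W with Z the mean Z-score over a fixed
window W (200 ms) from light onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from skimage.draw import line_aa
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .opsin_models import Trace
from .spike_analysis import two_sample_t

__all__ = [
    "VideoStack",
    "WhiskerGroundTruth",
    "AngleTrace",
    "AUCResult",
    "AUCRatioResult",
    "generate_whisker_video",
    "default_rois",
    "angle_from_frame",
    "track_angles",
    "zscore_trace",
    "response_auc",
    "auc_ratio_analysis",
    "make_response_angle_fn",
]


class DegenerateBaselineError(ValueError):
    """Baseline variability too small to standardize against."""


@dataclass
class VideoStack:
    """Grayscale 8-bit video: frames (T, H, W), fps."""

    frames: np.ndarray
    fps: float = 750.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit grayscale")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class WhiskerGroundTruth:
    """True per-whisker angle (deg) per frame and pivot pixel coordinates."""

    angles: np.ndarray  # (n_whiskers, T)
    pivots: List[Tuple[int, int]]  # (row, col)


@dataclass
class AngleTrace:
    """Tracked per-whisker angles (deg) per frame; NaN marks missing frames."""

    fps: float
    whisker_ids: List[int]
    angles: np.ndarray  # (n_whiskers, T), NaN = tracking failure
    quality: np.ndarray  # (n_whiskers, T) RMS inlier residual, px

    @property
    def n_frames(self) -> int:
        return self.angles.shape[1]


@dataclass
class AUCResult:
    """Windowed Z-score response statistic: auc = z_mean * window (Z*s)."""

    z_mean: float
    window: float  # s
    auc: float
    wavelength: Optional[float] = None
    trial_id: Optional[str] = None


@dataclass
class AUCRatioResult:
    """Per-animal blue/red AUC ratios with group statistics."""

    ratios: Dict[str, float]
    mean: float
    sem: float
    ttest: Optional[Tuple[float, float, float, bool]] = None


# ---------------------------------------------------------------------------
# synthetic video generation

_DEFAULT_LENGTH = 40.0
_DEFAULT_SPACING = 60


def generate_whisker_video(
    n_whiskers: int = 5,
    angle_fns: Optional[Sequence[Callable[[np.ndarray], np.ndarray]]] = None,
    duration: float = 1.0,
    fps: float = 750.0,
    noise_sd: float = 8.0,
    seed: Optional[int] = None,
    frame_height: int = 56,
    pivot_spacing: int = _DEFAULT_SPACING,
    length: float = _DEFAULT_LENGTH,
    roi_width: int = 56,
) -> Tuple[VideoStack, WhiskerGroundTruth]:
    """Render a stack of frames with line-like whiskers rotating about pivots.

    ``angle_fns`` maps a time array (s) to angles in degrees for each
    whisker (default: constant 55 deg).  Pivots sit along the bottom edge,
    ``pivot_spacing`` px apart; a spacing below the ROI width raises a
    configuration error.  Deterministic for a fixed seed.
    """
    if not (1 <= n_whiskers <= 12):
        raise ValueError("n_whiskers must be in [1, 12]")
    if pivot_spacing < roi_width:
        raise ValueError("pivot spacing smaller than the ROI size")
    if angle_fns is None:
        angle_fns = [lambda t: np.full_like(t, 55.0)] * n_whiskers
    if len(angle_fns) != n_whiskers:
        raise ValueError("need one angle function per whisker")
    n_frames = int(round(duration * fps))
    t = np.arange(n_frames) / fps
    height = frame_height
    width = pivot_spacing * (n_whiskers - 1) + roi_width + 10
    pivots = [(height - 3, 8 + i * pivot_spacing) for i in range(n_whiskers)]
    angles = np.vstack([np.asarray(fn(t), dtype=float) for fn in angle_fns])

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, height, width), dtype=np.uint8)
    for k in range(n_frames):
        img = np.zeros((height, width), dtype=float)
        for w, (pr, pc) in enumerate(pivots):
            a = np.deg2rad(angles[w, k])
            er = int(round(pr - length * np.sin(a)))
            ec = int(round(pc + length * np.cos(a)))
            er = np.clip(er, 0, height - 1)
            ec = np.clip(ec, 0, width - 1)
            rr, cc, val = line_aa(pr, pc, er, ec)
            img[rr, cc] = np.maximum(img[rr, cc], 200.0 * val)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[k] = np.clip(img, 0, 255).astype(np.uint8)
    return (
        VideoStack(frames=frames, fps=fps),
        WhiskerGroundTruth(angles=angles, pivots=pivots),
    )


def default_rois(
    truth: WhiskerGroundTruth,
    frame_shape: Tuple[int, int],
    roi_width: int = 56,
) -> List[Tuple[int, int, int, int]]:
    """One (r0, r1, c0, c1) box per whisker, full height around each pivot."""
    height, width = frame_shape
    rois = []
    for _, pc in truth.pivots:
        c0 = max(pc - 6, 0)
        c1 = min(c0 + roi_width, width)
        rois.append((0, height, c0, c1))
    return rois


# ---------------------------------------------------------------------------
# tracking

_MIN_PIXELS = 10


def _tls_angle(pts: np.ndarray) -> Tuple[float, float]:
    """Total-least-squares line direction of (row, col) points.

    Returns (angle_deg in (-90, 90], rms distance to the fitted line).
    Angle is measured from the column (horizontal) axis, positive when the
    whisker rises toward smaller row indices.
    """
    centered = pts - pts.mean(axis=0)
    # principal direction via SVD of the 2-column point cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    dr, dc = vt[0]
    angle = np.degrees(np.arctan2(-dr, dc))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    # distance of points to the principal line
    normal = vt[1] if vt.shape[0] > 1 else np.array([-dc, dr])
    dists = centered @ normal
    return float(angle), float(np.sqrt(np.mean(dists**2)))


def _ransac_line(pts: np.ndarray, inlier_dist: float = 1.0, n_iter: int = 32) -> np.ndarray:
    """Indices of the largest straight consensus set among the points."""
    n = pts.shape[0]
    if n <= 2:
        return np.arange(n)
    rng = np.random.default_rng(12345)  # deterministic given the same points
    ii = rng.integers(0, n, size=n_iter)
    jj = rng.integers(0, n - 1, size=n_iter)
    jj[jj >= ii] += 1  # distinct second index
    d = pts[jj] - pts[ii]  # (n_iter, 2)
    norm = np.hypot(d[:, 0], d[:, 1])
    keep = norm > 0
    normals = np.empty_like(d)
    normals[keep, 0] = -d[keep, 1] / norm[keep]
    normals[keep, 1] = d[keep, 0] / norm[keep]
    normals[~keep] = 0.0
    # distance of every point to every candidate line: (n, n_iter)
    dist = np.abs(
        (pts[:, None, :] - pts[ii][None, :, :]).transpose(1, 0, 2) @ normals[:, :, None]
    )[:, :, 0]
    counts = (dist <= inlier_dist).sum(axis=1)
    best = int(np.argmax(counts))
    if not keep[best]:
        return np.arange(n)
    return np.nonzero(dist[best] <= inlier_dist)[0]


def angle_from_frame(
    frame: np.ndarray, roi: Tuple[int, int, int, int]
) -> Tuple[float, float]:
    """Whisker angle (deg) within one ROI of one frame.

    Otsu threshold -> skeletonize -> largest straight consensus run ->
    total-least-squares fit.  Returns (angle, rms_residual); (nan, nan)
    flags a tracking failure (fewer than 10 candidate pixels).
    """
    r0, r1, c0, c1 = roi
    crop = np.asarray(frame[r0:r1, c0:c1], dtype=float)
    if crop.size == 0 or crop.max() == crop.min():
        return np.nan, np.nan
    thresh = threshold_otsu(crop)
    binary = crop > thresh
    if binary.sum() < _MIN_PIXELS:
        return np.nan, np.nan
    skel = skeletonize(binary)
    pts = np.column_stack(np.nonzero(skel)).astype(float)
    if pts.shape[0] < _MIN_PIXELS:
        pts = np.column_stack(np.nonzero(binary)).astype(float)
    if pts.shape[0] < _MIN_PIXELS:
        return np.nan, np.nan
    # clean single-line skeletons fit directly; RANSAC only when the cloud
    # is not already collinear (outliers, crossings)
    angle, resid = _tls_angle(pts)
    if resid > 0.75:
        inliers = _ransac_line(pts)
        if inliers.size >= _MIN_PIXELS // 2:
            angle, resid = _tls_angle(pts[inliers])
    return angle, resid


def track_angles(
    stack: VideoStack, rois: Sequence[Tuple[int, int, int, int]]
) -> AngleTrace:
    """Apply :func:`angle_from_frame` to every frame and ROI."""
    n_w = len(rois)
    n_t = stack.n_frames
    angles = np.full((n_w, n_t), np.nan)
    quality = np.full((n_w, n_t), np.nan)
    for k in range(n_t):
        frame = stack.frames[k]
        for w, roi in enumerate(rois):
            angles[w, k], quality[w, k] = angle_from_frame(frame, roi)
    return AngleTrace(
        fps=stack.fps, whisker_ids=list(range(n_w)), angles=angles, quality=quality
    )


# ---------------------------------------------------------------------------
# scoring

_BASELINE_MIN_FRAMES = 50
_SD_EPS = 1e-9


def zscore_trace(
    angle_trace: AngleTrace,
    baseline_window: Tuple[float, float],
    return_per_whisker: bool = False,
):
    """Standardized absolute angular deviation, averaged across whiskers.

    Per whisker: mu = mean baseline angle, d(t) = |theta(t) - mu|, and
    z(t) = (d(t) - mean_base(d)) / sd_base(d) with sample SD (ddof 1).
    Whisker Z-traces are averaged pointwise (ignoring missing frames).
    """
    fps = angle_trace.fps
    b0, b1 = baseline_window
    i0, i1 = int(round(b0 * fps)), int(round(b1 * fps))
    if i1 - i0 < _BASELINE_MIN_FRAMES:
        raise ValueError("baseline window must span at least 50 frames")
    z_all = np.full_like(angle_trace.angles, np.nan)
    for w in range(angle_trace.angles.shape[0]):
        theta = angle_trace.angles[w]
        base = theta[i0:i1]
        base = base[~np.isnan(base)]
        if base.size < _BASELINE_MIN_FRAMES // 2:
            continue
        mu = base.mean()
        d = np.abs(theta - mu)
        d_base = np.abs(base - mu)
        sd = d_base.std(ddof=1)
        if sd <= _SD_EPS:
            raise DegenerateBaselineError("baseline SD is (near) zero")
        z_all[w] = (d - d_base.mean()) / sd
    if np.all(np.isnan(z_all)):
        raise DegenerateBaselineError("no whisker had a usable baseline")
    z_mean = np.nanmean(z_all, axis=0)
    trace = Trace(t0=0.0, dt=1.0 / fps, values=np.nan_to_num(z_mean), units="dimensionless", kind="zscore")
    if return_per_whisker:
        return trace, z_all
    return trace


def response_auc(
    z_trace: Trace,
    onset: float,
    window: float = 200.0,
    wavelength: Optional[float] = None,
    trial_id: Optional[str] = None,
) -> AUCResult:
    """AUC = Z * W: mean Z over [onset, onset + window], times the window (s).

    ``window`` is in ms (default 200, i.e. 150 frames at 750 fps).
    """
    w_s = window * 1e-3
    seg = z_trace.slice(onset, onset + w_s)
    expected = int(round(w_s / z_trace.dt))
    if seg.size < expected:
        raise ValueError("window exceeds trace")
    z_mean = float(np.mean(seg))
    return AUCResult(
        z_mean=z_mean, window=w_s, auc=z_mean * w_s, wavelength=wavelength, trial_id=trial_id
    )


def auc_ratio_analysis(
    per_animal: Mapping[str, Mapping[float, Sequence[float]]],
    comparison: Optional[Mapping[str, Mapping[float, Sequence[float]]]] = None,
    blue_nm: float = 450.0,
    red_nm: float = 638.0,
) -> AUCRatioResult:
    """Per-animal blue/red AUC ratios and group statistics.

    For each animal the trial AUCs at each wavelength are averaged and the
    ratio mean_blue / mean_red computed; group mean and SEM are taken over
    animals.  When ``comparison`` is given, the two groups' ratios are
    compared with a Welch t-test.
    """

    def group_ratios(group: Mapping[str, Mapping[float, Sequence[float]]]) -> Dict[str, float]:
        ratios = {}
        for animal, per_wl in group.items():
            red_mean = float(np.mean(per_wl[red_nm]))
            if red_mean == 0:
                raise ZeroDivisionError(f"animal {animal!r} has zero red-light AUC")
            ratios[animal] = float(np.mean(per_wl[blue_nm])) / red_mean
        return ratios

    ratios = group_ratios(per_animal)
    vals = np.array(list(ratios.values()))
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    ttest = None
    if comparison is not None:
        other = np.array(list(group_ratios(comparison).values()))
        ttest = two_sample_t(vals, other)
    return AUCRatioResult(ratios=ratios, mean=mean, sem=sem, ttest=ttest)


def make_response_angle_fn(
    base_angle: float = 55.0,
    amplitude: float = 15.0,
    onsets: Sequence[float] = (0.5,),
    rise_ms: float = 20.0,
    decay_ms: float = 150.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Angle trajectory with protraction responses to light events.

    Each onset triggers a deflection amplitude * (1 - e^{-t/rise}) *
    e^{-t/decay}; amplitude 0 models a non-responding (suppressed) trial.
    """

    def fn(t: np.ndarray) -> np.ndarray:
        theta = np.full_like(t, base_angle, dtype=float)
        for on in onsets:
            dt_s = t - on
            mask = dt_s > 0
            x = dt_s[mask]
            theta[mask] += (
                amplitude
                * (1 - np.exp(-x / (rise_ms * 1e-3)))
                * np.exp(-x / (decay_ms * 1e-3))
            )
        return theta

    return fn
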