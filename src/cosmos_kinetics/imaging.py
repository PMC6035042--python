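"""Image-level layer: synthetic TIRF movies and spot-based event recovery.

A forward model renders simulated panels as two-channel image stacks
(symmetric Gaussian PSF, Poisson shot noise, Gaussian read noise, bright
persistent fiducial beads, optional stage drift), and an inverse pipeline
recovers per-location presence traces by matched-filter spot detection,
fiducial-based drift correction, affine channel registration, and
radius-based colocalization with the known RNA locations.

Coordinates are 0-based with the pixel-center convention: position (x, y)
means column x, row y, and integer coordinates sit at pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .acquisition import AcquisitionSchedule
from .simulate import PanelData, PresenceTrace, SlideLayout

__all__ = [
    "ImageStack",
    "Spot",
    "DriftTrajectory",
    "ChannelMapping",
    "render_image_stack",
    "detect_spots",
    "estimate_drift",
    "fit_channel_mapping",
    "colocalize_locations",
    "recover_presence_traces",
]


@dataclass
class ImageStack:
    """A stack of single-channel frames with physical calibration."""

    frames: np.ndarray  # (n_frames, h, w) photon counts
    channel: str  # "green" | "red"
    frame_times: np.ndarray  # s
    pixel_size: float  # µm per pixel
    fiducials: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        if (self.frames < 0).any():
            raise ValueError("photon counts must be non-negative")
        if self.frames.shape[0] != self.frame_times.size:
            raise ValueError("frame count must match frame_times")


@dataclass(frozen=True)
class Spot:
    """A detected fluorescent spot at sub-pixel resolution."""

    x: float
    y: float
    amplitude: float
    background: float
    frame: int


@dataclass
class DriftTrajectory:
    """Per-frame stage offset in pixels, zero at the reference frame."""

    offsets: np.ndarray  # (n_frames, 2) as (dx, dy)
    reference_frame: int = 0

    def __post_init__(self) -> None:
        ref = self.offsets[self.reference_frame]
        if not np.allclose(ref, 0.0, atol=1e-9):
            raise ValueError("offset at the reference frame must be (0, 0)")


@dataclass
class ChannelMapping:
    """Affine map from green- to red-channel coordinates."""

    matrix: np.ndarray  # 2x2
    offset: np.ndarray  # 2
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("channel mapping must be invertible")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.matrix.T + self.offset

    def inverse(self) -> "ChannelMapping":
        inv = np.linalg.inv(self.matrix)
        return ChannelMapping(inv, -inv @ self.offset, self.residual_rms)


# ---------------------------------------------------------------------------
# forward model


def _add_gaussian_spot(img, x, y, amplitude, sigma):
    """Accumulate a 2-D Gaussian of unit-integral `amplitude` photons."""
    h, w = img.shape
    r = max(int(np.ceil(4 * sigma)), 2)
    x0, y0 = int(round(x)), int(round(y))
    xs = np.arange(max(0, x0 - r), min(w, x0 + r + 1))
    ys = np.arange(max(0, y0 - r), min(h, y0 + r + 1))
    if xs.size == 0 or ys.size == 0:
        return
    gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
    patch = amplitude / (2 * np.pi * sigma**2) * np.outer(gy, gx)
    img[np.ix_(ys, xs)] += patch


def render_image_stack(
    panel: PanelData,
    psf_sigma: float = 1.0,
    pixel_size: float = 0.16,
    amplitude: float = 400.0,
    background: float = 20.0,
    read_noise: float = 2.0,
    n_fiducials: int = 3,
    fiducial_amplitude: float = 4000.0,
    fiducial_clearance: float = 10.0,
    drift_per_frame: tuple[float, float] = (0.0, 0.0),
    shot_noise: bool = True,
    seed: int = 0,
) -> ImageStack:
    """Render the green channel of a simulated panel as an image stack.

    Every location whose presence trace is on in a frame contributes a
    symmetric Gaussian spot of ``amplitude`` photons; fiducial beads are
    rendered bright and persistent in every frame; the whole field
    translates by ``drift_per_frame`` pixels per frame.  Red-interleave
    frames are rendered as pure background (no green excitation).
    """
    sched = panel.schedule
    nf = sched.n_frames
    fx, fy = panel.layout.field_size
    w = int(np.ceil(fx / pixel_size))
    h = int(np.ceil(fy / pixel_size))
    rng = np.random.default_rng(seed)
    positions = {
        lid: (x / pixel_size, y / pixel_size)
        for lid, _, x, y in panel.layout.locations
    }
    # beads are deposited sparsely; keep them clear of tethered molecules so
    # their bright PSF tails do not mask dim binding spots
    loc_xy = np.array(list(positions.values())) if positions else np.empty((0, 2))
    fiducials = np.empty((n_fiducials, 2))
    placed = 0
    while placed < n_fiducials:
        cand = rng.random(2) * [w - 1, h - 1]
        if loc_xy.size and np.hypot(*(loc_xy - cand).T).min() < fiducial_clearance:
            continue
        fiducials[placed] = cand
        placed += 1
    missing = sched.red_frame_mask()
    frames = np.empty((nf, h, w))
    drift = np.asarray(drift_per_frame, dtype=float)
    for f in range(nf):
        img = np.full((h, w), float(background))
        off = drift * f
        if not missing[f]:
            for lid, tr in panel.traces.items():
                if tr.present[f]:
                    px, py = positions[lid]
                    _add_gaussian_spot(
                        img, px + off[0], py + off[1], amplitude, psf_sigma
                    )
            for bx, by in fiducials:
                _add_gaussian_spot(
                    img, bx + off[0], by + off[1], fiducial_amplitude, psf_sigma
                )
        if shot_noise:
            img = rng.poisson(img).astype(float)
        if read_noise > 0:
            img = img + rng.normal(0.0, read_noise, img.shape)
        frames[f] = np.clip(img, 0.0, None)
    return ImageStack(
        frames, "green", sched.frame_start_times(), pixel_size, fiducials
    )


# ---------------------------------------------------------------------------
# detection


def detect_spots(
    image: np.ndarray,
    threshold: float,
    psf_sigma: float = 1.0,
    min_distance: int = 3,
) -> list[Spot]:
    """Matched-filter local-maxima spot detection with centroid refinement.

    The image is convolved with a Gaussian kernel matched to the PSF after
    background subtraction (median), local maxima above ``threshold`` are
    kept, and each is refined to sub-pixel precision by an
    intensity-weighted centroid over a small neighborhood.
    """
    img = np.asarray(image, dtype=float)
    bg = float(np.median(img))
    filtered = ndimage.gaussian_filter(img - bg, psf_sigma)
    peaks = peak_local_max(
        filtered, min_distance=min_distance, threshold_abs=threshold
    )
    spots: list[Spot] = []
    h, w = img.shape
    r = max(int(np.ceil(2 * psf_sigma)), 1)
    for py, px in peaks:
        ys = slice(max(0, py - r), min(h, py + r + 1))
        xs = slice(max(0, px - r), min(w, px + r + 1))
        patch = img[ys, xs] - bg
        patch = np.clip(patch, 0.0, None)
        total = patch.sum()
        if total <= 0:
            continue
        yy, xx = np.mgrid[ys, xs]
        cx = float((patch * xx).sum() / total)
        cy = float((patch * yy).sum() / total)
        spots.append(Spot(cx, cy, float(filtered[py, px]), bg, frame=-1))
    return spots


def sliding_window_frames(
    stack: ImageStack, window: int = 5, missing: np.ndarray | None = None
) -> np.ndarray:
    """Average frames with a centered sliding window, skipping missing ones."""
    frames = stack.frames
    nf = frames.shape[0]
    if missing is None:
        missing = np.zeros(nf, dtype=bool)
    half = window // 2
    out = np.empty_like(frames)
    for f in range(nf):
        lo, hi = max(0, f - half), min(nf, f + half + 1)
        sel = [i for i in range(lo, hi) if not missing[i]]
        out[f] = frames[sel].mean(axis=0) if sel else frames[f]
    return out


# ---------------------------------------------------------------------------
# drift and registration


def estimate_drift(
    fiducial_tracks: np.ndarray, reference_frame: int = 0
) -> DriftTrajectory:
    """Mean fiducial displacement per frame relative to the reference frame.

    ``fiducial_tracks`` has shape (n_fiducials, n_frames, 2) and may contain
    NaN where a fiducial was not tracked; gaps are linearly interpolated.
    At least one fiducial must be tracked in >= 90% of frames.
    """
    tracks = np.asarray(fiducial_tracks, dtype=float)
    if tracks.ndim != 3 or tracks.shape[0] == 0:
        raise ValueError("need at least one fiducial track")
    n_frames = tracks.shape[1]
    valid = ~np.isnan(tracks[..., 0])
    if not (valid.mean(axis=1) >= 0.9).any():
        raise ValueError("no fiducial tracked in >= 90% of frames")
    disp = tracks - tracks[:, [reference_frame], :]
    with np.errstate(invalid="ignore"):
        mean_disp = np.nanmean(disp, axis=0)
    # interpolate frames with no fiducial at all
    for d in range(2):
        col = mean_disp[:, d]
        bad = np.isnan(col)
        if bad.any():
            good = np.flatnonzero(~bad)
            col[bad] = np.interp(np.flatnonzero(bad), good, col[good])
    mean_disp[reference_frame] = 0.0
    return DriftTrajectory(mean_disp, reference_frame)


def fit_channel_mapping(
    green_points: np.ndarray, red_points: np.ndarray
) -> ChannelMapping:
    """Least-squares affine registration between the two channels.

    Needs at least three non-collinear bead pairs; returns the transform
    and the RMS residual of the fit.
    """
    g = np.atleast_2d(np.asarray(green_points, dtype=float))
    r = np.atleast_2d(np.asarray(red_points, dtype=float))
    if g.shape != r.shape or g.shape[0] < 3:
        raise ValueError("need >= 3 matched bead pairs")
    centered = g - g.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("bead positions are collinear; affine fit is degenerate")
    design = np.hstack([g, np.ones((g.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    resid = design @ coef - r
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return ChannelMapping(matrix, offset, rms)


# ---------------------------------------------------------------------------
# colocalization


def colocalize_locations(
    spots_per_frame: list[list[Spot]],
    locations: np.ndarray,
    radius: float,
    drift: DriftTrajectory | None = None,
) -> np.ndarray:
    """Assign detected spots to reference locations frame by frame.

    A location is bound in a frame iff at least one (drift-corrected) spot
    lies within ``radius`` pixels; when several locations compete for one
    spot the nearest wins.  Returns a (n_locations, n_frames) boolean
    matrix.
    """
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    nf = len(spots_per_frame)
    bound = np.zeros((locs.shape[0], nf), dtype=bool)
    tree = cKDTree(locs)
    for f, spots in enumerate(spots_per_frame):
        if not spots:
            continue
        pts = np.array([[s.x, s.y] for s in spots])
        if drift is not None:
            pts = pts - drift.offsets[f]
        dists, idx = tree.query(pts, k=1)
        for d, i in zip(dists, idx):
            if d <= radius:
                bound[i, f] = True
    return bound


def recover_presence_traces(
    stack: ImageStack,
    layout: SlideLayout,
    schedule: AcquisitionSchedule,
    threshold: float,
    psf_sigma: float = 1.0,
    radius: float | None = None,
    average_window: int = 5,
    drift: DriftTrajectory | None = None,
) -> dict[str, PresenceTrace]:
    """Full inverse pipeline: images -> spots -> per-location presence.

    Frames are sliding-window averaged before detection (the standard
    noise-suppression step for dim single-molecule spots); the
    colocalization radius defaults to 1.5 PSF sigma.
    """
    if radius is None:
        radius = 1.5 * psf_sigma
    missing = schedule.red_frame_mask()
    averaged = sliding_window_frames(stack, average_window, missing)
    spots_per_frame: list[list[Spot]] = []
    for f in range(schedule.n_frames):
        if missing[f]:
            spots_per_frame.append([])
        else:
            spots_per_frame.append(
                detect_spots(averaged[f], threshold, psf_sigma)
            )
    locs_px = layout.positions() / stack.pixel_size
    bound = colocalize_locations(spots_per_frame, locs_px, radius, drift)
    traces = {}
    for i, (lid, _, _, _) in enumerate(layout.locations):
        present = bound[i] & ~missing
        traces[lid] = PresenceTrace(lid, present, missing.copy(), schedule)
    return traces
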