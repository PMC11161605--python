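"""High-speed videolaryngoscopy pre-processing.

Endoscopic high-speed video needs three steps before glottal kinematics
can be measured: (1) removal of the periodic "honeycomb" artifact that
fiber-optic image guides imprint on the frames, done with a
frequency-selective 2-D FFT filter; (2) rotation of every frame so the
glottal main axis is vertical, with the angle estimated from
time-difference images (the glottis is the fastest-moving structure in
the scene); (3) cropping to a bounding box around the glottis.

Conventions: angles are in degrees, counterclockwise-positive, measured
from the vertical image axis.  Whether the top or bottom image edge is
posterior is *not* assumed; downstream analysis requires an explicit
declaration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

logger = logging.getLogger(__name__)

__all__ = [
    "HSVSequence",
    "AngleTrack",
    "remove_honeycomb",
    "estimate_glottis_angle",
    "rotate_align",
    "crop",
]


@dataclass
class HSVSequence:
    """A grayscale frame stack with its frame rate and labels."""

    frames: np.ndarray  # (n_frames, height, width), float intensities
    fps: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) stack")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def pixel_dims(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class AngleTrack:
    """Glottal main-axis angle at keyframes, degrees CCW from vertical."""

    frame_index: np.ndarray
    angle: np.ndarray  # degrees in (-90, 90]
    smoothed: bool = False

    def at(self, frames: np.ndarray) -> np.ndarray:
        """Angle linearly interpolated at arbitrary frame indices."""
        return np.interp(frames, self.frame_index, self.angle)


def _conjugate_mirror(mask: np.ndarray) -> np.ndarray:
    """Mirror an fftshifted-spectrum mask through the center frequency."""
    h, w = mask.shape
    out = mask[::-1, ::-1]
    # for even dimensions the center bin sits at index n//2, so the point
    # reflection needs a one-pixel roll to land on conjugate partners
    if h % 2 == 0:
        out = np.roll(out, 1, axis=0)
    if w % 2 == 0:
        out = np.roll(out, 1, axis=1)
    return out


def _remove_peaks_one(
    frame: np.ndarray,
    peak_threshold: float,
    protect_radius: int,
    dilation_radius: int,
    n_regions: int,
) -> tuple[np.ndarray, bool]:
    """FFT-filter one frame; returns (filtered, any_peaks_removed)."""
    h, w = frame.shape
    spec = np.fft.fftshift(np.fft.fft2(frame))
    logmag = np.log(np.abs(spec) + 1e-12)

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h // 2, w // 2
    protected = (yy - cy) ** 2 + (xx - cx) ** 2 <= protect_radius**2

    off = ~protected
    mu, sd = logmag[off].mean(), logmag[off].std()
    if sd == 0:
        return frame, False
    candidates = (logmag > mu + peak_threshold * sd) & off
    # real images have conjugate-symmetric spectra: enforce on the mask
    candidates |= _conjugate_mirror(candidates)
    candidates &= off

    labels = measure.label(candidates)
    if labels.max() < 2:
        return frame, False
    # rank peak regions by their strongest spectral magnitude
    strengths = ndimage.maximum(logmag, labels,
                                index=np.arange(1, labels.max() + 1))
    keep = np.argsort(strengths)[::-1][:n_regions] + 1
    mask = np.isin(labels, keep)
    mask = morphology.dilation(mask, morphology.disk(dilation_radius))
    mask &= off

    spec[mask] = 0.0
    out = np.real(np.fft.ifft2(np.fft.ifftshift(spec)))
    return np.clip(out, frame.min(), frame.max()), True


def remove_honeycomb(
    seq: HSVSequence,
    peak_threshold: float = 4.0,
    protect_radius: int = 8,
    dilation_radius: int = 2,
    n_regions: int = 2,
) -> HSVSequence:
    """Remove the fiber-optic honeycomb artifact with a 2-D FFT filter.

    Per frame, the log-magnitude spectrum is binarized at
    ``mean + peak_threshold * std`` (excluding a protected low-frequency
    disc of ``protect_radius`` px around the origin, which holds the
    scene).  The ``n_regions`` strongest off-center peak regions — for a
    single dominant periodic artifact, the conjugate-symmetric pair —
    are slightly enlarged by morphological dilation, zeroed, and the
    frame reconstructed by the inverse transform, clipped to the input
    intensity range.

    Frames with fewer than two off-center peak regions above threshold
    are passed through unchanged (with a logged notice).
    """
    if seq.n_frames == 0:
        raise ValueError("empty sequence")
    out = np.empty_like(seq.frames)
    n_skipped = 0
    for t in range(seq.n_frames):
        out[t], removed = _remove_peaks_one(
            seq.frames[t], peak_threshold, protect_radius,
            dilation_radius, n_regions,
        )
        n_skipped += not removed
    if n_skipped:
        logger.info(
            "remove_honeycomb: %d/%d frames had <2 off-center spectral "
            "peaks and were passed through unchanged", n_skipped, seq.n_frames,
        )
    return HSVSequence(out, seq.fps, dict(seq.metadata))


def estimate_glottis_angle(
    seq: HSVSequence,
    frame_offset: int = 5,
    keyframe_stride: int = 10,
    min_area: int = 20,
    median_window: int = 5,
) -> AngleTrack:
    """Estimate the glottal main-axis angle from time-difference images.

    The glottis is assumed to be the fastest-moving object in the scene:
    at each keyframe the absolute difference to the frame
    ``frame_offset`` later is binarized (Otsu), cleaned by morphological
    opening, and the largest connected component's ellipse-equivalent
    major-axis orientation is taken as the glottal angle.  Keyframes
    without a component above ``min_area`` px are interpolated from
    neighbours, and the track is median-filtered to suppress sudden
    improbable jumps.

    Raises
    ------
    ValueError
        If no keyframe yields a usable component (e.g. a static scene).
    """
    if seq.n_frames <= frame_offset:
        raise ValueError("sequence shorter than the difference offset")
    from skimage.filters import threshold_otsu

    keyframes = np.arange(0, seq.n_frames - frame_offset, keyframe_stride)
    angles = np.full(keyframes.size, np.nan)
    for idx, t in enumerate(keyframes):
        diff = np.abs(seq.frames[t + frame_offset] - seq.frames[t])
        if diff.max() <= 0:
            continue
        try:
            thr = threshold_otsu(diff)
        except ValueError:
            continue
        binary = morphology.opening(diff > thr, morphology.disk(1))
        labels = measure.label(binary)
        if labels.max() == 0:
            continue
        props = measure.regionprops(labels)
        largest = max(props, key=lambda p: p.area)
        if largest.area < min_area:
            continue
        # regionprops orientation: angle of the major axis versus the row
        # axis; negating gives degrees CCW from the vertical display axis
        angles[idx] = -np.degrees(largest.orientation)
    valid = ~np.isnan(angles)
    if not valid.any():
        raise ValueError(
            "no moving component found at any keyframe; cannot estimate "
            "glottal angle on a static sequence"
        )
    angles = np.interp(np.arange(keyframes.size),
                       np.flatnonzero(valid), angles[valid])
    if valid.sum() >= median_window:
        angles = ndimage.median_filter(angles, size=median_window,
                                       mode="nearest")
    return AngleTrack(frame_index=keyframes, angle=angles, smoothed=True)


def rotate_align(seq: HSVSequence, track: AngleTrack) -> HSVSequence:
    """Rotate every frame by minus its track angle about the image center.

    Bilinear interpolation; output dimensions preserved; pixels rotated
    in from outside the frame are zero-filled.
    """
    angles = track.at(np.arange(seq.n_frames))
    out = np.empty_like(seq.frames)
    for t in range(seq.n_frames):
        if angles[t] == 0.0:
            out[t] = seq.frames[t]
        else:
            # inverse of a display-CCW tilt by `angle` degrees
            out[t] = ndimage.rotate(
                seq.frames[t], angles[t], reshape=False, order=1,
                mode="constant", cval=0.0,
            )
    return HSVSequence(out, seq.fps, dict(seq.metadata))


def crop(
    seq: HSVSequence,
    bbox: tuple[int, int, int, int] | dict[int, tuple[int, int, int, int]],
) -> HSVSequence:
    """Crop all frames to a (possibly keyframed) glottis bounding box.

    ``bbox`` is ``(col, row, width, height)``, either one box for the
    whole sequence or a ``{frame: box}`` mapping at keyframes, linearly
    interpolated in between (box centers and sizes interpolate
    separately).  The output stack uses the largest interpolated box
    size so every frame has identical dimensions, with the box center
    kept at the crop center and zero padding where the box leaves the
    frame after rounding.
    """
    h, w = seq.pixel_dims
    if isinstance(bbox, dict):
        if not bbox:
            raise ValueError("empty bbox mapping")
        items = sorted(bbox.items())
        kf = np.array([k for k, _ in items], dtype=float)
        boxes = np.array([b for _, b in items], dtype=float)
    else:
        kf = np.array([0.0])
        boxes = np.array([bbox], dtype=float)
    for x, y, bw, bh in boxes:
        if bw < 1 or bh < 1 or x < 0 or y < 0 or x + bw > w or y + bh > h:
            raise ValueError(f"bbox {(x, y, bw, bh)} outside {w}x{h} frame")

    t_all = np.arange(seq.n_frames, dtype=float)
    cx = np.interp(t_all, kf, boxes[:, 0] + boxes[:, 2] / 2.0)
    cy = np.interp(t_all, kf, boxes[:, 1] + boxes[:, 3] / 2.0)
    out_w = int(np.ceil(boxes[:, 2].max()))
    out_h = int(np.ceil(boxes[:, 3].max()))

    out = np.zeros((seq.n_frames, out_h, out_w), dtype=seq.frames.dtype)
    for t in range(seq.n_frames):
        x0 = int(round(cx[t] - out_w / 2.0))
        y0 = int(round(cy[t] - out_h / 2.0))
        sx0, sy0 = max(0, x0), max(0, y0)
        sx1, sy1 = min(w, x0 + out_w), min(h, y0 + out_h)
        out[t, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = \
            seq.frames[t, sy0:sy1, sx0:sx1]
    return HSVSequence(out, seq.fps, dict(seq.metadata))
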