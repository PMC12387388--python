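"""Video loading and physical pixel calibration.

Echocardiography workstations export AVI videos whose only record of
physical scale is burnt into the pixels: Philips consoles draw a ruler
of evenly spaced green dots, GE consoles draw a scale line of known
length in the lower-right corner.  This module reads frames into RGB
arrays and turns those markers into cm-per-pixel factors, which the
planimetry stage multiplies into areas (cm²) and perimeters (cm).

Frames are plain ``numpy`` arrays, shape ``(h, w, 3)``, dtype ``uint8``,
channel order RGB everywhere in memory; decoder output that is natively
BGR is converted at the file boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

from ._avi import read_avi
from .errors import CalibrationError, ValidationError, VideoIOError

Frame = np.ndarray  # (h, w, 3) uint8, RGB

VendorDialect = Literal["philips", "ge", "explicit"]


@dataclass(frozen=True)
class PixelCalibration:
    """Physical size of one pixel.

    ``pixel_area_cm2`` is always the exact product of the two linear
    factors, so pixel counts convert to cm² without a second rounding.
    """

    cm_per_px_x: float
    cm_per_px_y: float
    pixel_area_cm2: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.cm_per_px_x > 0 and self.cm_per_px_y > 0):
            raise ValidationError("calibration factors must be positive")
        object.__setattr__(
            self, "pixel_area_cm2", self.cm_per_px_x * self.cm_per_px_y
        )

    def scaled(self, k: float) -> "PixelCalibration":
        return PixelCalibration(self.cm_per_px_x * k, self.cm_per_px_y * k)


@dataclass
class FrameSequence:
    """Ordered frames of one video; all frames share one shape."""

    frames: list[Frame]
    source_path: str = "<memory>"
    vendor_dialect: VendorDialect = "explicit"

    def __post_init__(self) -> None:
        if not self.frames:
            raise VideoIOError(f"{self.source_path}: empty frame sequence")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValidationError("all frames must share identical dimensions")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape[:2]


def extract_frames(
    video_path: str | Path, vendor_dialect: VendorDialect = "explicit"
) -> FrameSequence:
    """Decode every frame of an AVI video, in display order, as RGB.

    Raises :class:`VideoIOError` for unreadable files and for videos
    with no decodable frames.
    """
    stack = read_avi(video_path)
    return FrameSequence(
        frames=list(stack), source_path=str(video_path), vendor_dialect=vendor_dialect
    )


def explicit_calibration(cm_per_px_x: float, cm_per_px_y: float) -> PixelCalibration:
    """Build a calibration from user-supplied factors (no on-screen markers)."""
    return PixelCalibration(cm_per_px_x, cm_per_px_y)


def calibrate_philips(
    frame: Frame,
    marker_spacing_cm: float = 1.0,
    green_margin: int = 60,
    min_blob_px: int = 4,
) -> PixelCalibration:
    """Calibrate from the Philips ruler of green dots.

    A pixel counts as "green" when G ≥ 100 and G exceeds both R and B by
    ``green_margin``.  Green pixels are grouped into 8-connected blobs;
    blobs below ``min_blob_px`` pixels are discarded as speckle.  The
    centroid spacing of consecutive blobs along the ruler axis, together
    with the configured physical spacing, gives cm/px.  The orthogonal
    factor is set equal (square pixels) because the ruler constrains
    only one axis.
    """
    frame = np.asarray(frame)
    r = frame[:, :, 0].astype(np.int16)
    g = frame[:, :, 1].astype(np.int16)
    b = frame[:, :, 2].astype(np.int16)
    mask = (g >= 100) & (g - r >= green_margin) & (g - b >= green_margin)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(mask, labels, range(1, n + 1))
    keep = [i + 1 for i, s in enumerate(sizes) if s >= min_blob_px]
    if len(keep) < 2:
        raise CalibrationError(
            f"found {len(keep)} green marker blob(s); need at least 2 for the ruler"
        )
    centroids = np.array(ndimage.center_of_mass(mask, labels, keep))
    # sort along the axis the ruler runs on (largest centroid spread)
    axis = int(np.argmax(np.ptp(centroids, axis=0)))
    centroids = centroids[np.argsort(centroids[:, axis])]
    gaps = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    spacing_px = float(np.median(gaps))
    if spacing_px <= 0:
        raise CalibrationError("green marker blobs coincide")
    cm_per_px = marker_spacing_cm / spacing_px
    return PixelCalibration(cm_per_px, cm_per_px)


def calibrate_ge(
    frame: Frame,
    region: tuple[int, int, int, int] | None = None,
    line_length_cm: float = 1.0,
    brightness: int = 200,
) -> PixelCalibration:
    """Calibrate from the GE scale line.

    ``region`` is (row0, row1, col0, col1) in pixel coordinates; by
    default the lower-right quadrant of the frame is searched.  The
    longest bright horizontal run inside the region is taken as the
    scale line; its pixel length divides the configured physical length.
    The vertical factor is set equal — the pixel is assumed square.
    """
    frame = np.asarray(frame)
    h, w = frame.shape[:2]
    if region is None:
        region = (h // 2, h, w // 2, w)
    r0, r1, c0, c1 = region
    crop = frame[r0:r1, c0:c1]
    if crop.size == 0:
        raise CalibrationError("empty scale-line search region")
    bright = np.all(crop >= brightness, axis=2)
    labels, n = ndimage.label(bright, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise CalibrationError("no scale line found in region")
    slices = ndimage.find_objects(labels)
    length_px = max(s[1].stop - s[1].start for s in slices if s is not None)
    if length_px < 2:
        raise CalibrationError("detected bright blob is too short to be a scale line")
    cm_per_px = line_length_cm / length_px
    return PixelCalibration(cm_per_px, cm_per_px)


def step_length_cm(dy: int, dx: int, calibration: PixelCalibration) -> float:
    """Physical length of one pixel step, scaling each axis separately."""
    return math.hypot(dx * calibration.cm_per_px_x, dy * calibration.cm_per_px_y)
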