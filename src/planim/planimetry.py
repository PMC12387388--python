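"""Planimetry of the mitral valve orifice.

The measurement chain is deliberately simple digital image processing:

1. each RGB frame is converted to grayscale with the luminance weights
   ``0.2989 R + 0.5870 G + 0.1140 B``;
2. a single-band fixed threshold maps the gray frame to binary — a bit
   is 1 iff the intensity *strictly* exceeds the threshold;
3. in the binary frame, bright pixels are tissue and dark pixels are
   either background (touching the image border) or the valve orifice
   (a dark region fully enclosed by tissue).  The largest enclosed dark
   region is taken as the orifice; its pixel count times the pixel area
   gives the opening area in cm².

Because no single gray threshold suits every video, thresholds 10..30
are scanned.  At each threshold the frame with the largest opening is
kept; the scan stops when the contour perimeter between consecutive
thresholds jumps by more than 1.0 cm — the contour has "leaked" — and
the penultimate threshold is selected, or at the cap of 30 otherwise.
The selected record's area is the maximum mitral valve area (MVA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage import measure

from .errors import ValidationError
from .video_io import Frame, FrameSequence, PixelCalibration

GrayFrame = np.ndarray  # (h, w) uint8
BinaryMask = np.ndarray  # (h, w) uint8 in {0, 1}

#: Luminance weights for R, G, B.  Green dominates; the luminance model
#: tracks display brightness rather than human color sensitivity.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)

StopReason = Literal["perimeter_jump", "threshold_cap"]


@dataclass(frozen=True)
class OrificeContour:
    """Closed boundary of a detected valve opening, in physical units."""

    boundary: np.ndarray  # (k, 2) int pixel coordinates (row, col), closed path
    interior_pixel_count: int
    area_cm2: float
    perimeter_cm: float


@dataclass(frozen=True)
class ScanRecord:
    """Best frame found at one threshold."""

    threshold: int
    best_frame_index: int
    area_cm2: float
    perimeter_cm: float
    contour: OrificeContour | None = None


@dataclass(frozen=True)
class ScanResult:
    """Outcome of the incremental threshold scan."""

    records: tuple[ScanRecord, ...]
    selected_threshold: int
    selected_frame_index: int
    mva_cm2: float
    stop_reason: StopReason

    @property
    def selected_record(self) -> ScanRecord:
        for rec in self.records:
            if rec.threshold == self.selected_threshold:
                return rec
        raise ValueError("selected threshold missing from records")


def to_grayscale(frame: Frame) -> GrayFrame:
    """Luminance conversion, rounded half-up to the nearest integer."""
    frame = np.asarray(frame)
    wr, wg, wb = LUMA_WEIGHTS
    luma = (
        wr * frame[..., 0].astype(np.float64)
        + wg * frame[..., 1].astype(np.float64)
        + wb * frame[..., 2].astype(np.float64)
    )
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def binarize(gray: GrayFrame, threshold: int) -> BinaryMask:
    """Single-band fixed threshold: bit is 1 iff intensity > threshold.

    The threshold must lie strictly inside the gray range, 0 < t < 255;
    the degenerate thresholds would map every frame to all-ones or
    all-zeros and carry no contour information.
    """
    _check_threshold(threshold)
    return (np.asarray(gray) > threshold).astype(np.uint8)


def _check_threshold(threshold: int) -> None:
    if not 0 < threshold < 255:
        raise ValidationError(
            f"threshold must satisfy 0 < t < 255, got {threshold}"
        )


# Moore neighborhood in clockwise order starting due west.
_MOORE = (
    (0, -1), (-1, -1), (-1, 0), (-1, 1),
    (0, 1), (1, 1), (1, 0), (1, -1),
)


def trace_boundary(region: np.ndarray) -> np.ndarray:
    """Ordered closed boundary of a connected region, by Moore tracing.

    ``region`` is a boolean mask containing one 8-connected component.
    Returns the outer boundary as a (k, 2) array of (row, col) pixel
    coordinates; consecutive entries are 8-neighbors and the path closes
    back to the first entry.  A single-pixel region yields one point.
    Tracing stops when the start pixel is re-entered the same way it was
    first left (Jacob's criterion), which handles pinch points.
    """
    rows, cols = np.nonzero(region)
    if rows.size == 0:
        raise ValidationError("cannot trace an empty region")
    # topmost-leftmost pixel: its west neighbor is guaranteed background
    top = rows.min()
    start = (int(top), int(cols[rows == top].min()))
    h, w = region.shape

    def is_fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and bool(region[p])

    boundary = [start]
    p = start
    scan_from = 0  # begin scanning at the west neighbor (background)
    first_move: tuple[tuple[int, int], int] | None = None
    for _ in range(4 * rows.size + 8):
        move = None
        for k in range(8):
            idx = (scan_from + k) % 8
            dy, dx = _MOORE[idx]
            q = (p[0] + dy, p[1] + dx)
            if is_fg(q):
                move = (idx, q)
                break
        if move is None:
            break  # isolated single pixel
        idx, q = move
        if first_move is None:
            first_move = (p, idx)
        elif (p, idx) == first_move:
            break  # cycle closed
        boundary.append(q)
        p = q
        # resume scanning just past the pixel we arrived from
        scan_from = (idx + 6) % 8
    if len(boundary) > 1 and boundary[-1] == boundary[0]:
        boundary.pop()
    return np.array(boundary, dtype=int)


def _polygon_length_cm(path: np.ndarray, calibration: PixelCalibration) -> float:
    """Closed arc length of a pixel path with per-axis cm scaling."""
    if len(path) < 2:
        return 0.0
    closed = np.vstack([path, path[:1]])
    d = np.diff(closed, axis=0).astype(float)
    return float(
        np.hypot(d[:, 1] * calibration.cm_per_px_x, d[:, 0] * calibration.cm_per_px_y).sum()
    )


def find_orifice_contour(
    mask: BinaryMask, calibration: PixelCalibration
) -> OrificeContour | None:
    """Locate the valve orifice in a binary frame.

    The orifice is the largest 8-connected dark (0-valued) region that
    does not touch the image border; dark regions reaching the border
    are background.  Returns ``None`` when no enclosed dark region
    exists (valve closed).
    """
    mask = np.asarray(mask)
    dark = mask == 0
    labels = measure.label(dark, connectivity=2)
    if labels.max() == 0:
        return None
    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    touching = np.zeros(labels.max() + 1, dtype=bool)
    touching[np.unique(border)] = True
    counts = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    counts[0] = 0
    counts[touching] = 0
    if counts.max() == 0:
        return None
    lab = int(counts.argmax())  # ties: lowest label, i.e. first in raster order
    region = labels == lab
    boundary = trace_boundary(region)
    n_px = int(counts[lab])
    return OrificeContour(
        boundary=boundary,
        interior_pixel_count=n_px,
        area_cm2=n_px * calibration.pixel_area_cm2,
        perimeter_cm=_polygon_length_cm(boundary, calibration),
    )


def _as_frames(seq: FrameSequence | Sequence[Frame]) -> list[Frame]:
    frames = list(seq.frames) if isinstance(seq, FrameSequence) else list(seq)
    if not frames:
        raise ValidationError("empty frame sequence")
    return frames


def max_opening_frame(
    seq: FrameSequence | Sequence[Frame],
    threshold: int,
    calibration: PixelCalibration,
    _grays: Sequence[GrayFrame] | None = None,
) -> ScanRecord:
    """Best frame at one threshold: the largest orifice area wins.

    Frames with no detectable orifice score area 0; ties on area go to
    the earliest frame index, which makes the result deterministic.
    """
    _check_threshold(threshold)
    grays = _grays if _grays is not None else [to_grayscale(f) for f in _as_frames(seq)]
    best_idx, best_area, best_perim, best_contour = 0, 0.0, 0.0, None
    for i, gray in enumerate(grays):
        contour = find_orifice_contour(binarize(gray, threshold), calibration)
        area = contour.area_cm2 if contour is not None else 0.0
        if area > best_area:
            best_idx, best_area, best_contour = i, area, contour
            best_perim = contour.perimeter_cm
    return ScanRecord(
        threshold=threshold,
        best_frame_index=best_idx,
        area_cm2=best_area,
        perimeter_cm=best_perim,
        contour=best_contour,
    )


def threshold_scan(
    seq: FrameSequence | Sequence[Frame],
    calibration: PixelCalibration,
    t_min: int = 10,
    t_max: int = 30,
    perimeter_jump_cm: float = 1.0,
) -> ScanResult:
    """Incremental threshold scan selecting the frame of maximum opening.

    Thresholds ``t_min..t_max`` are applied in order; each picks its own
    best frame.  The scan stops at the first threshold whose best-frame
    contour perimeter differs from the previous threshold's by more than
    ``perimeter_jump_cm`` (in absolute value) — the *penultimate*
    threshold is then selected — or at ``t_max``, which is then selected
    itself.  The selected record's area is the reported MVA.
    """
    if t_min > t_max:
        raise ValidationError(f"t_min={t_min} exceeds t_max={t_max}")
    _check_threshold(t_min)
    _check_threshold(t_max)
    frames = _as_frames(seq)
    grays = [to_grayscale(f) for f in frames]

    records: list[ScanRecord] = []
    selected: ScanRecord | None = None
    stop_reason: StopReason = "threshold_cap"
    for t in range(t_min, t_max + 1):
        rec = max_opening_frame(frames, t, calibration, _grays=grays)
        records.append(rec)
        if len(records) >= 2:
            prev = records[-2]
            if abs(rec.perimeter_cm - prev.perimeter_cm) > perimeter_jump_cm:
                selected = prev
                stop_reason = "perimeter_jump"
                break
    if selected is None:
        selected = records[-1]
        stop_reason = "threshold_cap"
    return ScanResult(
        records=tuple(records),
        selected_threshold=selected.threshold,
        selected_frame_index=selected.best_frame_index,
        mva_cm2=selected.area_cm2,
        stop_reason=stop_reason,
    )


def overlay_contour(frame: Frame, contour: OrificeContour | None) -> Frame:
    """Copy of ``frame`` with the orifice boundary drawn as a solid white line."""
    out = np.asarray(frame).copy()
    if contour is not None and len(contour.boundary):
        rr, cc = contour.boundary[:, 0], contour.boundary[:, 1]
        out[rr, cc] = 255
    return out
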