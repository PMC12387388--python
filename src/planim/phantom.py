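"""Synthetic echocardiogram phantoms with known orifice ground truth.

Clinical transesophageal recordings cannot be redistributed, so every
stage of the package is exercised on phantom videos that reproduce the
visual contract the planimetry relies on: a black background that
reaches the image border, a bright multi-colored tissue disk (en face
valve surface) whose luminance stays well above the scanned thresholds,
and a central dark orifice whose area follows a smooth open–close
cardiac trajectory with a known diastolic maximum.  Vendor calibration
markers (Philips green dots or a GE scale line) are drawn on request,
and additive Gaussian channel noise stands in for speckle.

Ground truth is recorded from the rendered orifice mask itself (pixel
count × pixel area), so rasterization is part of the truth, not an
error term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ._avi import write_avi
from .errors import ValidationError
from .grading import StenosisGrade, classify_mva
from .video_io import PixelCalibration

#: Default tissue colors; every entry has luminance well above gray 30
#: and none satisfies the green-marker detection rule.
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (205, 90, 70),
    (225, 170, 95),
    (170, 110, 190),
    (120, 160, 170),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of one synthetic echo video."""

    diastolic_mva_cm2: float = 2.5
    image_size: int = 224
    n_frames: int = 24
    peak_frame: int | None = None  # default: mid-sequence
    orifice_shape: Literal["ellipse", "blob"] = "ellipse"
    tissue_palette: Sequence[tuple[int, int, int]] = DEFAULT_PALETTE
    noise_sigma: float = 8.0
    marker_dialect: Literal["philips", "ge", "none"] = "philips"
    cm_per_px: float = 0.02
    marker_spacing_cm: float = 1.0
    scale_line_length_cm: float = 1.0
    leaflet_thickening_px: float | None = None  # default: rule of _thickening_px
    seed: int = 0
    fps: int = 25

    def __post_init__(self) -> None:
        if self.diastolic_mva_cm2 < 0:
            raise ValidationError("diastolic MVA must be non-negative")
        if self.n_frames < 1 or self.image_size < 48:
            raise ValidationError("need n_frames >= 1 and image_size >= 48")
        peak = self.resolved_peak_frame
        if not 0 <= peak < self.n_frames:
            raise ValidationError("peak_frame must index a frame")
        if self.cm_per_px <= 0:
            raise ValidationError("cm_per_px must be positive")

    @property
    def resolved_peak_frame(self) -> int:
        return self.n_frames // 2 if self.peak_frame is None else self.peak_frame

    @property
    def calibration(self) -> PixelCalibration:
        return PixelCalibration(self.cm_per_px, self.cm_per_px)


@dataclass(frozen=True)
class PhantomTruth:
    """What the generator actually drew, frame by frame."""

    per_frame_area_cm2: tuple[float, ...]
    max_area_cm2: float = field(init=False)
    peak_frame: int = field(init=False)
    calibration: PixelCalibration = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        areas = self.per_frame_area_cm2
        object.__setattr__(self, "max_area_cm2", max(areas))
        object.__setattr__(self, "peak_frame", int(np.argmax(areas)))


#: Color of thickened leaflet tissue (pale, calcification-like).
THICKENED_LEAFLET_COLOR = (230, 220, 205)


def _thickening_px(spec: PhantomSpec) -> float:
    """Leaflet-rim thickness in pixels.

    Stenotic valves are stenotic *because* their leaflets are thickened
    and fused, and that morphology is visible in every frame of a real
    recording, open or closed.  The phantom mirrors it as a pale rim
    around the orifice: absent for non-stenotic valves (MVA ≥ 4 cm²),
    present at a clearly visible baseline whenever stenosis exists
    (thickening is diagnostic even in mild disease), and growing with
    severity.  At the default 0.02 cm/px the rule below spans roughly
    1.2–2.3 mm, matching reported rheumatic leaflet thickness.
    """
    if spec.leaflet_thickening_px is not None:
        return spec.leaflet_thickening_px
    mva = spec.diastolic_mva_cm2
    if mva >= 4.0:
        return 0.0
    return 6.0 + 1.5 * (4.0 - mva)


def _opening_fraction(spec: PhantomSpec) -> np.ndarray:
    """Raised-cosine open–close trajectory: 0 at the ends, 1 at the peak."""
    n, peak = spec.n_frames, spec.resolved_peak_frame
    if n == 1:
        return np.ones(1)
    f = np.arange(n, dtype=float)
    g = np.where(
        f <= peak,
        f / (2 * max(peak, 1)),
        0.5 + (f - peak) / (2 * max(n - 1 - peak, 1)),
    )
    return 0.5 * (1.0 - np.cos(2 * np.pi * g))


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render all frames in memory; returns (frames, truth).

    Frames are (n, h, w, 3) uint8 RGB.  Deterministic for a fixed spec.
    """
    size = spec.image_size
    cal = spec.calibration
    center = size / 2.0 - 0.5
    tissue_radius = 0.42 * size

    # peak orifice geometry must fit inside the tissue disk
    peak_area_px = spec.diastolic_mva_cm2 / cal.pixel_area_cm2
    rng = np.random.default_rng(spec.seed)
    if spec.orifice_shape == "ellipse":
        aspect = 1.3
        harmonics = None
    else:
        aspect = 1.0
        amps = 0.12 * rng.random(3)
        phases = rng.uniform(0, 2 * np.pi, 3)
        harmonics = (amps, phases)
    r0_peak = np.sqrt(peak_area_px / np.pi)
    if harmonics is not None:
        r0_peak /= np.sqrt(1.0 + 0.5 * float(np.sum(harmonics[0] ** 2)))
    max_extent = r0_peak * (aspect if aspect >= 1 else 1.0)
    if harmonics is not None:
        max_extent *= 1.0 + float(harmonics[0].sum())
    if max_extent > tissue_radius - 6:
        raise ValidationError(
            f"orifice of {spec.diastolic_mva_cm2} cm² does not fit inside the "
            f"tissue region at {spec.cm_per_px} cm/px and image size {size}"
        )

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - center, xx - center
    rad = np.hypot(dy, dx)
    ang = np.arctan2(dy, dx)
    tissue = rad <= tissue_radius

    palette = np.asarray(spec.tissue_palette, dtype=np.uint8)
    sector = ((ang + np.pi) / (2 * np.pi) * len(palette)).astype(int) % len(palette)
    base = np.zeros((size, size, 3), dtype=np.uint8)
    base[tissue] = palette[sector[tissue]]
    _draw_markers(base, spec)

    # elliptical (or harmonically perturbed) orifice radius field
    if harmonics is None:
        eff_rad = np.hypot(dx / aspect, dy * aspect)
        shape_scale = np.ones_like(rad)
    else:
        amps, phases = harmonics
        shape_scale = 1.0 + sum(
            a * np.cos((k + 2) * ang + p) for k, (a, p) in enumerate(zip(amps, phases))
        )
        eff_rad = rad / shape_scale

    fractions = _opening_fraction(spec)
    rim_t = _thickening_px(spec)
    frames = np.empty((spec.n_frames, size, size, 3), dtype=np.uint8)
    areas = []
    for i, w in enumerate(fractions):
        frame = base.copy()
        area_px = peak_area_px * w
        if area_px >= 1.0:
            r0 = r0_peak * np.sqrt(w)
            orifice = tissue & (eff_rad <= r0)
        else:
            r0 = 0.0
            orifice = np.zeros_like(tissue)
        if rim_t > 0:
            rim = tissue & (eff_rad > r0) & (eff_rad <= r0 + rim_t)
            frame[rim] = THICKENED_LEAFLET_COLOR
        frame[orifice] = 0
        areas.append(float(orifice.sum()) * cal.pixel_area_cm2)
        if spec.noise_sigma > 0:
            noise = rng.normal(0.0, spec.noise_sigma, frame.shape)
            frame = np.clip(frame.astype(float) + noise, 0, 255).astype(np.uint8)
        frames[i] = frame
    truth = PhantomTruth(per_frame_area_cm2=tuple(areas), calibration=cal)
    return frames, truth


def _draw_markers(base: np.ndarray, spec: PhantomSpec) -> None:
    size = spec.image_size
    if spec.marker_dialect == "philips":
        gap = int(round(spec.marker_spacing_cm / spec.cm_per_px))
        top = 10
        if top + gap + 2 >= size:
            raise ValidationError("green marker ruler does not fit in the image")
        for row in (top, top + gap):
            base[row - 1 : row + 2, 5:8] = (0, 255, 0)
    elif spec.marker_dialect == "ge":
        length = int(round(spec.scale_line_length_cm / spec.cm_per_px))
        row = size - 8
        c1 = size - 8
        c0 = c1 - length
        if c0 < size // 2:
            raise ValidationError("scale line does not fit in the lower-right corner")
        base[row, c0:c1] = 255


def generate_phantom(spec: PhantomSpec, out_path: str | Path) -> PhantomTruth:
    """Render a phantom and write it as an uncompressed AVI."""
    frames, truth = render_phantom(spec)
    write_avi(out_path, frames, fps=spec.fps)
    return truth


#: MVA sampling interval per grade, kept strictly inside each grade's
#: cutoffs so the sampled truth always classifies to its own grade.
GRADE_MVA_RANGES: dict[StenosisGrade, tuple[float, float]] = {
    StenosisGrade.NO_STENOSIS: (4.05, 5.5),
    StenosisGrade.MILD: (1.6, 3.9),
    StenosisGrade.MODERATE: (1.0, 1.5),
    StenosisGrade.SEVERE: (0.2, 0.95),
}


@dataclass(frozen=True)
class PhantomSample:
    path: Path
    truth: PhantomTruth
    grade: StenosisGrade
    spec: PhantomSpec


def generate_cohort(
    n_per_grade: int,
    seed: int,
    out_dir: str | Path,
    **spec_overrides,
) -> list[PhantomSample]:
    """Generate a labelled phantom cohort, ``n_per_grade`` videos per grade.

    Diastolic MVAs are sampled uniformly inside each grade's interval;
    every sample's ground truth therefore classifies to its intended
    grade.  Videos are written to ``out_dir`` as AVI files named
    ``<grade>_<index>.avi``.
    """
    if n_per_grade < 1:
        raise ValidationError("n_per_grade must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    for grade, (lo, hi) in GRADE_MVA_RANGES.items():
        for i in range(n_per_grade):
            mva = float(rng.uniform(lo, hi))
            spec = PhantomSpec(
                diastolic_mva_cm2=mva,
                seed=int(rng.integers(0, 2**31 - 1)),
                **spec_overrides,
            )
            path = out_dir / f"{grade.value}_{i:03d}.avi"
            truth = generate_phantom(spec, path)
            assert classify_mva(mva) is grade
            samples.append(PhantomSample(path=path, truth=truth, grade=grade, spec=spec))
    return samples
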