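"""End-to-end workflows: planimetric diagnosis and CNN screening.

Two runnable pipelines sit on top of the stage modules:

* :func:`run_dip` — video → frames → calibration → threshold scan →
  MVA, severity grade, and a report with the selected frame's contour;
* :func:`run_compare` — the same video through both the planimetric
  pipeline and a trained CNN, flagging disagreement between the two.

A scaled-down screening experiment on phantom cohorts
(:func:`run_screening_experiment`) trains and validates the CNN without
clinical data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import augment as aug
from . import cnn as cnn_mod
from .errors import CalibrationError, ValidationError
from .grading import StenosisGrade, classify_mva
from .phantom import GRADE_MVA_RANGES, PhantomSpec, generate_phantom
from .planimetry import ScanResult, overlay_contour, threshold_scan
from .video_io import (
    PixelCalibration,
    calibrate_ge,
    calibrate_philips,
    explicit_calibration,
    extract_frames,
)

log = logging.getLogger("planim")


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    calib_mode: str = "philips"  # philips | ge | explicit
    marker_spacing_cm: float = 1.0
    scale_line_length_cm: float = 1.0
    cm_per_px_x: float | None = None  # explicit mode
    cm_per_px_y: float | None = None
    t_min: int = 10
    t_max: int = 30
    perimeter_jump_cm: float = 1.0
    augmentation: aug.AugmentationConfig = field(default_factory=aug.AugmentationConfig)
    cnn: cnn_mod.CNNSpec = field(default_factory=cnn_mod.CNNSpec)
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "planim_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "augmentation" in d and isinstance(d["augmentation"], dict):
            d["augmentation"] = aug.AugmentationConfig(**d["augmentation"])
        if "cnn" in d and isinstance(d["cnn"], dict):
            c = dict(d["cnn"])
            if "conv_filters" in c:
                c["conv_filters"] = tuple(c["conv_filters"])
            d["cnn"] = cnn_mod.CNNSpec(**c)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def resolve_calibration(frame, config: RunConfig) -> PixelCalibration:
    if config.calib_mode == "philips":
        return calibrate_philips(frame, marker_spacing_cm=config.marker_spacing_cm)
    if config.calib_mode == "ge":
        return calibrate_ge(frame, line_length_cm=config.scale_line_length_cm)
    if config.calib_mode == "explicit":
        if config.cm_per_px_x is None or config.cm_per_px_y is None:
            raise CalibrationError(
                "explicit calibration requires cm_per_px_x and cm_per_px_y"
            )
        return explicit_calibration(config.cm_per_px_x, config.cm_per_px_y)
    raise ValidationError(f"unknown calibration mode {config.calib_mode!r}")


@dataclass
class DipReport:
    """Planimetric diagnosis for one video."""

    video: str
    mva_cm2: float
    grade: StenosisGrade
    scan: ScanResult
    calibration: PixelCalibration
    seed: int

    def to_dict(self) -> dict:
        return {
            "video": self.video,
            "mva_cm2": self.mva_cm2,
            "grade": self.grade.value,
            "selected_threshold": self.scan.selected_threshold,
            "selected_frame_index": self.scan.selected_frame_index,
            "stop_reason": self.scan.stop_reason,
            "calibration_cm_per_px": [
                self.calibration.cm_per_px_x,
                self.calibration.cm_per_px_y,
            ],
            "seed": self.seed,
            "scan_records": [
                {
                    "threshold": r.threshold,
                    "best_frame_index": r.best_frame_index,
                    "area_cm2": r.area_cm2,
                    "perimeter_cm": r.perimeter_cm,
                }
                for r in self.scan.records
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def run_dip(video_path: str | Path, config: RunConfig) -> DipReport:
    """Planimetric pipeline: MVA in cm², severity grade, scan trace."""
    try:
        seq = extract_frames(video_path, vendor_dialect=config.calib_mode)  # type: ignore[arg-type]
    except Exception as exc:
        raise type(exc)(f"[frame extraction] {exc}") from exc
    try:
        calibration = resolve_calibration(seq.frames[0], config)
    except CalibrationError as exc:
        raise CalibrationError(f"[calibration] {exc}") from exc
    scan = threshold_scan(
        seq,
        calibration,
        t_min=config.t_min,
        t_max=config.t_max,
        perimeter_jump_cm=config.perimeter_jump_cm,
    )
    grade = classify_mva(scan.mva_cm2)
    log.info(
        "%s: MVA %.2f cm² at threshold %d (frame %d, %s) -> %s",
        video_path, scan.mva_cm2, scan.selected_threshold,
        scan.selected_frame_index, scan.stop_reason, grade.value,
    )
    return DipReport(
        video=str(video_path),
        mva_cm2=scan.mva_cm2,
        grade=grade,
        scan=scan,
        calibration=calibration,
        seed=config.seed,
    )


def save_overlay(report: DipReport, video_path: str | Path, out_png: str | Path) -> None:
    """Selected frame with the orifice contour drawn as a solid white line."""
    seq = extract_frames(video_path)
    frame = seq.frames[report.scan.selected_frame_index]
    contour = report.scan.selected_record.contour
    Image.fromarray(overlay_contour(frame, contour)).save(out_png)


@dataclass
class ComparisonReport:
    """Side-by-side planimetric and CNN verdicts for one video."""

    dip: DipReport
    cnn_verdict: str
    agreement: bool

    def to_dict(self) -> dict:
        return {
            "dip": self.dip.to_dict(),
            "dip_verdict": (
                aug.HAS_STENOSIS if self.dip.grade.has_stenosis else aug.NO_STENOSIS
            ),
            "cnn_verdict": self.cnn_verdict,
            "agreement": self.agreement,
        }


def run_compare(
    video_path: str | Path, config: RunConfig, model: cnn_mod.Model
) -> ComparisonReport:
    """Both verdicts for one video; the planimetric side carries the
    extra outputs (area, contour, frame) the CNN cannot provide."""
    dip = run_dip(video_path, config)
    pred = cnn_mod.predict_video(model, video_path)
    dip_verdict = aug.HAS_STENOSIS if dip.grade.has_stenosis else aug.NO_STENOSIS
    return ComparisonReport(
        dip=dip,
        cnn_verdict=pred.verdict,
        agreement=(pred.verdict == dip_verdict),
    )


# ------------------------------------------------- screening experiment

_STENOTIC_GRADES = (StenosisGrade.SEVERE, StenosisGrade.MODERATE, StenosisGrade.MILD)


def generate_screening_cohort(
    n_per_class: int,
    seed: int,
    out_dir: str | Path,
    n_frames: int = 10,
    noise_sigma: float = 8.0,
) -> list[tuple[Path, str]]:
    """Balanced phantom cohort for binary screening.

    Non-stenotic videos sample MVA in the no-stenosis interval; stenotic
    videos draw a grade (severe/moderate/mild, round-robin) and sample
    inside its interval.  Returns (path, label) pairs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    videos: list[tuple[Path, str]] = []
    for i in range(n_per_class):
        lo, hi = GRADE_MVA_RANGES[StenosisGrade.NO_STENOSIS]
        spec = PhantomSpec(
            diastolic_mva_cm2=float(rng.uniform(lo, hi)),
            n_frames=n_frames,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        path = out_dir / f"{aug.NO_STENOSIS}_{i:03d}.avi"
        generate_phantom(spec, path)
        videos.append((path, aug.NO_STENOSIS))
    for i in range(n_per_class):
        lo, hi = GRADE_MVA_RANGES[_STENOTIC_GRADES[i % 3]]
        spec = PhantomSpec(
            diastolic_mva_cm2=float(rng.uniform(lo, hi)),
            n_frames=n_frames,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        path = out_dir / f"{aug.HAS_STENOSIS}_{i:03d}.avi"
        generate_phantom(spec, path)
        videos.append((path, aug.HAS_STENOSIS))
    return videos


def run_screening_experiment(
    work_dir: str | Path,
    seed: int = 0,
    n_per_class: int = 10,
    n_frames: int = 10,
    n_aug: int = 6,
    test_fraction: float = 0.3,
    holdout_videos: int = 2,
    input_size: int = 64,
    max_epochs: int = 10,
) -> dict:
    """Train and validate the screening CNN on a phantom cohort.

    Generates ``n_per_class`` videos per class, expands each frame with
    ``n_aug`` augmented copies, holds out ``holdout_videos`` whole
    videos per class, splits the rest 70/30 at frame level, trains with
    early stopping, and reports the held-out frame metrics plus the
    verdicts on the unseen holdout videos.
    """
    work_dir = Path(work_dir)
    videos = generate_screening_cohort(
        n_per_class, seed, work_dir / "videos", n_frames=n_frames
    )

    images = aug.LabelledImageSet()
    for path, label in videos:
        for frame in extract_frames(path).frames:
            images.add(frame, label, path.stem)
    cfg = aug.AugmentationConfig(n_aug_per_frame=n_aug, seed=seed)
    augmented = aug.augment_set(images, cfg)
    train_set, test_set, holdout_ids = aug.split_dataset(
        augmented, test_fraction, holdout_videos=holdout_videos, seed=seed
    )

    spec = cnn_mod.CNNSpec(input_size=input_size, max_epochs=max_epochs, seed=seed)
    model = cnn_mod.build_model(spec)
    x_train, y_train = cnn_mod.prepare_images(train_set, input_size)
    x_test, y_test = cnn_mod.prepare_images(test_set, input_size)
    history = cnn_mod.train(model, x_train, y_train, x_test, y_test, seed=seed)
    test_metrics = cnn_mod.evaluate_arrays(model, x_test, y_test)

    holdout_results = []
    by_stem = {p.stem: (p, label) for p, label in videos}
    for vid in holdout_ids:
        path, label = by_stem[vid]
        pred = cnn_mod.predict_video(model, path)
        holdout_results.append(
            {"video": path.name, "true": label, "predicted": pred.verdict}
        )
    return {
        "model": model,
        "history": history,
        "test_accuracy": test_metrics["accuracy"],
        "test_loss": test_metrics["loss"],
        "confusion": test_metrics["confusion"],
        "n_train": len(x_train),
        "n_test": len(x_test),
        "holdout": holdout_results,
        "holdout_correct": sum(
            r["true"] == r["predicted"] for r in holdout_results
        ),
    }
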