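"""Label-preserving image augmentation and dataset splitting.

The screening CNN sees few distinct videos, so each extracted frame is
expanded with random affine transforms: rotation up to ±40°, horizontal
and vertical shifts up to ±20% of the frame size, shear, zoom, and a
fair-coin horizontal flip.  Pixels exposed by a transform are filled by
replicating the nearest edge pixel.  Six augmented copies per frame is
the default.

Splitting works at two granularities, both of which the training
workflow uses: a frame-level random split into train/test at a given
fraction per class, and a video-level holdout that removes *all* frames
of selected videos from both sets so they remain genuinely unseen.
Note that the frame-level split alone leaks: frames of one video land
on both sides.  The video holdout is the leakage-free check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ValidationError
from .video_io import Frame

#: Binary screening labels.
HAS_STENOSIS = "has_stenosis"
NO_STENOSIS = "no_stenosis"


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_range_deg: float = 40.0
    width_shift: float = 0.2
    height_shift: float = 0.2
    shear_range: float = 0.2  # shear factor, ~11 degrees
    zoom_range: float = 0.2
    horizontal_flip: bool = True
    fill_mode: str = "nearest"
    n_aug_per_frame: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_range_deg < 0 or self.n_aug_per_frame < 0:
            raise ValidationError("rotation range and n_aug must be non-negative")
        if not (0 <= self.width_shift <= 1 and 0 <= self.height_shift <= 1):
            raise ValidationError("shifts must be fractions in [0, 1]")
        if self.fill_mode != "nearest":
            raise ValidationError("only nearest-neighbor fill is supported")


def _random_affine(rng: np.random.Generator, cfg: AugmentationConfig, h: int, w: int):
    """Sample one affine map (output→input) about the image center."""
    theta = math.radians(rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg))
    shear = rng.uniform(-cfg.shear_range, cfg.shear_range)
    zx = rng.uniform(1 - cfg.zoom_range, 1 + cfg.zoom_range)
    zy = rng.uniform(1 - cfg.zoom_range, 1 + cfg.zoom_range)
    ty = rng.uniform(-cfg.height_shift, cfg.height_shift) * h
    tx = rng.uniform(-cfg.width_shift, cfg.width_shift) * w
    flip = cfg.horizontal_flip and rng.random() < 0.5

    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    shr = np.array([[1.0, shear], [0.0, 1.0]])
    zoom = np.diag([1.0 / zy, 1.0 / zx])
    mat = rot @ shr @ zoom
    if flip:
        mat = mat @ np.diag([1.0, -1.0])
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - mat @ (center + np.array([ty, tx]))
    return mat, offset


def augment_frame(frame: Frame, config: AugmentationConfig) -> list[Frame]:
    """Generate ``n_aug_per_frame`` randomly transformed copies of a frame.

    Deterministic for a fixed config seed.  With every range set to zero
    and flipping off, the copies equal the input exactly.
    """
    frame = np.asarray(frame)
    h, w = frame.shape[:2]
    rng = np.random.default_rng(config.seed)
    out: list[Frame] = []
    for _ in range(config.n_aug_per_frame):
        mat, offset = _random_affine(rng, config, h, w)
        channels = [
            ndimage.affine_transform(
                frame[:, :, c].astype(np.float32),
                mat,
                offset=offset,
                order=1,
                mode="nearest",
            )
            for c in range(frame.shape[2])
        ]
        out.append(np.clip(np.stack(channels, axis=2), 0, 255).astype(np.uint8))
    return out


@dataclass
class LabelledImageSet:
    """Images with binary class labels and their source video ids.

    Filenames follow ``<class>_<counter>.png`` so a directory dump keeps
    the class recoverable from the name alone.
    """

    images: list[Frame] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    video_ids: list[str] = field(default_factory=list)
    filenames: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)

    def add(self, image: Frame, label: str, video_id: str) -> None:
        self.filenames.append(f"{label}_{len(self.filenames):06d}.png")
        self.images.append(image)
        self.labels.append(label)
        self.video_ids.append(video_id)

    def classes(self) -> set[str]:
        return set(self.labels)

    def subset(self, idx: list[int]) -> "LabelledImageSet":
        return LabelledImageSet(
            images=[self.images[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            video_ids=[self.video_ids[i] for i in idx],
            filenames=[self.filenames[i] for i in idx],
        )

    def save_directory(self, root: str | Path) -> None:
        """One folder per class, images as PNG, plus a manifest that
        preserves each image's source video id."""
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        for img, label, name in zip(self.images, self.labels, self.filenames):
            d = root / label
            d.mkdir(parents=True, exist_ok=True)
            Image.fromarray(img).save(d / name)
        lines = ["filename,label,video_id"]
        lines += [
            f"{n},{l},{v}"
            for n, l, v in zip(self.filenames, self.labels, self.video_ids)
        ]
        (root / "manifest.csv").write_text("\n".join(lines) + "\n")

    @classmethod
    def load_directory(cls, root: str | Path) -> "LabelledImageSet":
        """Inverse of :meth:`save_directory`; class = folder name.

        Without a manifest each image becomes its own video id.
        """
        root = Path(root)
        video_of: dict[str, str] = {}
        manifest = root / "manifest.csv"
        if manifest.exists():
            for line in manifest.read_text().splitlines()[1:]:
                name, _, vid = line.split(",")
                video_of[name] = vid
        out = cls()
        for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for png in sorted(class_dir.glob("*.png")):
                img = np.asarray(Image.open(png).convert("RGB"))
                out.images.append(img)
                out.labels.append(class_dir.name)
                out.video_ids.append(video_of.get(png.name, png.stem))
                out.filenames.append(png.name)
        if not out.images:
            raise ValidationError(f"{root}: no class folders with PNG images")
        return out


def augment_set(images: LabelledImageSet, config: AugmentationConfig) -> LabelledImageSet:
    """Originals plus ``n_aug_per_frame`` augmented copies of each image."""
    out = LabelledImageSet()
    for i, (img, label, vid) in enumerate(
        zip(images.images, images.labels, images.video_ids)
    ):
        out.add(img, label, vid)
        per_image = replace(config, seed=config.seed + 1 + i)
        for aug in augment_frame(img, per_image):
            out.add(aug, label, vid)
    return out


def split_dataset(
    images: LabelledImageSet,
    test_fraction: float,
    holdout_videos: int = 0,
    seed: int = 0,
) -> tuple[LabelledImageSet, LabelledImageSet, list[str]]:
    """Frame-level train/test split plus a video-level holdout.

    ``holdout_videos`` whole videos per class are removed from both
    splits (their frames appear nowhere); the remaining images are split
    per class at ``test_fraction``.  Returns (train, test, holdout ids).
    """
    if len(images.classes()) < 2:
        raise ValidationError("both classes must be present to split")
    if not 0 <= test_fraction <= 1:
        raise ValidationError("test_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    holdout_ids: list[str] = []
    for label in sorted(images.classes()):
        vids = sorted({v for v, l in zip(images.video_ids, images.labels) if l == label})
        if holdout_videos > len(vids):
            raise ValidationError(
                f"cannot hold out {holdout_videos} videos from class {label!r} "
                f"with only {len(vids)} videos"
            )
        chosen = rng.choice(len(vids), size=holdout_videos, replace=False)
        holdout_ids.extend(vids[i] for i in sorted(chosen))

    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(images.classes()):
        idx = [
            i
            for i, (l, v) in enumerate(zip(images.labels, images.video_ids))
            if l == label and v not in holdout_ids
        ]
        perm = rng.permutation(len(idx))
        n_test = int(round(test_fraction * len(idx)))
        test_idx.extend(idx[i] for i in perm[:n_test])
        train_idx.extend(idx[i] for i in perm[n_test:])
    return images.subset(sorted(train_idx)), images.subset(sorted(test_idx)), holdout_ids
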