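import numpy as np
import pytest

from planim.augment import (
    HAS_STENOSIS,
    NO_STENOSIS,
    AugmentationConfig,
    LabelledImageSet,
    augment_frame,
    augment_set,
    split_dataset,
)
from planim.errors import ValidationError


@pytest.fixture
def frame():
    rng = np.random.default_rng(0)
    return rng.integers(0, 256, (48, 64, 3), dtype=np.uint8)


def _two_class_set(frame, n_videos=6, frames_per_video=10):
    s = LabelledImageSet()
    for v in range(n_videos):
        label = HAS_STENOSIS if v < n_videos // 2 else NO_STENOSIS
        for _ in range(frames_per_video):
            s.add(frame, label, f"vid{v}")
    return s


class TestAugmentFrame:
    def test_produces_requested_count(self, frame):
        out = augment_frame(frame, AugmentationConfig(n_aug_per_frame=6, seed=1))
        assert len(out) == 6
        assert all(a.shape == frame.shape and a.dtype == np.uint8 for a in out)

    def test_identity_config_returns_exact_copies(self, frame):
        cfg = AugmentationConfig(
            rotation_range_deg=0, width_shift=0, height_shift=0,
            shear_range=0, zoom_range=0, horizontal_flip=False,
            n_aug_per_frame=3,
        )
        assert all((a == frame).all() for a in augment_frame(frame, cfg))

    def test_same_seed_same_output(self, frame):
        cfg = AugmentationConfig(n_aug_per_frame=4, seed=9)
        a = augment_frame(frame, cfg)
        b = augment_frame(frame, cfg)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_different_seeds_differ(self, frame):
        a = augment_frame(frame, AugmentationConfig(n_aug_per_frame=1, seed=1))
        b = augment_frame(frame, AugmentationConfig(n_aug_per_frame=1, seed=2))
        assert not (a[0] == b[0]).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            AugmentationConfig(width_shift=1.5)
        with pytest.raises(ValidationError):
            AugmentationConfig(fill_mode="reflect")


class TestAugmentSet:
    def test_labels_preserved_and_counts(self, frame):
        s = _two_class_set(frame, n_videos=2, frames_per_video=3)
        out = augment_set(s, AugmentationConfig(n_aug_per_frame=6, seed=0))
        assert len(out) == len(s) * 7  # original + 6
        # every augmented image keeps its source label and video id
        for i in range(len(s)):
            block = slice(i * 7, (i + 1) * 7)
            assert set(out.labels[block]) == {s.labels[i]}
            assert set(out.video_ids[block]) == {s.video_ids[i]}

    def test_filenames_unique_with_class_prefix(self, frame):
        s = _two_class_set(frame, n_videos=2, frames_per_video=2)
        out = augment_set(s, AugmentationConfig(n_aug_per_frame=2, seed=0))
        assert len(set(out.filenames)) == len(out)
        assert all(
            name.startswith(label) for name, label in zip(out.filenames, out.labels)
        )


class TestSplitDataset:
    def test_fraction_split_per_class(self, frame):
        s = _two_class_set(frame, n_videos=6, frames_per_video=10)
        train, test, holdout = split_dataset(s, 0.3, holdout_videos=0, seed=1)
        assert holdout == []
        assert len(train) + len(test) == len(s)
        for label in (HAS_STENOSIS, NO_STENOSIS):
            n_test = sum(1 for l in test.labels if l == label)
            assert n_test == 9  # round(0.3 * 30)

    def test_holdout_videos_appear_nowhere(self, frame):
        s = _two_class_set(frame)
        train, test, holdout = split_dataset(s, 0.3, holdout_videos=1, seed=2)
        assert len(holdout) == 2  # one per class
        used = set(train.video_ids) | set(test.video_ids)
        assert used.isdisjoint(holdout)
        held_frames = sum(1 for v in s.video_ids if v in holdout)
        assert len(train) + len(test) == len(s) - held_frames

    def test_zero_fraction_empty_test(self, frame):
        s = _two_class_set(frame)
        train, test, _ = split_dataset(s, 0.0, seed=0)
        assert len(test) == 0
        assert len(train) == len(s)

    def test_single_class_rejected(self, frame):
        s = LabelledImageSet()
        s.add(frame, HAS_STENOSIS, "v0")
        with pytest.raises(ValidationError):
            split_dataset(s, 0.3)

    def test_directory_round_trip(self, frame, tmp_path):
        s = _two_class_set(frame, n_videos=2, frames_per_video=2)
        s.save_directory(tmp_path / "imgs")
        back = LabelledImageSet.load_directory(tmp_path / "imgs")
        assert sorted(back.filenames) == sorted(s.filenames)
        assert set(back.video_ids) == set(s.video_ids)
        orig = {n: i for n, i in zip(s.filenames, s.images)}
        assert all((img == orig[n]).all() for n, img in zip(back.filenames, back.images))
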