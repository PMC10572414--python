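"""Shared fixtures: small phantom corpora and domain-shifted datasets.

Everything is generated programmatically at session start; nothing is read
from checked-in data.  The "shifted" pair of datasets realizes a purely
photometric train/validation domain shift: training eyes are rendered with
no brightness/contrast jitter while validation eyes get strong jitter, so
photometric augmentation genuinely closes the gap.
"""

from __future__ import annotations

import numpy as np
import pytest

from octaug import PhantomConfig, generate_phantom
from octaug.augment import ImageMaskPair
from octaug.search import SegDataset


def _load_dataset(dataset, prefix: str) -> SegDataset:
    pairs = [ImageMaskPair(*dataset.load_pair(r)) for r in dataset.records]
    patients = [prefix + r.patient_id for r in dataset.records]
    return SegDataset(pairs, patients)


@pytest.fixture(scope="session")
def phantom_small(tmp_path_factory):
    """2 patients x 1 eye x 25 scans at 64 px, default appearance."""
    cfg = PhantomConfig(n_patients=2, eyes_per_patient=1, scans_per_eye=25,
                        image_size=64, seed=7)
    return generate_phantom(cfg, tmp_path_factory.mktemp("phantom_small"))


@pytest.fixture(scope="session")
def shifted_sets(tmp_path_factory):
    """Photometric-shift pair: clean train set, jittered validation set."""
    root = tmp_path_factory.mktemp("shifted")
    clean = PhantomConfig(n_patients=3, eyes_per_patient=1, scans_per_eye=4,
                          image_size=32, seed=21,
                          brightness_jitter=(0, 0), contrast_jitter=(1, 1))
    jittered = PhantomConfig(n_patients=3, eyes_per_patient=1, scans_per_eye=4,
                             image_size=32, seed=22,
                             brightness_jitter=(-60, 60),
                             contrast_jitter=(0.4, 1.6))
    train = _load_dataset(generate_phantom(clean, root / "train"), "TR-")
    valid = _load_dataset(generate_phantom(jittered, root / "valid"), "VA-")
    return train, valid


@pytest.fixture(scope="session")
def pairs64(phantom_small) -> list[ImageMaskPair]:
    """Eight 64-px image/mask pairs for overfit-style checks."""
    records = phantom_small.records[:8]
    return [ImageMaskPair(*phantom_small.load_pair(r)) for r in records]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
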