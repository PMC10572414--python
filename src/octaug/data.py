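"""Dataset manifest I/O, patient-level nested splits, and model-tensor prep.

The manifest is a CSV with one row per B-scan: ``patient_id, eye,
scan_index, image_path, mask_path``.  Splits are strictly at the patient
level — all scans of both eyes of a patient travel together — so no OCT
volume ever appears on two sides of a partition.  The nested scheme per
fold: the fold itself is the test set (1/k of patients), 12.5% of the
remaining patients form the augmentation-search validation set, and the
rest train the model (70/10/20 of the cohort for k = 5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["ScanRecord", "SplitPlan", "write_manifest", "read_manifest",
           "make_splits", "to_model_input", "mask_to_onehot"]

MANIFEST_COLUMNS = ["patient_id", "eye", "scan_index", "image_path", "mask_path"]


@dataclass(frozen=True)
class ScanRecord:
    patient_id: str
    eye: str
    scan_index: int
    image_path: str
    mask_path: str


def write_manifest(records: list[ScanRecord], path: str | Path):
    frame = pd.DataFrame([vars(r) for r in records], columns=MANIFEST_COLUMNS)
    frame.to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[ScanRecord]:
    frame = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records = [ScanRecord(str(r.patient_id), str(r.eye), int(r.scan_index),
                          str(r.image_path), str(r.mask_path))
               for r in frame.itertuples()]
    keys = [(r.patient_id, r.eye, r.scan_index) for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("manifest contains duplicate (patient, eye, scan) keys")
    return records


@dataclass
class SplitPlan:
    """Per-fold patient assignments: test fold, validation subset, train rest."""

    folds: list[dict[str, list[str]]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.folds)

    def to_json(self) -> str:
        return json.dumps({f"fold_{i}": fold for i, fold in enumerate(self.folds)},
                          indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        doc = json.loads(text)
        return cls([doc[f"fold_{i}"] for i in range(len(doc))])

    def save(self, path: str | Path):
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SplitPlan":
        return cls.from_json(Path(path).read_text())


def make_splits(records: list[ScanRecord], k: int = 5,
                valid_fraction_of_training: float = 0.125,
                seed: int = 0) -> SplitPlan:
    """Patient-level k-fold plan with a nested validation subset.

    Patients are shuffled once under the seed and dealt into k folds of
    near-equal size.  For each fold, the validation set is a rounded
    ``valid_fraction_of_training`` share of the non-test patients.
    """
    patients = sorted({r.patient_id for r in records})
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients, have {len(patients)}")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    fold_members = [order[i::k] for i in range(k)]

    folds = []
    for i in range(k):
        test = sorted(fold_members[i])
        rest = [p for p in order if p not in fold_members[i]]
        n_valid = int(round(valid_fraction_of_training * len(rest)))
        if valid_fraction_of_training > 0 and len(rest) > 1:
            n_valid = min(max(n_valid, 1), len(rest) - 1)
        valid = sorted(rest[:n_valid])
        train = sorted(rest[n_valid:])
        folds.append({"train": train, "valid": valid, "test": test})
    return SplitPlan(folds)


def mask_to_onehot(mask: np.ndarray) -> np.ndarray:
    """Binary (H, W) mask -> one-hot (2, H, W); channel 1 is the cavity."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    return np.stack([(mask == 0), (mask == 1)]).astype(np.float64)


def _resize_with_padding(img: Image.Image, target: int, resample
                         ) -> tuple[Image.Image, dict]:
    w, h = img.size
    scale = target / max(w, h)
    nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
    resized = img.resize((nw, nh), resample=resample)
    canvas = Image.new("L", (target, target), 0)
    canvas.paste(resized, (0, 0))
    meta = {"scale": scale, "resized": (nw, nh), "pad_right": target - nw,
            "pad_bottom": target - nh}
    return canvas, meta


def to_model_input(record: ScanRecord, target_size: int = 512,
                   return_meta: bool = False):
    """Load one scan as model tensors.

    Returns the grayscale image as (1, H, W) floats in [0, 1] and the mask
    as a one-hot (2, H, W) array.  Images are resized aspect-preserved with
    zero padding on the right/bottom; the mask uses nearest-neighbour
    resampling.  ``return_meta`` additionally yields the scale/padding used,
    for mapping predictions back to native coordinates.
    """
    img = Image.open(record.image_path).convert("L")
    mask_img = Image.open(record.mask_path)
    mask_arr = (np.asarray(mask_img) > 0).astype(np.uint8)
    raw = np.asarray(mask_img)
    if not np.isin(np.unique(raw), (0, 1, 255)).all():
        raise ValueError(f"mask {record.mask_path} has values outside {{0, 1}}")
    mask_img = Image.fromarray(mask_arr, mode="L")

    if img.size != mask_img.size:
        raise ValueError("image/mask dimensions differ")
    img_t, meta = _resize_with_padding(img, target_size, Image.BILINEAR)
    mask_t, _ = _resize_with_padding(mask_img, target_size, Image.NEAREST)

    image = np.asarray(img_t, dtype=np.float64)[None] / 255.0
    onehot = mask_to_onehot(np.asarray(mask_t))
    if return_meta:
        return image, onehot, meta
    return image, onehot
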