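"""Synthetic OCT phantom: a layered-retina corpus with ground-truth masks.

Emulates the structure of a clinical retinoschisis OCT cohort — patients x
eyes x 25 consecutive B-scans — without any clinical data.  Each eye is a
small 3-D scene rendered scan by scan:

* a smooth retinal band (bright layered tissue on a dark vitreous/choroid
  background) with a foveal dip and gentle column-wise undulation;
* 1-4 hypo-reflective schisis cavities modelled as 3-D ellipsoids spanning
  several consecutive scans, so adjacent scans show coherent, smoothly
  evolving cross-sections (the coherence the annotation protocol for real
  cavities relies on);
* multiplicative speckle noise (gamma-distributed multi-look model),
  spatially smoothed to mimic correlated OCT speckle;
* occasional dark vertical vessel shadows;
* a per-acquisition (per-eye) brightness offset and contrast gain,
  emulating device/operator variability between sessions.

Masks mark cavity pixels.  What the phantom does *not* emulate: real
layer-by-layer reflectivity profiles, motion artifacts, or pathology other
than cavities; conclusions drawn on it are structural, not clinical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .data import ScanRecord, write_manifest

__all__ = ["PhantomConfig", "PhantomDataset", "generate_phantom"]


@dataclass(frozen=True)
class PhantomConfig:
    n_patients: int = 30
    eyes_per_patient: int = 2
    scans_per_eye: int = 25
    image_size: int = 512
    # retina geometry, as fractions of image height
    retina_top: float = 0.30
    retina_thickness: float = 0.38
    fovea_dip: float = 0.06
    # cavities
    cavity_count_range: tuple[int, int] = (1, 4)
    cavity_rx_range: tuple[float, float] = (0.05, 0.16)   # fraction of width
    cavity_ry_range: tuple[float, float] = (0.04, 0.10)   # fraction of height
    coherence_halfwidth: float = 9.0   # cavity extent along the scan axis, scans
    # appearance
    speckle_strength: float = 0.25
    vessel_shadow_rate: float = 0.4
    brightness_jitter: tuple[float, float] = (-20.0, 20.0)
    contrast_jitter: tuple[float, float] = (0.8, 1.2)
    # photometric jitter applied to *every* eye; set False to restrict it to
    # a subset (used to create train/validation appearance shifts)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_patients", "eyes_per_patient", "scans_per_eye", "image_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("cavity_count_range", "brightness_jitter", "contrast_jitter"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be a valid (lo, hi) interval")


@dataclass
class PhantomDataset:
    root: Path
    records: list[ScanRecord] = field(default_factory=list)

    @property
    def manifest_path(self) -> Path:
        return self.root / "manifest.csv"

    def load_pair(self, record: ScanRecord) -> tuple[np.ndarray, np.ndarray]:
        image = np.asarray(Image.open(record.image_path).convert("L"))
        mask = np.asarray(Image.open(record.mask_path))
        return image, (mask > 0).astype(np.uint8)


@dataclass
class _Cavity:
    cx: float       # column, fraction of width
    cy: float       # depth within the retina band, fraction of thickness
    rx: float
    ry: float
    s0: float       # central scan index
    rs: float       # half-extent along the scan axis, scans
    drift: float    # column drift per scan, fraction of width


def _eye_scene(cfg: PhantomConfig, rng: np.random.Generator) -> dict:
    n_cav = int(rng.integers(cfg.cavity_count_range[0], cfg.cavity_count_range[1] + 1))
    cavities = []
    for _ in range(n_cav):
        cavities.append(_Cavity(
            cx=float(rng.uniform(0.2, 0.8)),
            cy=float(rng.uniform(0.3, 0.7)),
            rx=float(rng.uniform(*cfg.cavity_rx_range)),
            ry=float(rng.uniform(*cfg.cavity_ry_range)),
            s0=float(rng.uniform(0.25, 0.75) * (cfg.scans_per_eye - 1)),
            rs=float(cfg.coherence_halfwidth * rng.uniform(0.7, 1.3)),
            drift=float(rng.normal(0.0, 0.002)),
        ))
    return {
        "cavities": cavities,
        "undulation_phase": float(rng.uniform(0, 2 * np.pi)),
        "undulation_amp": float(rng.uniform(0.0, 0.03)),
        "brightness": float(rng.uniform(*cfg.brightness_jitter)),
        "contrast": float(rng.uniform(*cfg.contrast_jitter)),
        "layer_gains": rng.uniform(0.75, 1.25, size=6),
    }


# relative reflectivity of the stacked retinal layers, vitreous to choroid
_LAYER_FRACTIONS = np.array([0.10, 0.12, 0.22, 0.16, 0.22, 0.18])
_LAYER_INTENSITY = np.array([190.0, 120.0, 90.0, 130.0, 95.0, 200.0])


def render_scan(cfg: PhantomConfig, scene: dict, scan_index: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render one B-scan and its cavity mask from an eye scene."""
    size = cfg.image_size
    xs = np.arange(size) / size
    ys = np.arange(size) / size

    # retinal band geometry: foveal dip + gentle undulation
    top = (cfg.retina_top
           + cfg.fovea_dip * np.exp(-((xs - 0.5) ** 2) / (2 * 0.08**2))
           + scene["undulation_amp"] * np.sin(2 * np.pi * xs + scene["undulation_phase"]))
    thickness = cfg.retina_thickness

    depth = (ys[:, None] - top[None, :]) / thickness  # 0 at top, 1 at bottom
    img = np.full((size, size), 18.0)
    bounds = np.concatenate([[0.0], np.cumsum(_LAYER_FRACTIONS)])
    for li in range(len(_LAYER_FRACTIONS)):
        sel = (depth >= bounds[li]) & (depth < bounds[li + 1])
        img[sel] = _LAYER_INTENSITY[li] * scene["layer_gains"][li]

    # cavities: ellipsoid cross-sections at this scan index
    mask = np.zeros((size, size), dtype=np.uint8)
    yy = ys[:, None]
    xx = xs[None, :]
    for cav in scene["cavities"]:
        u = (scan_index - cav.s0) / cav.rs
        if abs(u) >= 1.0:
            continue
        scale = np.sqrt(1.0 - u * u)
        cx = cav.cx + cav.drift * (scan_index - cav.s0)
        cy_abs = top[np.clip(int(cx * size), 0, size - 1)] + cav.cy * thickness
        rx, ry = cav.rx * scale, cav.ry * scale
        if rx * size < 1.5 or ry * size < 1.5:
            continue
        inside = ((xx - cx) / rx) ** 2 + ((yy - cy_abs) / ry) ** 2 <= 1.0
        inside &= (depth >= 0.02) & (depth <= 0.98)  # keep within the band
        img[inside] *= 0.22
        mask |= inside.astype(np.uint8)

    # vessel shadows: dark vertical streaks through the tissue
    if rng.random() < cfg.vessel_shadow_rate:
        for _ in range(int(rng.integers(1, 4))):
            x0 = rng.uniform(0.1, 0.9)
            wdt = rng.uniform(0.008, 0.02)
            profile = 1.0 - 0.55 * np.exp(-((xs - x0) ** 2) / (2 * wdt**2))
            img *= np.where(depth > 0.05, profile[None, :], 1.0)

    # correlated multiplicative speckle
    looks = max(1.0 / max(cfg.speckle_strength, 1e-6) ** 2, 1.0)
    speckle = rng.gamma(shape=looks, scale=1.0 / looks, size=img.shape)
    speckle = gaussian_filter(speckle, sigma=0.8)
    img *= speckle

    # per-acquisition brightness/contrast
    img = (img - 128.0) * scene["contrast"] + 128.0 + scene["brightness"]
    return np.clip(img, 0, 255).astype(np.uint8), mask


def generate_phantom(config: PhantomConfig, out_dir: str | Path) -> PhantomDataset:
    """Render the full corpus to ``out_dir`` and write its manifest."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    records: list[ScanRecord] = []
    for p in range(config.n_patients):
        pid = f"P{p + 1:03d}"
        for e in range(config.eyes_per_patient):
            eye = ("OD", "OS")[e % 2]
            scene = _eye_scene(config, rng)
            eye_dir = root / pid / eye
            eye_dir.mkdir(parents=True, exist_ok=True)
            for s in range(config.scans_per_eye):
                img, mask = render_scan(config, scene, s, rng)
                img_path = eye_dir / f"scan_{s:02d}.png"
                mask_path = eye_dir / f"mask_{s:02d}.png"
                Image.fromarray(img, mode="L").save(img_path)
                Image.fromarray(mask, mode="L").save(mask_path)
                records.append(ScanRecord(pid, eye, s, str(img_path), str(mask_path)))
    dataset = PhantomDataset(root=root, records=records)
    write_manifest(records, dataset.manifest_path)
    return dataset
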