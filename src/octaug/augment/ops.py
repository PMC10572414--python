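"""The 16 image transformations of the augmentation search space.

Each operation carries a name, a geometric/photometric category and, for
the eleven magnitude-bearing operations, a native-unit magnitude range that
is discretized into ten equally spaced levels.  Application probability is
discretized into eleven levels (0.0, 0.1, ..., 1.0).  Operations are the
classic PIL transformation set: shears and translations along both axes,
rotation, flips, and the PIL photometric enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OpSpec", "OP_TABLE", "OP_NAMES", "GEOMETRIC_OPS", "PHOTOMETRIC_OPS",
    "get_op_spec", "magnitude_value", "NUM_OPS", "NUM_MAGNITUDE_LEVELS",
    "NUM_PROBABILITY_LEVELS",
]

NUM_OPS = 16
NUM_MAGNITUDE_LEVELS = 10   # levels 0..9 across the magnitude range
NUM_PROBABILITY_LEVELS = 11  # levels 0..10 -> probabilities 0.0..1.0


@dataclass(frozen=True)
class OpSpec:
    """Static description of one transformation."""

    name: str
    has_magnitude: bool
    magnitude_range: tuple[float, float] | None
    category: str  # "geometric" | "photometric"


_SPECS = [
    # geometric, signed ranges discretized across the full range
    OpSpec("ShearX", True, (-0.3, 0.3), "geometric"),
    OpSpec("ShearY", True, (-0.3, 0.3), "geometric"),
    OpSpec("TranslateX", True, (-150.0, 150.0), "geometric"),
    OpSpec("TranslateY", True, (-150.0, 150.0), "geometric"),
    OpSpec("Rotate", True, (-30.0, 30.0), "geometric"),
    OpSpec("HorizontalFlip", False, None, "geometric"),
    OpSpec("VerticalFlip", False, None, "geometric"),
    # photometric
    OpSpec("Color", True, (0.1, 0.9), "photometric"),
    OpSpec("Posterize", True, (4.0, 8.0), "photometric"),
    OpSpec("Solarize", True, (0.0, 256.0), "photometric"),
    OpSpec("Contrast", True, (0.0, 0.9), "photometric"),
    OpSpec("Sharpness", True, (0.0, 0.9), "photometric"),
    OpSpec("Brightness", True, (0.0, 0.9), "photometric"),
    OpSpec("AutoContrast", False, None, "photometric"),
    OpSpec("Equalize", False, None, "photometric"),
    OpSpec("Invert", False, None, "photometric"),
]

OP_TABLE: dict[str, OpSpec] = {s.name: s for s in _SPECS}
OP_NAMES: list[str] = [s.name for s in _SPECS]
GEOMETRIC_OPS = frozenset(s.name for s in _SPECS if s.category == "geometric")
PHOTOMETRIC_OPS = frozenset(s.name for s in _SPECS if s.category == "photometric")

assert len(OP_TABLE) == NUM_OPS

_ALIASES = {"horizontal flip": "HorizontalFlip", "vertical flip": "VerticalFlip"}


def _canonical(name: str) -> str:
    key = name.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    for canon in OP_TABLE:
        if canon.lower() == key.replace(" ", "").replace("_", ""):
            return canon
    raise KeyError(name)


def get_op_spec(name: str) -> OpSpec:
    """Look up an operation by name (case/space-insensitive)."""
    try:
        return OP_TABLE[_canonical(name)]
    except KeyError:
        raise ValueError(f"unknown operation name: {name!r}") from None


def magnitude_value(op_name: str, magnitude_level: int | None) -> float | None:
    """Map a discrete magnitude level to the operation's native units.

    Level ``l`` in 0..9 maps linearly across the printed range:
    ``min + l * (max - min) / 9``.  Operations without a magnitude return
    ``None``.  A ``None`` level on a magnitude-bearing operation (seen in
    published policies) falls back to the range midpoint.  Posterize is
    rounded to an integer bit count.
    """
    spec = get_op_spec(op_name)
    if not spec.has_magnitude:
        return None
    lo, hi = spec.magnitude_range
    if magnitude_level is None:
        value = 0.5 * (lo + hi)
    else:
        if not 0 <= magnitude_level <= NUM_MAGNITUDE_LEVELS - 1:
            raise ValueError(
                f"magnitude_level {magnitude_level} outside [0, {NUM_MAGNITUDE_LEVELS - 1}]"
            )
        value = lo + magnitude_level * (hi - lo) / (NUM_MAGNITUDE_LEVELS - 1)
    if spec.name == "Posterize":
        value = float(round(value))
    return value
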