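"""The 16-operation search space and mask-consistent application."""

import json
from pathlib import Path

import numpy as np
import pytest

from octaug.augment import (GEOMETRIC_OPS, NUM_OPS, OP_NAMES, OP_TABLE,
                            PHOTOMETRIC_OPS, ImageMaskPair, OpInstance,
                            Strategy, SubStrategy, apply_op, apply_strategy,
                            apply_substrategy, get_op_spec, load_strategy,
                            magnitude_value, parse_strategy, serialize_strategy)
from octaug.augment.strategy import PolicyParseError

POLICY_PATH = Path(__file__).resolve().parents[1] / "policies" / "unetpp_consolidated.json"


# ---------------------------------------------------------------- op specs
def test_operation_table_matches_published_grid():
    assert len(OP_TABLE) == NUM_OPS == 16
    expected_ranges = {
        "ShearX": (-0.3, 0.3), "ShearY": (-0.3, 0.3),
        "TranslateX": (-150.0, 150.0), "TranslateY": (-150.0, 150.0),
        "Rotate": (-30.0, 30.0), "Color": (0.1, 0.9), "Posterize": (4.0, 8.0),
        "Solarize": (0.0, 256.0), "Contrast": (0.0, 0.9),
        "Sharpness": (0.0, 0.9), "Brightness": (0.0, 0.9),
    }
    for name, rng_ in expected_ranges.items():
        spec = get_op_spec(name)
        assert spec.has_magnitude and spec.magnitude_range == rng_
    for name in ("AutoContrast", "Equalize", "Invert", "HorizontalFlip",
                 "VerticalFlip"):
        assert not get_op_spec(name).has_magnitude
    assert GEOMETRIC_OPS == {"ShearX", "ShearY", "TranslateX", "TranslateY",
                             "Rotate", "HorizontalFlip", "VerticalFlip"}
    assert GEOMETRIC_OPS | PHOTOMETRIC_OPS == set(OP_NAMES)


@pytest.mark.parametrize("op,level,expected", [
    ("Rotate", 0, -30.0),          # level 0 maps to the range minimum
    ("Rotate", 9, 30.0),
    ("Contrast", 9, 0.9),
    ("TranslateX", 6, 50.0),
    ("Solarize", 0, 0.0),
])
def test_magnitude_levels_map_linearly(op, level, expected):
    assert magnitude_value(op, level) == pytest.approx(expected)


def test_posterize_levels_round_to_integer_bits():
    # hand-computed: 4 + l*4/9 rounded for l = 0..9
    assert [magnitude_value("Posterize", l) for l in range(10)] == \
        [4, 4, 5, 5, 6, 6, 7, 7, 8, 8]


def test_magnitude_free_ops_return_none():
    assert magnitude_value("AutoContrast", 5) is None
    assert magnitude_value("Invert", None) is None


def test_unknown_op_name_raises():
    with pytest.raises(ValueError, match="unknown operation"):
        magnitude_value("Twirl", 3)


# ----------------------------------------------------------- apply_op core
def _square_pair(size=96):
    mask = np.zeros((size, size), np.uint8)
    mask[30:55, 40:70] = 1
    return ImageMaskPair((mask * 255).astype(np.uint8), mask)


def test_zero_probability_returns_input_bit_exact(rng):
    pair = _square_pair()
    for name in OP_NAMES:
        out = apply_op(pair, OpInstance(name, 9, 0), rng)
        assert out is pair


def test_output_conserves_shape_and_binary_mask(rng):
    pair = _square_pair()
    for name in OP_NAMES:
        out = apply_op(pair, OpInstance(name, 7, 10), rng)
        assert out.image.shape == pair.image.shape
        assert set(np.unique(out.mask)) <= {0, 1}
        assert out.image.dtype == np.uint8


def test_geometric_ops_move_mask_with_image(rng):
    """Thresholding a transformed indicator image reproduces the
    transformed mask (exact for flips/integer translations, Dice >= 0.99
    for interpolating ops)."""
    pair = _square_pair()
    for name in sorted(GEOMETRIC_OPS):
        out = apply_op(pair, OpInstance(name, 7, 10), np.random.default_rng(1))
        thresholded = (out.image > 128).astype(np.uint8)
        inter = int((thresholded & out.mask).sum())
        total = int(thresholded.sum() + out.mask.sum())
        dice = 1.0 if total == 0 else 2 * inter / total
        if name in ("HorizontalFlip", "VerticalFlip"):
            assert np.array_equal(thresholded, out.mask)
        else:
            assert dice >= 0.99, f"{name}: dice {dice}"


def test_photometric_ops_leave_mask_bit_exact(rng):
    pair = _square_pair()
    for name in sorted(PHOTOMETRIC_OPS):
        out = apply_op(pair, OpInstance(name, 5, 10), np.random.default_rng(2))
        assert np.array_equal(out.mask, pair.mask), name


def test_translate_moves_single_pixel_by_native_magnitude(rng):
    img = np.zeros((512, 512), np.uint8)
    mask = np.zeros((512, 512), np.uint8)
    img[100, 200] = 255
    mask[100, 200] = 1
    out = apply_op(ImageMaskPair(img, mask), OpInstance("TranslateX", 6, 10), rng)
    # level 6 -> +50 px at native 512-px width; vacated region is background
    assert np.argwhere(out.mask).tolist() == [[100, 250]]
    assert out.mask.sum() == 1


def test_horizontal_flip_is_involution(rng):
    pair = _square_pair()
    op = OpInstance("HorizontalFlip", None, 10)
    out = apply_op(apply_op(pair, op, rng), op, rng)
    assert np.array_equal(out.image, pair.image)
    assert np.array_equal(out.mask, pair.mask)


def test_application_frequency_matches_probability_level():
    """Empirical firing rate of phi = 0.3 within 3 binomial SEs over 10k
    seeded trials."""
    pair = ImageMaskPair(np.full((16, 16), 100, np.uint8),
                         np.zeros((16, 16), np.uint8))
    op = OpInstance("Invert", None, 3)
    rng = np.random.default_rng(42)
    n = 10_000
    fired = sum(not np.array_equal(apply_op(pair, op, rng).image, pair.image)
                for _ in range(n))
    p = 0.3
    se = np.sqrt(p * (1 - p) / n)
    assert abs(fired / n - p) < 3 * se


def test_identical_seeds_give_identical_outputs():
    pair = _square_pair()
    op = OpInstance("Rotate", 8, 5)
    a = apply_op(pair, op, np.random.default_rng(9))
    b = apply_op(pair, op, np.random.default_rng(9))
    assert np.array_equal(a.image, b.image) and np.array_equal(a.mask, b.mask)


def test_invalid_pairs_are_rejected():
    with pytest.raises(ValueError, match="binary"):
        ImageMaskPair(np.zeros((4, 4), np.uint8), np.full((4, 4), 2, np.uint8))
    with pytest.raises(ValueError, match="shape"):
        ImageMaskPair(np.zeros((4, 4), np.uint8), np.zeros((4, 5), np.uint8))


# ------------------------------------------------------------ sub-strategy
def test_substrategy_composes_single_op_reference_outputs(rng):
    """Equalize then Invert at phi = 1 equals invert(equalize(image))."""
    image = (np.arange(64 * 64) % 251).reshape(64, 64).astype(np.uint8)
    pair = ImageMaskPair(image, np.zeros((64, 64), np.uint8))
    sub = SubStrategy(OpInstance("Equalize", None, 10),
                      OpInstance("Invert", None, 10))
    composed = apply_substrategy(pair, sub, rng)
    step1 = apply_op(pair, OpInstance("Equalize", None, 10),
                     np.random.default_rng(0))
    step2 = apply_op(step1, OpInstance("Invert", None, 10),
                     np.random.default_rng(0))
    assert np.array_equal(composed.image, step2.image)
    assert np.array_equal(composed.mask, pair.mask)


def test_identity_substrategy_is_identity(rng):
    pair = _square_pair()
    sub = SubStrategy(OpInstance("Rotate", 9, 0), OpInstance("Invert", None, 0))
    assert apply_substrategy(pair, sub, rng) is pair


# ---------------------------------------------------------------- strategy
def _identity_strategy():
    sub = SubStrategy(OpInstance("Invert", None, 0), OpInstance("Invert", None, 0))
    return Strategy([sub] * 5)


def test_identity_strategy_returns_input_bit_exact(rng):
    pair = _square_pair()
    out = apply_strategy(pair, _identity_strategy(), rng)
    assert np.array_equal(out.image, pair.image)


def test_empty_strategy_is_rejected(rng):
    with pytest.raises(ValueError, match="empty"):
        apply_strategy(_square_pair(), Strategy([]), rng)


def test_strategy_application_is_seed_reproducible():
    pair = _square_pair()
    strategy = load_strategy(POLICY_PATH)
    a = apply_strategy(pair, strategy, np.random.default_rng(5))
    b = apply_strategy(pair, strategy, np.random.default_rng(5))
    assert np.array_equal(a.image, b.image) and np.array_equal(a.mask, b.mask)


def test_singleton_strategy_matches_substrategy_distribution():
    """A 1-sub-strategy strategy equals direct sub-strategy application
    draw for draw over 1000 seeded trials."""
    pair = _square_pair()
    sub = SubStrategy(OpInstance("Brightness", 8, 5), OpInstance("Rotate", 2, 5))
    strategy = Strategy([sub])
    rng_a = np.random.default_rng(3)
    rng_b = np.random.default_rng(3)
    matches = 0
    for _ in range(1000):
        rng_a.integers(0, 1)  # the (deterministic) selection draw
        a = apply_substrategy(pair, sub, rng_a)
        b = apply_strategy(pair, strategy, rng_b)
        matches += np.array_equal(a.image, b.image)
    assert matches == 1000


# ------------------------------------------------------------ serialization
def test_serialize_parse_round_trip():
    strategy = load_strategy(POLICY_PATH)
    doc = serialize_strategy(strategy)
    again = serialize_strategy(parse_strategy(doc))
    assert json.loads(doc) == json.loads(again)


def test_shipped_policy_parses_to_25_substrategies():
    strategy = load_strategy(POLICY_PATH)
    assert len(strategy) == 25
    first = strategy.substrategies[0]
    assert first.first == OpInstance("Sharpness", 2, 5)
    assert first.second == OpInstance("AutoContrast", None, 4)
    assert first.first.probability == pytest.approx(0.5)


def test_parse_rejects_out_of_range_probability():
    with pytest.raises(PolicyParseError, match="sub-strategy 1"):
        parse_strategy('[[["Rotate", 3, 11], ["Invert", null, 2]]]')


def test_parse_rejects_unknown_op():
    with pytest.raises(PolicyParseError):
        parse_strategy('[[["Swirl", 3, 1], ["Invert", null, 2]]]')
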