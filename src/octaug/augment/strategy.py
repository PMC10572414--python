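"""Strategy data structures and their JSON serialization.

A *sub-strategy* is an ordered pair of transformation instances; a
*strategy* is an ordered list of sub-strategies — five when sampled by the
controller, twenty-five after consolidating the top five searched
strategies.  The on-disk policy document is a JSON list of sub-strategies,
each a 2-element list of ``[op_name, magnitude_level, probability_level]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .ops import (NUM_MAGNITUDE_LEVELS, NUM_PROBABILITY_LEVELS, get_op_spec,
                  magnitude_value)

__all__ = [
    "OpInstance", "SubStrategy", "Strategy",
    "serialize_strategy", "parse_strategy",
    "save_strategy", "load_strategy",
]


@dataclass(frozen=True)
class OpInstance:
    """One transformation with its discrete magnitude and probability levels.

    ``magnitude_level`` may be ``None``: for magnitude-free operations it is
    simply ignored, and for magnitude-bearing ones the native value falls
    back to the range midpoint (some published policies omit the level).
    """

    op: str
    magnitude_level: int | None
    probability_level: int

    def __post_init__(self):
        spec = get_op_spec(self.op)  # raises on unknown name
        object.__setattr__(self, "op", spec.name)
        if self.magnitude_level is not None and not (
                0 <= self.magnitude_level <= NUM_MAGNITUDE_LEVELS - 1):
            raise ValueError(f"magnitude_level {self.magnitude_level} out of range")
        if not 0 <= self.probability_level <= NUM_PROBABILITY_LEVELS - 1:
            raise ValueError(f"probability_level {self.probability_level} out of range")

    @property
    def probability(self) -> float:
        return self.probability_level / (NUM_PROBABILITY_LEVELS - 1)

    @property
    def magnitude(self) -> float | None:
        return magnitude_value(self.op, self.magnitude_level)


@dataclass(frozen=True)
class SubStrategy:
    """Two transformations applied in order."""

    first: OpInstance
    second: OpInstance

    def __iter__(self):
        yield self.first
        yield self.second


@dataclass
class Strategy:
    """Ordered list of sub-strategies; the unit the controller searches over."""

    substrategies: list[SubStrategy] = field(default_factory=list)

    def __len__(self):
        return len(self.substrategies)

    def __iter__(self):
        return iter(self.substrategies)

    def op_names(self) -> list[str]:
        return [op.op for sub in self.substrategies for op in sub]


def _op_to_list(op: OpInstance) -> list:
    return [op.op, op.magnitude_level, op.probability_level]


def serialize_strategy(strategy: Strategy) -> str:
    """Render a strategy as a human-readable JSON policy document."""
    doc = [[_op_to_list(sub.first), _op_to_list(sub.second)]
           for sub in strategy.substrategies]
    return json.dumps(doc, indent=1)


class PolicyParseError(ValueError):
    pass


def _parse_op(entry, where: str) -> OpInstance:
    if not isinstance(entry, (list, tuple)) or len(entry) != 3:
        raise PolicyParseError(f"{where}: expected [op, magnitude_level, "
                               f"probability_level], got {entry!r}")
    name, lvl, plvl = entry
    try:
        return OpInstance(str(name), None if lvl is None else int(lvl), int(plvl))
    except (ValueError, TypeError) as exc:
        raise PolicyParseError(f"{where}: {exc}") from exc


def parse_strategy(document: str) -> Strategy:
    """Parse a JSON policy document; arbitrary lengths are accepted."""
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise PolicyParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, list):
        raise PolicyParseError("policy document must be a JSON list")
    subs = []
    for i, sub in enumerate(doc):
        where = f"sub-strategy {i + 1}"
        if not isinstance(sub, list) or len(sub) != 2:
            raise PolicyParseError(f"{where}: expected exactly two operations")
        subs.append(SubStrategy(_parse_op(sub[0], where + ", op 1"),
                                _parse_op(sub[1], where + ", op 2")))
    return Strategy(subs)


def save_strategy(strategy: Strategy, path: str | Path):
    Path(path).write_text(serialize_strategy(strategy) + "\n")


def load_strategy(path: str | Path) -> Strategy:
    return parse_strategy(Path(path).read_text())
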