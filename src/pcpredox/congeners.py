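"""Chlorophenol congener bookkeeping and dechlorination pathway inference.

A congener is identified by the set of ring positions bearing chlorine,
with the phenolic hydroxyl fixed at position 1.  Positions 2 and 6 are
*ortho*, 3 and 5 *meta*, and 4 *para* relative to the hydroxyl.  Reductive
dechlorination removes one chlorine per step, so an observed metabolite
chain such as

    PCP -> 2,3,4,5-TeCP -> 3,4,5-TCP -> 3,5-DCP -> 3-CP

maps to a sequence of removed positions and their classes
(here: ortho, ortho, para, meta).

Symmetry-equivalent position sets (e.g. {2,3,4,5} and its mirror
{2,3,4,6}) are deliberately NOT merged: congeners are named literally so
that 2,3,4,5-TeCP and 2,3,4,6-TeCP remain distinct analytes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pcpredox.errors import InvalidPositionError, NotADechlorinationStepError

__all__ = [
    "Congener",
    "PathwayStep",
    "PCP",
    "PHENOL",
    "position_class",
    "canonical_name",
    "parse_name",
    "infer_step",
    "infer_pathway",
    "order_by_first_detection",
]

VALID_POSITIONS = frozenset({2, 3, 4, 5, 6})

_SUFFIX = {1: "CP", 2: "DCP", 3: "TCP", 4: "TeCP"}
_SUFFIX_COUNT = {v: n for n, v in _SUFFIX.items()}

_ORTHO = frozenset({2, 6})
_META = frozenset({3, 5})


def position_class(position: int) -> str:
    """Classify a ring position relative to the hydroxyl at position 1.

    2, 6 -> ``"ortho"``; 3, 5 -> ``"meta"``; 4 -> ``"para"``.
    """
    if position in _ORTHO:
        return "ortho"
    if position in _META:
        return "meta"
    if position == 4:
        return "para"
    raise InvalidPositionError(
        f"ring position must be one of {{2,3,4,5,6}}, got {position!r}"
    )


def canonical_name(positions: Iterable[int]) -> str:
    """Canonical name for a chlorine position set.

    ``{2,3,4,5,6}`` -> ``"PCP"``, ``{}`` -> ``"phenol"``, otherwise
    sorted positions joined by commas plus a count suffix, e.g.
    ``{3,4,5}`` -> ``"3,4,5-TCP"``.
    """
    pos = frozenset(positions)
    if not pos <= VALID_POSITIONS:
        bad = sorted(pos - VALID_POSITIONS)
        raise InvalidPositionError(f"invalid ring positions: {bad}")
    n = len(pos)
    if n == 0:
        return "phenol"
    if n == 5:
        return "PCP"
    locants = ",".join(str(p) for p in sorted(pos))
    return f"{locants}-{_SUFFIX[n]}"


_NAME_RE = re.compile(r"^(\d(?:,\d)*)-(CP|DCP|TCP|TeCP)$")


def parse_name(name: str) -> frozenset[int]:
    """Inverse of :func:`canonical_name`."""
    s = name.strip()
    if s.lower() == "phenol":
        return frozenset()
    if s.upper() == "PCP":
        return frozenset(VALID_POSITIONS)
    m = _NAME_RE.match(s)
    if not m:
        raise InvalidPositionError(f"unrecognised congener name: {name!r}")
    positions = frozenset(int(p) for p in m.group(1).split(","))
    if not positions <= VALID_POSITIONS:
        raise InvalidPositionError(f"invalid ring positions in {name!r}")
    if len(positions) != _SUFFIX_COUNT[m.group(2)]:
        raise InvalidPositionError(
            f"{name!r}: locant count does not match suffix {m.group(2)}"
        )
    return positions


@dataclass(frozen=True)
class Congener:
    """A chlorophenol congener, identified by its chlorine positions."""

    positions: frozenset[int]

    def __post_init__(self) -> None:
        pos = frozenset(self.positions)
        if not pos <= VALID_POSITIONS:
            raise InvalidPositionError(
                f"invalid ring positions: {sorted(pos - VALID_POSITIONS)}"
            )
        object.__setattr__(self, "positions", pos)

    @classmethod
    def from_name(cls, name: str) -> "Congener":
        return cls(parse_name(name))

    @property
    def name(self) -> str:
        return canonical_name(self.positions)

    @property
    def n_chlorines(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:
        return self.name


PCP = Congener(frozenset({2, 3, 4, 5, 6}))
PHENOL = Congener(frozenset())


@dataclass(frozen=True)
class PathwayStep:
    """One dechlorination step: parent loses exactly one chlorine."""

    parent: Congener
    child: Congener
    removed_position: int
    position_class: str


def infer_step(parent: Congener, child: Congener) -> PathwayStep:
    """Identify the chlorine removed between two congeners.

    Succeeds iff ``child.positions`` is a subset of ``parent.positions``
    with exactly one element missing.
    """
    diff = parent.positions - child.positions
    if not (child.positions < parent.positions and len(diff) == 1):
        raise NotADechlorinationStepError(
            f"{parent.name} -> {child.name} is not a single "
            "chlorine-removal step"
        )
    (removed,) = diff
    return PathwayStep(parent, child, removed, position_class(removed))


def infer_pathway(chain: Sequence[Congener]) -> list[PathwayStep]:
    """Resolve an ordered congener chain into dechlorination steps.

    For the chain PCP -> 2,3,4,5-TeCP -> 3,4,5-TCP -> 3,5-DCP -> 3-CP the
    class sequence is [ortho, ortho, para, meta].
    """
    steps = []
    for parent, child in zip(chain, chain[1:]):
        try:
            steps.append(infer_step(parent, child))
        except NotADechlorinationStepError as exc:
            raise NotADechlorinationStepError(
                f"invalid consecutive pair {parent.name} -> {child.name}"
            ) from exc
    return steps


def order_by_first_detection(
    detections: Mapping[str, tuple],
    threshold: float = 1.0,
) -> list[Congener]:
    """Order congeners by the first time they exceed a detection threshold.

    Parameters
    ----------
    detections
        Map of congener name -> (times, values) arrays.
    threshold
        Detection limit in the series unit (default 1 µM).

    Returns
    -------
    Congeners sorted by first-detection time; ties broken by descending
    chlorine count (a parent is detected no later than its product).
    Congeners never exceeding the threshold are omitted.
    """
    first: list[tuple[float, int, Congener]] = []
    for name, (times, values) in detections.items():
        cong = Congener.from_name(name)
        for t, v in zip(times, values):
            if v >= threshold:
                first.append((float(t), -cong.n_chlorines, cong))
                break
    first.sort(key=lambda item: (item[0], item[1]))
    return [cong for _, _, cong in first]
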