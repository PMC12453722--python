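"""Alteration ruleset for eight-directional (F8) chain codes.

Each alteration rewrites one consecutive symbol pair into a replacement
segment of 0-3 symbols whose net displacement equals that of the pair,
so loops stay closed and path endpoints stay fixed.  Seven concrete
alterations exist (REMOVE, PUSH, WRAP, FLIP, PULL, CUT, ROTATE); two
dispatch classes are composites that resolve to one of two concrete
rules by a fair coin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class AlterationKind(Enum):
    REMOVE = "REMOVE"
    PUSH = "PUSH"
    WRAP = "WRAP"
    FLIP = "FLIP"
    PULL = "PULL"
    CUT = "CUT"
    ROTATE = "ROTATE"
    # Dispatch-level composites; resolved to a concrete kind before application.
    FLIP_OR_CUT = "FLIP_OR_CUT"
    ROTATE_OR_CUT = "ROTATE_OR_CUT"

    @property
    def is_composite(self) -> bool:
        return self in (AlterationKind.FLIP_OR_CUT, AlterationKind.ROTATE_OR_CUT)


@dataclass(frozen=True)
class AlterationResult:
    """Replacement segment for one symbol pair plus the rule that produced it."""

    replacement: tuple[int, ...]
    kind: AlterationKind
    branch: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind.is_composite:
            raise ValueError("AlterationResult kind must be concrete")
        # F8 replacements span 0-3 symbols; the F4 U-turn WRAP spans 4.
        if not 0 <= len(self.replacement) <= 4:
            raise ValueError("replacement must have 0-4 symbols")


class WrongRuleError(ValueError):
    """A rule was applied to a pair outside its dispatch class."""


def _check(sym: int) -> int:
    if not 0 <= sym <= 7:
        raise WrongRuleError(f"symbol {sym} outside F8 alphabet")
    return sym


def classify_pair_f8(c1: int, c2: int) -> AlterationKind:
    """Dispatch a symbol pair to its unique alteration class."""
    _check(c1), _check(c2)
    d = abs(c1 - c2)
    if d == 4:
        return AlterationKind.REMOVE
    if c1 == c2:
        return AlterationKind.PUSH if c1 % 2 == 0 else AlterationKind.WRAP
    if d in (1, 7):
        return AlterationKind.FLIP
    if d in (2, 6):
        return AlterationKind.PULL if c1 % 2 == 1 else AlterationKind.FLIP_OR_CUT
    # d in (3, 5)
    return AlterationKind.ROTATE_OR_CUT


def remove_f8() -> AlterationResult:
    """Erase an out-and-back pair of opposite steps."""
    return AlterationResult((), AlterationKind.REMOVE)


def push_f8(c: int, branch: str = "A") -> AlterationResult:
    """Bend a straight axis-aligned pair (c, c) into a two-step diagonal detour.

    Branch A turns left first (⟨c+1, c-1⟩ mod 8), branch B right first.
    """
    if _check(c) % 2 != 0:
        raise WrongRuleError("PUSH requires an even (axis-aligned) symbol")
    if branch == "A":
        return AlterationResult(((c + 1) % 8, (c + 7) % 8), AlterationKind.PUSH, "A")
    if branch == "B":
        return AlterationResult(((c + 7) % 8, (c + 1) % 8), AlterationKind.PUSH, "B")
    raise ValueError(f"unknown branch {branch!r}")


def wrap_f8(c: int, branch: str = "A") -> AlterationResult:
    """Expand a pair of equal diagonal steps (c, c) into a three-step bulge."""
    if _check(c) % 2 != 1:
        raise WrongRuleError("WRAP requires an odd (diagonal) symbol")
    if branch == "A":
        return AlterationResult(((c + 1) % 8, c, (c + 7) % 8), AlterationKind.WRAP, "A")
    if branch == "B":
        return AlterationResult(((c + 7) % 8, c, (c + 1) % 8), AlterationKind.WRAP, "B")
    raise ValueError(f"unknown branch {branch!r}")


def flip_f8(c1: int, c2: int) -> AlterationResult:
    """Swap the two steps of a turn, mirroring left turns into right turns."""
    _check(c1), _check(c2)
    return AlterationResult((c2, c1), AlterationKind.FLIP)


def pull_f8(c1: int, c2: int) -> AlterationResult:
    """Straighten a 90° turn with odd first symbol into two equal steps."""
    _check(c1), _check(c2)
    d = abs(c1 - c2)
    if c1 % 2 != 1 or d not in (2, 6):
        raise WrongRuleError(f"PULL does not apply to pair ({c1}, {c2})")
    if d == 2:
        m = ((c1 + c2) // 2) % 8
    else:
        m = ((c1 + c2) % 8) // 2
    return AlterationResult((m, m), AlterationKind.PULL)


def cut_f8(c1: int, c2: int) -> AlterationResult:
    """Collapse a turn into the single step that spans the same displacement."""
    _check(c1), _check(c2)
    d = abs(c1 - c2)
    s = c1 + c2
    if d == 2:
        m = s // 2
    elif d == 3:
        m = math.ceil(s / 2) if s in (3, 7, 11) else math.floor(s / 2)
    elif s in (5, 6, 9):
        m = (max(c1, c2) + 1) % 8
    elif s == 7:
        m = (min(c1, c2) - 1) % 8
    else:
        raise WrongRuleError(f"CUT does not apply to pair ({c1}, {c2})")
    return AlterationResult((m,), AlterationKind.CUT)


def rotate_f8(c1: int, c2: int) -> AlterationResult:
    """Rotate both steps of a 135° turn by 45°, keeping the net displacement."""
    _check(c1), _check(c2)
    if abs(c1 - c2) not in (3, 5):
        raise WrongRuleError(f"ROTATE does not apply to pair ({c1}, {c2})")
    if c1 + c2 in (3, 7, 11):
        return AlterationResult(((c1 + 1) % 8, (c2 + 1) % 8), AlterationKind.ROTATE)
    return AlterationResult(((c1 + 7) % 8, (c2 + 7) % 8), AlterationKind.ROTATE)


def candidate_alterations_f8(c1: int, c2: int, rng) -> list[AlterationResult]:
    """Guard-ordered candidates for an F8 pair.

    Composite classes list their length-preserving rewrite (FLIP or
    ROTATE) first and the shortening CUT as a fallback for when the
    topology guard rejects the primary; every other class has a single
    candidate.  PUSH/WRAP branch choice is the only RNG draw.
    """
    kind = classify_pair_f8(c1, c2)
    if kind is AlterationKind.REMOVE:
        return [remove_f8()]
    if kind is AlterationKind.PUSH:
        return [push_f8(c1, "A" if rng.integers(2) == 0 else "B")]
    if kind is AlterationKind.WRAP:
        return [wrap_f8(c1, "A" if rng.integers(2) == 0 else "B")]
    if kind is AlterationKind.FLIP:
        return [flip_f8(c1, c2)]
    if kind is AlterationKind.PULL:
        return [pull_f8(c1, c2)]
    if kind is AlterationKind.FLIP_OR_CUT:
        return [flip_f8(c1, c2), cut_f8(c1, c2)]
    return [rotate_f8(c1, c2), cut_f8(c1, c2)]


def alter_f8(c1: int, c2: int, rng) -> AlterationResult:
    """Draw a concrete alteration for an F8 pair, context-free.

    Unlike the injector's guard-aware candidate ordering, this resolves
    composites by a fair coin.  RNG draw order is fixed for
    reproducibility: (1) composite resolution, (2) PUSH/WRAP branch
    choice; rules without choices draw nothing.
    """
    kind = classify_pair_f8(c1, c2)
    if kind is AlterationKind.FLIP_OR_CUT:
        kind = AlterationKind.FLIP if rng.integers(2) == 0 else AlterationKind.CUT
    elif kind is AlterationKind.ROTATE_OR_CUT:
        kind = AlterationKind.ROTATE if rng.integers(2) == 0 else AlterationKind.CUT
    if kind is AlterationKind.REMOVE:
        return remove_f8()
    if kind is AlterationKind.PUSH:
        return push_f8(c1, "A" if rng.integers(2) == 0 else "B")
    if kind is AlterationKind.WRAP:
        return wrap_f8(c1, "A" if rng.integers(2) == 0 else "B")
    if kind is AlterationKind.FLIP:
        return flip_f8(c1, c2)
    if kind is AlterationKind.PULL:
        return pull_f8(c1, c2)
    if kind is AlterationKind.CUT:
        return cut_f8(c1, c2)
    return rotate_f8(c1, c2)
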