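"""Alteration ruleset for four-directional (F4) chain codes.

Only three alterations exist: WRAP (straight pair → four-step U-turn,
length +2), REMOVE (opposite pair erased, length −2) and FLIP (turn
mirrored, length 0).  As with F8, every replacement conserves the
pair's net displacement.
"""

from __future__ import annotations

from .alter_f8 import AlterationKind, AlterationResult, WrongRuleError


def _check(sym: int) -> int:
    if not 0 <= sym <= 3:
        raise WrongRuleError(f"symbol {sym} outside F4 alphabet")
    return sym


def classify_pair_f4(c1: int, c2: int) -> AlterationKind:
    """Dispatch an F4 pair: equal → WRAP, opposite → REMOVE, else FLIP."""
    _check(c1), _check(c2)
    if c1 == c2:
        return AlterationKind.WRAP
    if abs(c1 - c2) == 2:
        return AlterationKind.REMOVE
    return AlterationKind.FLIP


def wrap_f4(c: int, branch: str = "A") -> AlterationResult:
    """Turn a straight pair (c, c) into a U-turn bulging left (A) or right (B)."""
    _check(c)
    if branch == "A":
        return AlterationResult(((c + 1) % 4, c, c, (c + 3) % 4), AlterationKind.WRAP, "A")
    if branch == "B":
        return AlterationResult(((c + 3) % 4, c, c, (c + 1) % 4), AlterationKind.WRAP, "B")
    raise ValueError(f"unknown branch {branch!r}")


def remove_f4() -> AlterationResult:
    return AlterationResult((), AlterationKind.REMOVE)


def flip_f4(c1: int, c2: int) -> AlterationResult:
    _check(c1), _check(c2)
    return AlterationResult((c2, c1), AlterationKind.FLIP)


def candidate_alterations_f4(c1: int, c2: int, rng) -> list[AlterationResult]:
    """Guard-ordered candidates for an F4 pair (always a single option)."""
    return [alter_f4(c1, c2, rng)]


def alter_f4(c1: int, c2: int, rng) -> AlterationResult:
    """Draw a concrete alteration for an F4 pair (one draw for WRAP's branch)."""
    kind = classify_pair_f4(c1, c2)
    if kind is AlterationKind.WRAP:
        return wrap_f4(c1, "A" if rng.integers(2) == 0 else "B")
    if kind is AlterationKind.REMOVE:
        return remove_f4()
    return flip_f4(c1, c2)
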