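"""Deterministic generators for test shapes.

The factory reproduces the study geometries that can be rebuilt exactly
from their printed properties — a 200-step line segment and a
100-pixel-side square (400 symbols) — plus structural analogues of the
harder classes: loop-with-rings shapes and a self-intersecting
figure-eight, and the two short demonstration paths used throughout the
alteration examples.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chain_core import Chain, CodeType, Role, Shape


@dataclass(frozen=True)
class ShapeSpec:
    """Declarative recipe for a factory shape."""

    kind: str  # line | square | ring_shape | figure_eight | demo_f8 | demo_f4
    size: int = 0
    hole_sides: tuple[int, ...] = ()
    hole_offsets: tuple[tuple[int, int], ...] = ()
    code_type: CodeType = CodeType.F8

    def build(self) -> Shape:
        if self.kind == "line":
            return make_line(self.size, self.code_type)
        if self.kind == "square":
            return make_square(self.size, self.code_type)
        if self.kind == "ring_shape":
            return make_ring_shape(self.size, list(self.hole_sides),
                                   list(self.hole_offsets) or None, self.code_type)
        if self.kind == "figure_eight":
            return make_figure_eight(self.size)
        if self.kind == "demo_f8":
            return demo_fixtures()[0]
        if self.kind == "demo_f4":
            return demo_fixtures()[1]
        raise ValueError(f"unknown shape kind {self.kind!r}")


def make_line(length: int, code_type: CodeType = CodeType.F8) -> Shape:
    """Open horizontal path of ``length`` identical symbols."""
    if length < 2:
        raise ValueError("line length must be at least 2 steps")
    chain = Chain((0,) * length, (0, 0), Role.PATH, code_type)
    return Shape((chain,), closed=False)


def _square_symbols(side: int, code_type: CodeType) -> tuple[int, ...]:
    east, north, west, south = ((0, 2, 4, 6) if code_type is CodeType.F8
                                else (0, 1, 2, 3))
    return (east,) * side + (north,) * side + (west,) * side + (south,) * side


def make_square(side: int, code_type: CodeType = CodeType.F8,
                start: tuple[int, int] = (0, 0), role: Role = Role.LOOP) -> Shape:
    """Axis-aligned square loop with ``side`` steps per edge (4·side symbols)."""
    if side < 2:
        raise ValueError("square side must be at least 2 steps")
    chain = Chain(_square_symbols(side, code_type), start, role, code_type)
    return Shape((chain,), closed=True)


def make_ring_shape(
    outer_side: int,
    hole_sides: list[int],
    hole_offsets: list[tuple[int, int]] | None = None,
    code_type: CodeType = CodeType.F8,
) -> Shape:
    """Closed loop with square rings (holes) placed strictly inside.

    Default placement lines holes up along the diagonal with ≥2-pixel
    clearance from the loop and from each other; explicit offsets (of the
    hole's lower-left pixel) override it.
    """
    shape = make_square(outer_side, code_type)
    if not hole_sides:
        return shape
    if hole_offsets is None:
        hole_offsets = []
        x = y = 3
        for side in hole_sides:
            hole_offsets.append((x, y))
            x += side + 5
            y += side + 5
    chains = list(shape.chains)
    occupied = set()
    for side, (ox, oy) in zip(hole_sides, hole_offsets, strict=True):
        if not (1 + 2 <= ox and ox + side + 2 <= outer_side - 1
                and 1 + 2 <= oy and oy + side + 2 <= outer_side - 1):
            raise ValueError(f"hole of side {side} at {(ox, oy)} does not fit "
                             f"inside outer loop of side {outer_side} with "
                             "2-pixel clearance")
        ring = Chain(_square_symbols(side, code_type), (ox, oy), Role.RING, code_type)
        cells = {(ox + dx, oy + dy) for dx in range(-2, side + 3)
                 for dy in range(-2, side + 3)}
        if cells & occupied:
            raise ValueError("holes overlap or touch")
        occupied |= cells
        chains.append(ring)
    return Shape(tuple(chains), closed=True)


def make_figure_eight(lobe: int) -> Shape:
    """Single F8 loop of two square lobes crossing at one shared pixel.

    The start pixel is the crossing: it is visited at the start of the
    first lobe and again between the lobes, giving exactly one pixel of
    multiplicity 2.
    """
    if lobe < 3:
        raise ValueError("lobe side must be at least 3 steps to cross cleanly")
    first = _square_symbols(lobe, CodeType.F8)
    second = ((4,) * lobe + (6,) * lobe + (0,) * lobe + (2,) * lobe)
    chain = Chain(first + second, (0, 0), Role.LOOP, CodeType.F8)
    return Shape((chain,), closed=True)


# Demonstration paths used in all alteration worked examples.
DEMO_F8_DIGITS = "370011233542441"
DEMO_F4_DIGITS = "000113"


def demo_fixtures() -> tuple[Shape, Shape]:
    """The F8 and F4 demonstration paths, both open and starting at the origin."""
    f8 = Shape((Chain.from_digits(DEMO_F8_DIGITS, (0, 0), Role.PATH, CodeType.F8),),
               closed=False)
    f4 = Shape((Chain.from_digits(DEMO_F4_DIGITS, (0, 0), Role.PATH, CodeType.F4),),
               closed=False)
    return f8, f4
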