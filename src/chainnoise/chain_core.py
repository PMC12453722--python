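"""Freeman chain-code domain model.

A shape boundary is encoded as one or more chains of direction symbols.
The eight-directional code (F8) steps at 45° increments, the
four-directional code (F4) at 90°; a crack code (F4_CRACK) walks pixel
*edges* instead of pixel centres.  The coordinate convention throughout
is x growing right and y growing up, so F8 symbol 2 points to (0, +1);
raster export flips y at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterator, Sequence


class CodeType(Enum):
    """Chain-code dialect: which alphabet and step geometry a chain uses."""

    F8 = "F8"
    F4 = "F4"
    F4_CRACK = "F4_CRACK"

    @property
    def alphabet_size(self) -> int:
        return 8 if self is CodeType.F8 else 4


class Role(Enum):
    """Structural role of a chain: outer boundary, hole boundary, or open curve."""

    LOOP = "loop"
    RING = "ring"
    PATH = "path"


# Unit steps, indexed by symbol.  F8 symbol c moves at angle 45°·c from +x,
# F4 symbol c at 90°·c; diagonal F8 steps have both components ±1.
F8_STEPS: tuple[tuple[int, int], ...] = (
    (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1),
)
F4_STEPS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (-1, 0), (0, -1))


class InvalidSymbolError(ValueError):
    """A symbol falls outside the alphabet of its code type."""


class CrackConversionError(ValueError):
    """A crack-code sequence does not bound a consistent pixel set."""


def symbol_displacement(sym: int, code_type: CodeType) -> tuple[int, int]:
    """Unit grid step for one chain-code symbol.

    Raises :class:`InvalidSymbolError` if ``sym`` is outside the alphabet.
    """
    n = code_type.alphabet_size
    if not isinstance(sym, (int,)) or isinstance(sym, bool) or not (0 <= sym < n):
        raise InvalidSymbolError(f"symbol {sym!r} outside alphabet of {code_type.value}")
    return F8_STEPS[sym] if n == 8 else F4_STEPS[sym]


@dataclass(frozen=True)
class Chain:
    """One chain-code sequence: symbols, a start pixel and a structural role.

    Loops and rings store the start pixel explicitly and do not duplicate
    the closing symbol; closedness is derived from the net displacement.
    """

    symbols: tuple[int, ...]
    start: tuple[int, int] = (0, 0)
    role: Role = Role.PATH
    code_type: CodeType = CodeType.F8

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(int(s) for s in self.symbols))
        object.__setattr__(self, "start", (int(self.start[0]), int(self.start[1])))

    def __len__(self) -> int:
        return len(self.symbols)

    def with_symbols(self, symbols: Sequence[int]) -> "Chain":
        return replace(self, symbols=tuple(symbols))

    def digits(self) -> str:
        """The symbols as a digit string, e.g. ``"370011233542441"``."""
        return "".join(str(s) for s in self.symbols)

    @classmethod
    def from_digits(
        cls,
        digits: str,
        start: tuple[int, int] = (0, 0),
        role: Role = Role.PATH,
        code_type: CodeType = CodeType.F8,
    ) -> "Chain":
        return cls(tuple(int(d) for d in digits), start, role, code_type)


@dataclass(frozen=True)
class PixelPath:
    """Rasterised trace of a chain: one pixel per symbol plus the start."""

    pixels: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.pixels)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.pixels)


@dataclass(frozen=True)
class Shape:
    """An ordered set of chains describing one object.

    A closed shape has one loop (chain 0) and zero or more rings (holes);
    an open shape is a single path.
    """

    chains: tuple[Chain, ...]
    closed: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "chains", tuple(self.chains))

    @property
    def code_type(self) -> CodeType:
        return self.chains[0].code_type

    def total_symbols(self) -> int:
        return sum(len(c) for c in self.chains)

    def replace_chain(self, idx: int, chain: Chain) -> "Shape":
        chains = list(self.chains)
        chains[idx] = chain
        return Shape(tuple(chains), self.closed)


def rasterise_chain(chain: Chain) -> PixelPath:
    """Cumulative pixel trace of a chain from its start pixel."""
    x, y = chain.start
    pixels = [(x, y)]
    for sym in chain.symbols:
        dx, dy = symbol_displacement(sym, chain.code_type)
        x, y = x + dx, y + dy
        pixels.append((x, y))
    return PixelPath(tuple(pixels))


def net_displacement(chain: Chain) -> tuple[int, int]:
    dx = dy = 0
    for sym in chain.symbols:
        sx, sy = symbol_displacement(sym, chain.code_type)
        dx += sx
        dy += sy
    return (dx, dy)


def is_closed(chain: Chain) -> bool:
    """True iff the chain returns to its start pixel."""
    return net_displacement(chain) == (0, 0)


def pixel_visits(chain: Chain) -> list[tuple[int, int]]:
    """Pixel visit multiset of a chain.

    For a loop or ring the duplicate closing pixel is dropped so the start
    pixel is counted once; a path keeps all ``len + 1`` pixels.
    """
    pixels = list(rasterise_chain(chain).pixels)
    if chain.role in (Role.LOOP, Role.RING) and len(pixels) > 1:
        pixels = pixels[:-1]
    return pixels


def validate_shape(shape: Shape) -> list[str]:
    """Check all chain and shape invariants; violations are data, not errors."""
    violations: list[str] = []
    if not shape.chains:
        if shape.closed:
            violations.append("shape: closed shape must have at least one chain")
        return violations
    code_type = shape.chains[0].code_type
    for i, chain in enumerate(shape.chains):
        if chain.code_type is not code_type:
            violations.append(f"chain {i}: code type {chain.code_type.value} differs "
                              f"from chain 0 ({code_type.value})")
        n = chain.code_type.alphabet_size
        for sym in chain.symbols:
            if not (0 <= sym < n):
                violations.append(f"chain {i}: invalid symbol {sym} for "
                                  f"{chain.code_type.value}")
                break
        else:
            if chain.role in (Role.LOOP, Role.RING) and not is_closed(chain):
                violations.append(f"chain {i}: role {chain.role.value} but net "
                                  "displacement is nonzero")
    if shape.closed:
        if shape.chains[0].role is not Role.LOOP:
            violations.append("chain 0: closed shape must start with a loop")
        for i, chain in enumerate(shape.chains[1:], start=1):
            if chain.role is not Role.RING:
                violations.append(f"chain {i}: closed shape's later chains must be rings")
    else:
        if len(shape.chains) != 1:
            violations.append("shape: open shape must consist of exactly one chain")
        elif shape.chains[0].role is not Role.PATH:
            violations.append("chain 0: open shape's chain must be a path")
    return violations


def _crack_left_pixel(vertex: tuple[int, int], sym: int) -> tuple[int, int]:
    """Pixel on the left of a directed crack step leaving ``vertex``.

    Pixel (px, py) occupies the unit square [px, px+1] × [py, py+1] whose
    lower-left corner is the lattice vertex (px, py).
    """
    x, y = vertex
    if sym == 0:    # right: pixel above the edge
        return (x, y)
    if sym == 1:    # up: pixel to the left
        return (x - 1, y)
    if sym == 2:    # left: pixel below
        return (x - 1, y - 1)
    if sym == 3:    # down: pixel to the right
        return (x, y - 1)
    raise InvalidSymbolError(f"symbol {sym!r} outside alphabet of F4_CRACK")


def crack_to_centre(chain: Chain) -> Chain:
    """Convert an edge-walking crack chain to a centre-format F4 chain.

    The encoded pixel lies on the *left* of each crack step (a
    counter-clockwise outer-boundary tour).  Consecutive duplicate pixels
    (produced at turns) collapse, and the remaining centre-to-centre moves
    must all be unit F4 steps.
    """
    if chain.code_type is not CodeType.F4_CRACK:
        raise ValueError("crack_to_centre expects an F4_CRACK chain")
    if not chain.symbols:
        raise CrackConversionError("empty crack sequence bounds no pixel")
    if chain.role in (Role.LOOP, Role.RING) and not is_closed(chain):
        raise CrackConversionError("crack loop/ring does not close")
    vertex = chain.start
    pixels: list[tuple[int, int]] = []
    for sym in chain.symbols:
        px = _crack_left_pixel(vertex, sym)
        if not pixels or pixels[-1] != px:
            pixels.append(px)
        dx, dy = symbol_displacement(sym, CodeType.F4)
        vertex = (vertex[0] + dx, vertex[1] + dy)
    step_to_sym = {step: sym for sym, step in enumerate(F4_STEPS)}
    symbols: list[int] = []
    for (x0, y0), (x1, y1) in zip(pixels, pixels[1:]):
        step = (x1 - x0, y1 - y0)
        if step not in step_to_sym:
            raise CrackConversionError(
                f"crack tour implies non-adjacent centre move {step} "
                f"between pixels {(x0, y0)} and {(x1, y1)}")
        symbols.append(step_to_sym[step])
    return Chain(tuple(symbols), pixels[0], chain.role, CodeType.F4)
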