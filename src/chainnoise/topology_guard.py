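"""Raster-space occupancy index and the alteration accept/reject test.

Chains are implicitly rasterised before injection; every pixel visit is
stored in a hash-keyed multiset (h(x, y) = x_max·y + x over an offset
grid).  Pixels with multiplicity ≥ 2 are exactly the self-intersection
pixels.  An alteration is rejected if it would bring the boundary into
contact with a distant part of itself (which could create or destroy a
hole or crossing) or change the visit count of an existing crossing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .alter_f8 import AlterationResult
from .chain_core import Chain, Role, Shape, pixel_visits, symbol_displacement

_NEIGHBOURS_8 = tuple(
    (dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)
)

# Loops/rings shorter than 4 symbols or paths shorter than 2 cannot bound a
# meaningful raster segment; alterations shrinking below these are rejected.
MIN_LOOP_SYMBOLS = 4
MIN_PATH_SYMBOLS = 2


class GuardContractError(RuntimeError):
    """An alteration was committed without topology-guard approval."""


@dataclass
class OccupancyIndex:
    """Multiset of occupied pixels keyed by h(x, y) = x_max·(y−y0) + (x−x0).

    The hash domain is sized with a growth margin so outward noise growth
    rarely overflows; keys outside the margin trigger a transparent
    re-index onto a larger domain.
    """

    x0: int
    y0: int
    x_max: int
    y_max: int
    cells: dict[int, int] = field(default_factory=dict)

    def _key(self, x: int, y: int) -> int:
        if not (self.x0 <= x < self.x0 + self.x_max
                and self.y0 <= y < self.y0 + self.y_max):
            self._reindex(x, y)
        return self.x_max * (y - self.y0) + (x - self.x0)

    def _reindex(self, x: int, y: int) -> None:
        pixels = self.pixel_counts()
        xs = [p[0] for p in pixels] + [x]
        ys = [p[1] for p in pixels] + [y]
        pad = max(self.x_max, self.y_max)
        self.x0, self.y0 = min(xs) - pad, min(ys) - pad
        self.x_max = (max(xs) - self.x0) + pad + 1
        self.y_max = (max(ys) - self.y0) + pad + 1
        self.cells = {
            self.x_max * (py - self.y0) + (px - self.x0): c
            for (px, py), c in pixels.items()
        }

    def pixel_counts(self) -> dict[tuple[int, int], int]:
        """Decode the hash table back to coordinate → multiplicity."""
        out = {}
        for key, count in self.cells.items():
            y, x = divmod(key, self.x_max)
            out[(x + self.x0, y + self.y0)] = count
        return out

    def count(self, x: int, y: int) -> int:
        if not (self.x0 <= x < self.x0 + self.x_max
                and self.y0 <= y < self.y0 + self.y_max):
            return 0
        return self.cells.get(self.x_max * (y - self.y0) + (x - self.x0), 0)

    def add(self, x: int, y: int, n: int = 1) -> None:
        key = self._key(x, y)
        self.cells[key] = self.cells.get(key, 0) + n

    def remove(self, x: int, y: int, n: int = 1) -> None:
        key = self._key(x, y)
        new = self.cells.get(key, 0) - n
        if new < 0:
            raise ValueError(f"visit count at {(x, y)} would become negative")
        if new == 0:
            self.cells.pop(key, None)
        else:
            self.cells[key] = new

    def total_visits(self) -> int:
        return sum(self.cells.values())

    def crossing_pixels(self) -> list[tuple[int, int]]:
        return [p for p, c in self.pixel_counts().items() if c >= 2]


def build_occupancy(shape: Shape, margin: int = 0) -> OccupancyIndex:
    """Index every pixel visit of every chain, with a growth margin.

    ``margin`` is typically 2·n for an n-iteration injection run, so the
    hash domain absorbs the worst-case outward growth without re-indexing.
    """
    visits: Counter[tuple[int, int]] = Counter()
    for chain in shape.chains:
        visits.update(pixel_visits(chain))
    if visits:
        xs = [p[0] for p in visits]
        ys = [p[1] for p in visits]
        x0, y0 = min(xs) - margin - 1, min(ys) - margin - 1
        x_max = (max(xs) - x0) + margin + 2
        y_max = (max(ys) - y0) + margin + 2
    else:
        x0 = y0 = 0
        x_max = y_max = max(margin, 1)
    index = OccupancyIndex(x0=x0, y0=y0, x_max=x_max, y_max=y_max)
    for (x, y), c in visits.items():
        index.add(x, y, c)
    return index


def _pixel_at(chain: Chain, pos: int) -> tuple[int, int]:
    """Pixel P_pos reached after the first ``pos`` symbols."""
    x, y = chain.start
    for sym in chain.symbols[:pos]:
        dx, dy = symbol_displacement(sym, chain.code_type)
        x, y = x + dx, y + dy
    return (x, y)


def _step(p: tuple[int, int], sym: int, chain: Chain) -> tuple[int, int]:
    dx, dy = symbol_displacement(sym, chain.code_type)
    return (p[0] + dx, p[1] + dy)


def _local_geometry(
    chain: Chain, pos: int, result: AlterationResult, p0: tuple[int, int]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]], list[tuple[int, int]], Counter]:
    """Old window, new segment, flank pixels and the signed visit delta.

    ``p0`` is the pixel at ``pos`` (start of the replaced pair).  Flanks
    are the single chain pixel on each side of the window (wrapping for
    loops/rings); the chain legitimately touches them, so they are exempt
    from the bordering test.
    """
    m = len(chain)
    closed = chain.role in (Role.LOOP, Role.RING)
    p1 = _step(p0, chain.symbols[pos], chain)
    p2 = _step(p1, chain.symbols[pos + 1], chain)
    old = [p0, p1, p2]
    new = [p0]
    x, y = p0
    for sym in result.replacement:
        dx, dy = symbol_displacement(sym, chain.code_type)
        x, y = x + dx, y + dy
        new.append((x, y))
    flanks: list[tuple[int, int]] = []
    if pos >= 1:
        sx, sy = symbol_displacement(chain.symbols[pos - 1], chain.code_type)
        flanks.append((p0[0] - sx, p0[1] - sy))
    elif closed:
        sx, sy = symbol_displacement(chain.symbols[m - 1], chain.code_type)
        flanks.append((p0[0] - sx, p0[1] - sy))
    if pos + 2 < m:
        flanks.append(_step(p2, chain.symbols[pos + 2], chain))
    elif closed:
        # Window ends at the closing pixel; the next chain pixel is P_1.
        flanks.append(_step(chain.start, chain.symbols[0], chain))
    delta: Counter = Counter(new)
    delta.subtract(old)
    return old, new, flanks, delta


def preserves_topology(
    index: OccupancyIndex,
    shape: Shape,
    chain_idx: int,
    pos: int,
    result: AlterationResult,
    at: tuple[int, int] | None = None,
) -> bool:
    """Accept/reject test for replacing the pair at ``pos`` with the result.

    Rejects when the altered local segment would (a) place or leave a pixel
    in 8-contact with any occupied pixel outside its own along-chain
    neighbourhood, or (b) add or delete a visit at a pixel whose current
    multiplicity is ≥ 2 (protecting existing self-intersections), or (c)
    shrink the chain below the minimum meaningful length.

    ``at`` is the pixel at ``pos`` if the caller already knows it (the
    injector tracks it while sweeping); otherwise it is recomputed.
    """
    chain = shape.chains[chain_idx]
    if not 0 <= pos < len(chain) - 1:
        raise IndexError(f"pair position {pos} out of range for chain of "
                         f"length {len(chain)}")
    new_len = len(chain) + len(result.replacement) - 2
    min_len = MIN_LOOP_SYMBOLS if chain.role in (Role.LOOP, Role.RING) else MIN_PATH_SYMBOLS
    if new_len < min_len:
        return False

    p0 = at if at is not None else _pixel_at(chain, pos)
    old, new, flanks, delta = _local_geometry(chain, pos, result, p0)
    # Visits the local neighbourhood legitimately accounts for: the replaced
    # window, its flanks, and the pixels of the replacement segment itself.
    exempt: Counter = Counter(old)
    exempt.update(flanks)
    exempt.update(new)

    added = [p for p, d in delta.items() if d > 0]
    removed = [p for p, d in delta.items() if d < 0]

    for px, py in added:
        # A new visit on an already-occupied pixel would create a crossing.
        if index.count(px, py) > 0:
            return False
    for px, py in removed:
        # Deleting a visit at a crossing would destroy it.
        if index.count(px, py) >= 2:
            return False

    # Bordering test on every pixel the alteration adds or removes: any
    # 8-adjacent occupied visit not explained by the local window means the
    # boundary would touch (or stop separating) a distant segment.
    for px, py in set(added) | set(removed):
        for dx, dy in _NEIGHBOURS_8:
            nx, ny = px + dx, py + dy
            if index.count(nx, ny) > exempt.get((nx, ny), 0):
                return False
    return True


def commit_alteration(
    index: OccupancyIndex,
    shape: Shape,
    chain_idx: int,
    pos: int,
    result: AlterationResult,
    at: tuple[int, int] | None = None,
    *,
    approved: bool = False,
) -> Shape:
    """Apply an alteration, updating chain symbols and the occupancy index.

    Callers that have not already obtained guard approval get the check
    re-run here; committing a rejected alteration raises
    :class:`GuardContractError`.  The index is mutated in place and the
    updated shape returned.
    """
    chain = shape.chains[chain_idx]
    p0 = at if at is not None else _pixel_at(chain, pos)
    if not approved and not preserves_topology(index, shape, chain_idx, pos, result, at=p0):
        raise GuardContractError("commit_alteration requires guard approval")
    _, _, _, delta = _local_geometry(chain, pos, result, p0)
    for (px, py), d in delta.items():
        if d > 0:
            index.add(px, py, d)
        elif d < 0:
            index.remove(px, py, -d)
    symbols = chain.symbols[:pos] + result.replacement + chain.symbols[pos + 2:]
    return shape.replace_chain(chain_idx, chain.with_symbols(symbols))


def rasterise_shape(shape: Shape, pad: int = 1) -> tuple[np.ndarray, tuple[int, int]]:
    """Binary foreground mask of all chain pixels (y-up row order), padded."""
    visits: Counter = Counter()
    for chain in shape.chains:
        visits.update(pixel_visits(chain))
    if not visits:
        return np.zeros((2 * pad + 1, 2 * pad + 1), dtype=bool), (0, 0)
    xs = [p[0] for p in visits]
    ys = [p[1] for p in visits]
    x0, y0 = min(xs) - pad, min(ys) - pad
    grid = np.zeros((max(ys) - y0 + pad + 1, max(xs) - x0 + pad + 1), dtype=bool)
    for x, y in visits:
        grid[y - y0, x - x0] = True
    return grid, (x0, y0)


def count_holes(shape: Shape) -> int:
    """Flood-fill hole count: bounded background components of the raster.

    Background connectivity is 4-connected (foreground 8-connected, the
    standard duality).  For a closed shape the outer loop's interior is
    one bounded component but not a hole, so one is subtracted.
    """
    grid, _ = rasterise_shape(shape, pad=1)
    background = ~grid
    labels, n = ndimage.label(background, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    border_labels = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :])) \
        | set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
    border_labels.discard(0)
    bounded = n - len(border_labels)
    if shape.closed and bounded > 0:
        bounded -= 1
    return bounded


def count_crossings(shape: Shape) -> int:
    """Number of pixels visited more than once by the shape's chains."""
    visits: Counter = Counter()
    for chain in shape.chains:
        visits.update(pixel_visits(chain))
    return sum(1 for c in visits.values() if c >= 2)
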