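"""Chain-code file dialect and raster export.

No community standard exists for Freeman chain-code files, so a small
plain-text dialect is defined here (version-tagged ``chaincode v1``)::

    chaincode v1
    type F8
    chain 0 loop 0 0 00224466...
    chain 1 ring 3 3 0123...

Coordinates are the start pixel (x right, y up); the digit string is the
symbol sequence.  Reading and writing round-trip losslessly.  Raster
export flips y to image convention at this boundary only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .chain_core import Chain, CodeType, Role, Shape, crack_to_centre
from .topology_guard import rasterise_shape

FORMAT_TAG = "chaincode v1"


class ChainFileError(ValueError):
    """Malformed chain file; the message carries the offending line number."""


def write_chain_file(shape: Shape, path) -> None:
    lines = [FORMAT_TAG, f"type {shape.code_type.value}"]
    for i, chain in enumerate(shape.chains):
        lines.append(f"chain {i} {chain.role.value} "
                     f"{chain.start[0]} {chain.start[1]} {chain.digits()}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_chain_file(path, convert_crack: bool = False) -> Shape:
    """Parse a chain file; optionally convert crack chains to centre format."""
    raw = Path(path).read_text().splitlines()
    lines = [(no, line.strip()) for no, line in enumerate(raw, start=1)
             if line.strip() and not line.strip().startswith("#")]
    if not lines or lines[0][1] != FORMAT_TAG:
        raise ChainFileError(f"line 1: expected header {FORMAT_TAG!r}")
    if len(lines) < 2 or not lines[1][1].startswith("type "):
        raise ChainFileError("line 2: expected 'type F8|F4|F4_CRACK'")
    type_name = lines[1][1].split(None, 1)[1]
    try:
        code_type = CodeType(type_name)
    except ValueError:
        raise ChainFileError(f"line {lines[1][0]}: unknown code type {type_name!r}")

    chains: list[Chain] = []
    seen_indices: set[int] = set()
    for no, line in lines[2:]:
        fields = line.split()
        if len(fields) != 6 or fields[0] != "chain":
            raise ChainFileError(f"line {no}: expected "
                                 "'chain <idx> <role> <x> <y> <symbols>'")
        _, idx_s, role_s, x_s, y_s, digits = fields
        try:
            idx, x, y = int(idx_s), int(x_s), int(y_s)
        except ValueError:
            raise ChainFileError(f"line {no}: non-integer index or coordinate")
        if idx in seen_indices:
            raise ChainFileError(f"line {no}: duplicate chain index {idx}")
        seen_indices.add(idx)
        try:
            role = Role(role_s)
        except ValueError:
            raise ChainFileError(f"line {no}: unknown role {role_s!r}")
        alphabet = set("01234567") if code_type is CodeType.F8 else set("0123")
        for ch in digits:
            if ch not in alphabet:
                raise ChainFileError(f"line {no}: illegal digit {ch!r} for "
                                     f"{code_type.value}")
        chains.append(Chain.from_digits(digits, (x, y), role, code_type))
    if not chains:
        raise ChainFileError("file declares no chains")
    if sorted(seen_indices) != list(range(len(chains))):
        raise ChainFileError("chain indices must be 0..n-1 without gaps")
    closed = chains[0].role is not Role.PATH
    if convert_crack and code_type is CodeType.F4_CRACK:
        chains = [crack_to_centre(c) for c in chains]
    return Shape(tuple(chains), closed=closed)


def export_mask(shape: Shape, path, format: str | None = None) -> None:
    """Write the boundary-pixel mask as PGM (plain text) or PNG.

    The bounding box is padded by one pixel and the y axis flipped to the
    usual top-down image convention.
    """
    grid, _ = rasterise_shape(shape, pad=1)
    grid = np.flipud(grid)
    fmt = (format or Path(path).suffix.lstrip(".")).upper()
    if fmt == "PGM":
        rows = "\n".join(" ".join("1" if v else "0" for v in row) for row in grid)
        Path(path).write_text(
            f"P1\n{grid.shape[1]} {grid.shape[0]}\n{rows}\n")
    elif fmt == "PNG":
        img = Image.fromarray((grid * np.uint8(255)))
        img.save(path, format="PNG")
    else:
        raise ValueError(f"unsupported raster format {fmt!r} (use PGM or PNG)")
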