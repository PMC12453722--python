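"""Noise-quantification metrics: fractal dimension and mean distance from original.

The fractal dimension here is the single-scale index FD = ln N / ln(1/ε),
with N the number of distinct boundary pixels and ε the pixel-to-space
ratio (one over the longer side of the current bounding box, measured in
pixels).  It is 1 for a straight line and grows towards 2 as the boundary
fills space.  MDfO averages, over chains and over each noisy chain's
pixels, the Euclidean distance to the nearest pixel of the corresponding
original chain; it is 0 exactly when no pixel has moved off the original
footprint.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chain_core import Shape, pixel_visits


@dataclass(frozen=True)
class FdResult:
    value: float
    n_pixels: int
    epsilon: float


@dataclass(frozen=True)
class MdfoResult:
    value: float
    per_chain: tuple[float, ...]


def fractal_dimension(shape: Shape) -> FdResult:
    """Single-scale fractal dimension of the rasterised boundary.

    A single-pixel shape has ε = 1; its FD is defined as 0 (the ln 1 / ln 1
    limit convention).
    """
    pixels: set[tuple[int, int]] = set()
    for chain in shape.chains:
        pixels.update(pixel_visits(chain))
    if not pixels:
        raise ValueError("fractal_dimension requires a non-empty shape")
    xs = [p[0] for p in pixels]
    ys = [p[1] for p in pixels]
    # 1/ε is the longer side length of the current bounding box (a square
    # drawn with 100 steps per edge spans 100 units, so 1/ε = 100).
    side = max(max(xs) - min(xs), max(ys) - min(ys))
    n = len(pixels)
    epsilon = 1.0 / side if side >= 1 else 1.0
    value = 0.0 if side <= 1 else math.log(n) / math.log(side)
    return FdResult(value=value, n_pixels=n, epsilon=epsilon)


def mdfo(noisy: Shape, original: Shape) -> MdfoResult:
    """Mean distance from original, chains paired by index.

    Index pairing is safe because the injector never reorders or
    adds/removes chains.
    """
    if len(noisy.chains) != len(original.chains):
        raise ValueError(
            f"chain-count mismatch: noisy has {len(noisy.chains)}, "
            f"original has {len(original.chains)}")
    per_chain = []
    for noisy_chain, orig_chain in zip(noisy.chains, original.chains):
        orig_pixels = np.array(sorted(set(pixel_visits(orig_chain))), dtype=float)
        noisy_pixels = np.array(pixel_visits(noisy_chain), dtype=float)
        tree = cKDTree(orig_pixels)
        dists, _ = tree.query(noisy_pixels)
        per_chain.append(float(np.mean(dists)))
    return MdfoResult(value=float(np.mean(per_chain)), per_chain=tuple(per_chain))


def metric_record(
    shape_id: str, mu: float, n: int, seed: int,
    fd: FdResult, md: MdfoResult | None,
) -> dict:
    return {
        "shape": shape_id,
        "mu": mu,
        "n": n,
        "seed": seed,
        "FD": round(fd.value, 2),
        "MDfO": round(md.value, 2) if md is not None else None,
    }


def write_metric_reports(records: list[dict], json_path=None, csv_path=None) -> None:
    """Persist metric records as JSON and/or CSV (two-decimal reporting)."""
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(records, fh, indent=2)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["shape", "mu", "n", "seed", "FD", "MDfO"])
            writer.writeheader()
            writer.writerows(records)
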