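"""Stochastic noise-injection sweep over a shape's chain codes.

For each of ``n`` iterations, every chain is swept left to right over its
consecutive symbol pairs; with probability μ a pair is offered to the
matching alteration ruleset, and the resulting rewrite is committed only
if the topology guard accepts it.  The position index advances one
symbol per pass and the loop bound tracks the mutating chain, so a
committed replacement's tail symbols can pair with their new successors
later in the same sweep.  This keeps the boundary growing gently instead
of freezing at a rewrite equilibrium.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .alter_f4 import candidate_alterations_f4
from .alter_f8 import AlterationKind, candidate_alterations_f8
from .chain_core import CodeType, Shape, symbol_displacement, validate_shape
from .topology_guard import build_occupancy, commit_alteration, preserves_topology


@dataclass(frozen=True)
class NoiseParams:
    """Injection parameters: per-pair probability μ, sweep count n, RNG seed."""

    mu: float
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mu <= 1:
            raise ValueError(f"mu must lie in (0, 1], got {self.mu}")
        if self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")


@dataclass
class IterationDiagnostics:
    """Per-iteration alteration accounting and length bookkeeping.

    ``k`` is the relative length-change rate: the net symbol delta of the
    iteration divided by the pre-iteration length, so
    ``length_after = length_before * (1 + k)`` exactly.
    """

    iteration: int
    counts: dict[str, int]
    rejected: int
    length_before: int
    length_after: int
    k: float

    def to_json(self) -> str:
        return json.dumps({
            "iteration": self.iteration,
            "counts": self.counts,
            "rejected": self.rejected,
            "L_before": self.length_before,
            "L_after": self.length_after,
            "k": self.k,
        })


_LENGTH_DELTA_F8 = {
    AlterationKind.REMOVE: -2,
    AlterationKind.CUT: -1,
    AlterationKind.WRAP: +1,
}
_LENGTH_DELTA_F4 = {
    AlterationKind.REMOVE: -2,
    AlterationKind.WRAP: +2,
}


def expected_length_delta(counts: dict[str, int], code_type: CodeType) -> int:
    """Net symbol-count change implied by an iteration's alteration counts."""
    table = _LENGTH_DELTA_F8 if code_type is CodeType.F8 else _LENGTH_DELTA_F4
    return sum(table.get(AlterationKind(kind), 0) * c for kind, c in counts.items())


def iteration_stats(
    iteration: int,
    length_before: int,
    length_after: int,
    counts: dict[str, int],
    rejected: int,
) -> IterationDiagnostics:
    """Assemble diagnostics for one sweep; k = ΔL / L_before."""
    k = (length_after - length_before) / length_before if length_before else 0.0
    return IterationDiagnostics(
        iteration=iteration,
        counts=dict(counts),
        rejected=rejected,
        length_before=length_before,
        length_after=length_after,
        k=k,
    )


def inject_noise(
    shape: Shape,
    params: NoiseParams,
    rng: np.random.Generator | None = None,
) -> tuple[Shape, list[IterationDiagnostics]]:
    """Run the guarded stochastic sweep for ``params.n`` iterations.

    One RNG stream drives everything, with a fixed draw order per fired
    pair: the position draw r, then (PUSH/WRAP only) the branch choice.
    Composite dispatch classes draw nothing: the length-preserving
    rewrite is tried first and CUT applied only if the guard rejects it.
    Identical (shape, μ, n, seed) therefore give bit-identical output.
    A custom ``rng`` (anything with ``random()`` and ``integers(n)``)
    overrides the seeded default stream.
    """
    violations = validate_shape(shape)
    if violations:
        raise ValueError("invalid shape: " + "; ".join(violations))
    if shape.code_type is CodeType.F4_CRACK:
        raise ValueError("crack chains must be converted to centre format "
                         "before noise injection (see crack_to_centre)")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    candidates = (candidate_alterations_f8 if shape.code_type is CodeType.F8
                  else candidate_alterations_f4)

    index = build_occupancy(shape, margin=2 * params.n)
    diagnostics: list[IterationDiagnostics] = []
    for iteration in range(params.n):
        length_before = shape.total_symbols()
        counts: dict[str, int] = {}
        rejected = 0
        for chain_idx in range(len(shape.chains)):
            j = 0
            # Track the sweep pixel so the guard gets O(1) local geometry.
            pixel = shape.chains[chain_idx].start
            while j + 1 < len(shape.chains[chain_idx]):
                chain = shape.chains[chain_idx]
                r = rng.random()
                if r < params.mu:
                    committed = False
                    for result in candidates(chain.symbols[j], chain.symbols[j + 1], rng):
                        if preserves_topology(index, shape, chain_idx, j, result, at=pixel):
                            shape = commit_alteration(
                                index, shape, chain_idx, j, result, at=pixel,
                                approved=True)
                            counts[result.kind.value] = counts.get(result.kind.value, 0) + 1
                            committed = True
                            break
                    if not committed:
                        rejected += 1
                    chain = shape.chains[chain_idx]
                    if j >= len(chain):
                        break
                dx, dy = symbol_displacement(chain.symbols[j], chain.code_type)
                pixel = (pixel[0] + dx, pixel[1] + dy)
                j += 1
        diagnostics.append(iteration_stats(
            iteration, length_before, shape.total_symbols(), counts, rejected))
    return shape, diagnostics


def write_diagnostics(diagnostics: list[IterationDiagnostics], path) -> None:
    """Serialise diagnostics as JSON lines, one record per iteration."""
    with open(path, "w") as fh:
        for diag in diagnostics:
            fh.write(diag.to_json() + "\n")
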