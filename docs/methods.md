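# Methods

## Shape model

A shape 𝒮 is an ordered set of chains 𝒞 = {C_i}.  Each chain carries a
start pixel (x, y), a role and a symbol sequence over the F8 alphabet
{0..7} (step at angle 45°·c; even symbols axis-aligned, odd diagonal)
or the F4 alphabet {0..3} (90°·c).  Coordinates grow right and up;
raster export flips y to image convention at the I/O boundary only.
Closed shapes have one loop (chain 0) and any number of rings; open
shapes are a single path.  Loops store the start pixel and no duplicate
closing symbol — closedness is the derived property "net displacement
is zero".  Crack-coded F4 input (a walk along pixel *edges*) is
converted to centre format before any processing; the encoded pixel is
taken to lie on the left of each crack step, i.e. tours are
counter-clockwise around the outer boundary.  The conversion collapses
the duplicate left-pixels produced at turns and requires every
remaining centre-to-centre move to be a unit F4 step.

## Alteration rulesets

An alteration rewrites one consecutive symbol pair into a replacement
segment of 0–4 symbols with the *same net displacement*.  This single
conservation law is what keeps loops closed, rings closed and path
endpoints pinned, independent of where and how often alterations fire.

F8 dispatch on the pair (a, b), d = |a − b|:

| condition            | rule        | length delta |
|----------------------|-------------|--------------|
| d = 4                | REMOVE → ⟨⟩ | −2 |
| a = b, a even        | PUSH → ⟨a±1, a∓1⟩ | 0 |
| a = b, a odd         | WRAP → ⟨a±1, a, a∓1⟩ | +1 |
| d ∈ {1, 7}           | FLIP → ⟨b, a⟩ | 0 |
| d ∈ {2, 6}, a odd    | PULL → two equal mean symbols | 0 |
| d ∈ {2, 6}, a even   | FLIP, or CUT as fallback | 0 / −1 |
| d ∈ {3, 5}           | ROTATE, or CUT as fallback | 0 / −1 |

CUT collapses a turn to the single symbol spanning the same
displacement, with the branch chosen by d and the pair sum (for d = 3
the mean is rounded up when the sum is 3, 7 or 11 and down when it is 5
or 9; for d ∈ {5, 6} the symbol is max+1 mod 8 when the sum is 5, 6 or
9 and min−1 mod 8 when it is 7).  ROTATE turns both steps 45°
(+1 mod 8 for sums 3, 7, 11; −1 mod 8 for sums 5, 9).  F4 has only
WRAP (equal pair → four-symbol U-turn, +2), REMOVE (opposite pair, −2)
and FLIP (otherwise).  All 64 F8 and 16 F4 ordered pairs match exactly
one dispatch class; displacement conservation, alphabet closure and the
length deltas {−2, −1, 0, +1} (F8) / {−2, 0, +2} (F4) are verified by
exhaustive enumeration in the test suite.

PUSH and WRAP bulge to one side or the other; the side is a fair coin
from the injection RNG.  The two-way dispatch classes (FLIP-or-CUT,
ROTATE-or-CUT) are resolved *by the topology guard*: the
length-preserving rewrite (FLIP or ROTATE) is tried first and CUT is
applied only if the guard rejects it.  This was a genuinely open design
point.  A fair coin between the two was tried first and discarded on
measurement: with CUT firing as often as WRAP, the total symbol count
freezes at a rewrite equilibrium a few percent above L₀, and the
fractal dimension *decreases* with the iteration count — the opposite
of the intended behaviour of accumulating noise, whose length
accounting L_i = L₀·Π(1+k_j) only has content when k_j is persistently
nonzero.  The guard-fallback rule needs no arbitrary probability and
produces gentle sustained growth.  (`alter_f8` still exposes the
context-free fair-coin resolution for standalone sampling.)

## Topology guard

Chains are implicitly rasterised: every pixel visit is held in a
multiset keyed by the hash h(x, y) = x_max·y + x over an offset grid
sized with a growth margin of 2n, re-indexed transparently on overflow.
Pixels with multiplicity ≥ 2 are exactly the self-intersections.

A proposed rewrite of the pair at position j replaces the 3-pixel
window P_j, P_{j+1}, P_{j+2} by the replacement's pixel trace.  It is
rejected when:

1. an added pixel lands on any occupied pixel (would create a
   crossing);
2. a removed visit touches a pixel of multiplicity ≥ 2 (would destroy
   an existing crossing — note this makes REMOVE unreachable in guarded
   runs, since a removable out-and-back pair always stands on a
   doubly-visited base pixel);
3. any added or removed pixel is 8-adjacent to an occupied visit not
   accounted for by the local neighbourhood — the replaced window, one
   chain pixel on each side of it, and the replacement's own pixels;
4. the chain would shrink below 4 symbols (loop/ring) or 2 (path).

Rule 3 is deliberately conservative: 8-adjacency (rather than
4-adjacency) means a rewrite can never silently create a diagonal
contact, and testing removed pixels as well as added ones means a CUT
cannot unseal a one-pixel hole.  Both relaxations were tried and
measurably change hole counts in long runs, so they are not offered as
options.  The price of conservatism is that some topologically safe
rewrites are rejected and the boundary cannot fold back alongside
itself; see Limitations.

Hole and crossing counts are *never* computed by the guard (it is O(1)
per proposal); they are verified independently by oracles: crossings as
the number of multiplicity-≥2 pixels, holes by flood fill of the raster
background with 4-connectivity (foreground 8-connected, the standard
duality), counting bounded components and, for closed shapes,
discounting the loop interior, which is not a hole.

## Injection sweep

`inject_noise(shape, NoiseParams(mu, n, seed))` runs n iterations; each
iteration visits chains in index order and pair positions left to
right.  A uniform draw r < μ fires the pair; the candidate rewrite(s)
are guard-tested and the first acceptable one committed.  The position
index then advances one symbol per pass with the loop bound tracking
the mutating chain (the straightforward reading of a mutating `for j`
loop), so the tail of an inserted segment may pair with its new
successor later in the same sweep; the closing pair of a loop (last
symbol, first symbol) is never offered.  One RNG stream drives
everything with a fixed draw order — position draw, then (PUSH/WRAP
only) branch choice — so identical (shape, μ, n, seed) give
bit-identical output.

Per-iteration diagnostics record the count of each committed rule, the
guard rejections, the symbol totals before and after, and the relative
rate k_i = ΔL_i/L_i; the identities ΔL = |WRAP| − |CUT| − 2·|REMOVE|
(F8), ΔL = 2·|WRAP| − 2·|REMOVE| (F4) and L_n = L₀·Π(1+k_i) hold
exactly and are asserted in the tests.

## Metrics

**Fractal dimension.**  FD = ln N / ln(1/ε), with N the number of
*distinct* occupied pixels (a crossing counts once) and 1/ε the longer
side length of the current bounding box, max − min of the occupied
coordinates: a square drawn with 100 steps per edge spans 100 units, so
its pristine FD is ln 400 / ln 100 ≈ 1.30 and a 200-step line gives
ln 201 / ln 200 ≈ 1.00.  Degenerate shapes spanning ≤ 1 unit have
FD = 0 by convention.

**Mean distance from original.**  Chains are paired by index (the
injector never reorders or renumbers chains).  For each noisy chain,
the mean over its pixel visits of the Euclidean distance to the nearest
pixel of the paired original chain; the shape value is the mean of the
per-chain means.  Zero exactly when no pixel has left the original
footprint.  Distances are between pixel centres — symbol values are
directions, not positions, and their numeric differences would be
meaningless as distances.

Reported values are rounded to two decimals.

## Synthetic shapes

The factory rebuilds deterministically, with no RNG:

- `make_line(200)` — the 200-symbol open segment (exact reconstruction
  from its published properties);
- `make_square(100)` — the 400-symbol axis-aligned loop (likewise
  exact; `side` is steps per edge, so symbol and boundary-pixel counts
  are both 4·side);
- `make_ring_shape(outer, holes)` — a loop with square rings placed
  with ≥ 2-pixel clearance: the structural class of multi-chain shapes
  with holes;
- `make_figure_eight(lobe)` — one closed loop of two square lobes
  sharing a single pixel: exactly one multiplicity-2 crossing, the
  structural class of self-intersecting shapes;
- the two demonstration paths 370011233542441 (F8) and 000113 (F4).

The remaining published test shapes (a twisted loop with four
crossings, and loop-plus-ring figures of 1.4k–64k symbols) exist only
as externally hosted chain-code files; their *structural classes* are
covered by the generators above, but their exact sequences — and hence
their tabulated metric values — are not reproduced here.  The
generators emulate clean synthetic geometry: axis-aligned boundaries,
exact closure, no encoding noise.  Real traced boundaries are already
rough; passing tests on these fixtures demonstrates topology
preservation and metric behaviour, not robustness to malformed
real-world encodings.

Test problem sizes (squares of side 40–100, 24-step ring fixtures,
8-step lobes; trend checks over 3–10 seeds) were chosen so the whole
suite exercises thousands of guarded alterations while staying
comfortably fast on one core.

## Known limitations

- **Growth saturation.**  With the conservative guard, boundary
  roughness saturates: once the curve is locally crowded, bulges are
  rejected and length growth levels off (for the 100-pixel square at
  μ = 0.10, FD rises 1.30 → ~1.33 by a few hundred iterations and then
  plateaus, and MDfO growth slows correspondingly).  Published figures
  for this class of method report FD continuing to ~1.56 at n = 1000,
  which implies boundaries folding back alongside themselves at
  single-pixel spacing; every guard relaxation we tested that permits
  this also permits occasional hole creation, so this implementation
  keeps the strict guard and accepts the saturation.
- REMOVE never fires in guarded runs (see rule 2 above); it remains
  available for unguarded rewriting and in the length accounting.
- The guard may reject rewrites that are in fact topologically safe
  (any bordering contact is refused); rejection rates are reported in
  the diagnostics.
- Hole counting assumes 4-connected background / 8-connected
  foreground; other connectivity conventions would need a different
  oracle.
- Only Freeman F8/F4 (and crack input) are supported; other chain-code
  families would need their own rulesets.
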