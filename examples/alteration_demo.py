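"""Apply each chain-code alteration to the demonstration paths.

Every rule rewrites one consecutive symbol pair into a replacement whose
net displacement is identical, so the curve's endpoints never move.  The
printed before/after strings are the full symbol sequences.
"""

from chainnoise import (
    cut_f8, demo_fixtures, flip_f4, flip_f8, pull_f8, push_f8,
    remove_f4, remove_f8, rotate_f8, wrap_f4, wrap_f8,
)


def rewrite(digits, pos1, result):
    symbols = [int(d) for d in digits]
    symbols[pos1 - 1:pos1 + 1] = list(result.replacement)
    return "".join(map(str, symbols))


f8_shape, f4_shape = demo_fixtures()
f8 = f8_shape.chains[0].digits()
c = [int(d) for d in f8]
f4 = f4_shape.chains[0].digits()
d = [int(x) for x in f4]

print(f"F8 demonstration path: {f8}")
for name, pos, res in [
    ("REMOVE", 1, remove_f8()),
    ("PUSH  ", 3, push_f8(c[2], "A")),
    ("WRAP  ", 5, wrap_f8(c[4], "B")),
    ("FLIP  ", 7, flip_f8(c[6], c[7])),
    ("PULL  ", 9, pull_f8(c[8], c[9])),
    ("CUT   ", 11, cut_f8(c[10], c[11])),
    ("ROTATE", 14, rotate_f8(c[13], c[14])),
]:
    print(f"  {name} at pair {pos:>2}: -> {rewrite(f8, pos, res)}")

print(f"\nF4 demonstration path: {f4}")
for name, pos, res in [
    ("WRAP  ", 1, wrap_f4(d[0], "B")),
    ("REMOVE", 5, remove_f4()),
    ("FLIP  ", 3, flip_f4(d[2], d[3])),
]:
    print(f"  {name} at pair {pos:>2}: -> {rewrite(f4, pos, res)}")

print("\nEach output differs from its input only inside the rewritten pair;")
print("REMOVE shortens by 2, CUT by 1, F8 WRAP lengthens by 1, F4 WRAP by 2.")
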