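"""Convert a crack code (edge walk) into a centre-format F4 chain.

A crack code traverses the edges between pixels; before noise injection
it must be converted to the format that steps between pixel centres.
The encoded pixel lies on the left of each crack step, so a
counter-clockwise tour of a pixel block yields its boundary ring.
"""

from chainnoise import Chain, CodeType, Role, crack_to_centre, rasterise_chain

for w, h in [(1, 1), (2, 1), (3, 3)]:
    tour = "0" * w + "1" * h + "2" * w + "3" * h
    crack = Chain.from_digits(tour, (0, 0), Role.LOOP, CodeType.F4_CRACK)
    centre = crack_to_centre(crack)
    pixels = sorted(set(rasterise_chain(centre).pixels))
    print(f"{w}x{h} block crack tour {tour!r}")
    print(f"  centre chain: {centre.digits()!r} starting at {centre.start}, "
          f"{len(pixels)} boundary pixel(s): {pixels}")

print("\nA single pixel has no centre-to-centre moves; larger blocks yield")
print("the ring of boundary pixel centres, ready for noise injection.")
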