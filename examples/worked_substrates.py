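"""Dice the classic bench substrates and print the product sizes.

Each substrate is a pair of complementary synthetic RNA strands; only
their lengths and end geometry matter. The engine measures 24 nt from
the recessed 5' terminus at the engaged end and makes a second cut
offset by 2 nt on the paired strand.
"""

from dcl3dice import DicingParams, DicingMode, dice, get_fixture

params = DicingParams()

for name in ("fig1C_37_38", "fig1C_37_39", "fig2A_24_25", "fig2B_23_24",
             "fig2C_24_23"):
    d = get_fixture(name)
    oc = dice(d, params)
    if oc.mode is DicingMode.DICED:
        print(
            f"{name}: {len(d.top)}/{len(d.bottom)} nt duplex, "
            f"left overhang {d.left_ext} -> diced at {oc.chosen_end.value}: "
            f"products {len(oc.product.top)} nt (top) + "
            f"{len(oc.product.bottom)} nt (bottom), "
            f"released fragments {[len(f) for f in oc.fragments]}"
        )
    else:
        print(
            f"{name}: {len(d.top)}/{len(d.bottom)} nt duplex -> {oc.mode.value}"
        )

# A 37/38 duplex with a 1-nt 3' overhang gives the canonical asymmetric
# 24 + 23 nt siRNA duplex; widening the overhang to 2 nt gives 24 + 24;
# the 24/23 product mimic is refractory (already a product, not recut).
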