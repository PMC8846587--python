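"""Enumerate the dicing routes over the end x delta grid.

For a tail-bearing precursor, the enzyme can engage the left end (the
RDR2 tail overhang) or the right end (the delta-nt overhang left by
internal RDR2 initiation). Deduplicating identical outcomes leaves two
routes to a 24-nt siRNA from each strand and one to a 23-nt siRNA.
"""

from dcl3dice import DicingParams, enumerate_routes, route_counts

routes = enumerate_routes(DicingParams())
print(routes.to_string(index=False))
print()
for (source, size), n in sorted(route_counts(routes).items(),
                                key=lambda kv: (kv[0][0].value, kv[0][1])):
    print(f"routes to a {size}-nt siRNA from the {source.value} strand: {n}")
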