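"""Compute FAP retention indices on the locked reference ladder.

The fatty-acid-pyrrolidide (FAP) ladder assigns every anchor exactly
100 x its carbon number; analytes interpolate linearly between the two
bracketing anchors.  The scale is invariant under affine drift of the
time axis, which is what makes it robust across runs and columns.
"""

import fapindex as fx

anchors = fx.FAPAnchorSet(fx.reference_anchor_times())
print("anchor ladder (minutes):")
for carbon, rt in sorted(anchors.anchors.items()):
    print(f"  {carbon}:0-P  {rt:7.3f}")

for rt in (32.972, 31.486, 27.19):
    ri = fx.compute_ri_fap(rt, anchors)
    print(f"RT {rt:6.3f} min -> RI_FAP {ri.rounded}  (bracket {ri.bracketing_carbons})")

# the inverse: where does a compound of index 2306 elute on this column?
t = fx.invert_ri_fap(2306, anchors)
print(f"RI 2306 (beta-sitosterol) -> {t:.3f} min")
# indices also work on any monotone proxy, e.g. the published RRT ladder
rrt_ladder = fx.FAPAnchorSet({22: 1.38, 23: 1.47})
print(f"stigmasterol RRT 1.42 -> RI {float(fx.compute_ri_fap(1.42, rrt_ladder)):.1f} "
      "(printed: 2247)")
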