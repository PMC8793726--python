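"""Genetic distance from a Marey map: interpolation and the 0.5 rule.

Builds a tiny two-chromosome genome with hand-written Marey maps and prints
the genetic distance between a few gene pairs.
"""

import numpy as np

from retrolink import GeneLocus, dist, genetic_position, validate_map

# chr1: 2 cM spread over 1 Mb; chr2: 4 cM over 2 Mb
marey = validate_map(
    {
        "chr1": (np.array([0, 1_000_000]), np.array([0.0, 2.0])),
        "chr2": (np.array([0, 2_000_000]), np.array([0.0, 4.0])),
    }
)

parent = GeneLocus.from_1based("parent", "chr1", 100_000, 102_000)
near = GeneLocus.point("near_copy", "chr1", 600_000)
far = GeneLocus.point("far_copy", "chr2", 1_500_000)

print(f"genetic position of parent midpoint: {genetic_position(marey, 'chr1', parent.point_bp):.4f} M")
print(f"dist(parent, same-chromosome copy) = {dist(parent, near, marey):.4f} M")
print(f"dist(parent, other-chromosome copy) = {dist(parent, far, marey):.4f} M")

# The first two numbers come from linear interpolation on the chr1 map
# (2 cM/Mb), so ~0.5 Mb of separation is ~0.01 Morgans.  The last is the
# fixed 0.5 Morgan convention for unlinked (interchromosomal) pairs.
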