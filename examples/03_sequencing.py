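"""Decompose a fluence map into deliverable MLC apertures.

Sweep (level) decomposition opens, at each intensity level, the bixels
whose quantised value reaches that level; with no cap on the segment
count the weighted sum of aperture masks rebuilds the map exactly.
"""

import numpy as np

import beamsel as bs

fmap = np.array([[0.0, 1.2, 2.4, 2.4, 1.2],
                 [1.2, 2.4, 3.6, 2.4, 1.2],
                 [0.0, 1.2, 2.4, 1.2, 0.0]])
intmap = bs.quantize_fluence(fmap, levels=3)
print("quantised map:\n", intmap)

result = bs.sweep_sequence(intmap)
print(f"\n{len(result.apertures)} apertures "
      f"(exact reconstruction: {result.exact})")
total = np.zeros(intmap.shape)
for k, ap in enumerate(result.apertures):
    print(f"  aperture {k}: weight {ap.weight:.0f}, rows {ap.rows}")
    total += ap.weight * ap.mask(intmap.shape[1])
print("\nweighted sum of masks:\n", total.astype(int))
assert np.array_equal(total.astype(int), intmap)
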