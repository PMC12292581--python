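"""Augmentation-vote uncertainty and interval-sampled replay buffer.

Trains a tiny CNN on a 4-class set, scores each image by the disagreement of
argmax votes over S=10 stochastic augmentations, then fills a 40-slot
class-balanced buffer by evenly spaced ranks of the uncertainty-sorted
candidates — so the buffer spans representative (low-U) through diverse
(high-U) samples.
"""

import numpy as np

from dscnl import (AugmentationSpec, MemoryBuffer, estimate_uncertainties,
                   generate_synthetic_dataset, make_backbone, update_buffer)

ds = generate_synthetic_dataset(4, 100, 32, 1.0, seed=1)
net = make_backbone(4, 32, seed=1)
rng = np.random.default_rng(1)
for _ in range(8):
    net.train_epoch(ds.images, ds.true_labels, rng=rng)

spec = AugmentationSpec(S=10, family="mix")
u = estimate_uncertainties(net, ds.images, spec,
                           rng=np.random.default_rng(2))
print(f"uncertainty over {len(u)} samples: min={u.min():.2f} "
      f"mean={u.mean():.3f} max={u.max():.2f} (bounded by 1 - 1/S = 0.9)")

buffer = MemoryBuffer(capacity=40)
update_buffer(buffer, ds.images, ds.true_labels, u, classes_seen=[0, 1, 2, 3])
print("per-class buffer counts:", buffer.class_counts(), "(quota 40/4 = 10)")
for c in buffer.class_order:
    s = buffer.stores[c]
    print(f"  class {c}: stored uncertainty spectrum "
          f"{s.uncertainties.min():.2f} .. {s.uncertainties.max():.2f}")
# Both spectrum endpoints of every class are stored: the most stable
# (class-centre) and most fragile (boundary) samples are always replayed.
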