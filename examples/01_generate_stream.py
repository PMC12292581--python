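"""Generate a synthetic noisy class-incremental stream and write it to NPZ.

Builds an 8-class desk-scale image stream (distinct per-class colour/texture
templates), corrupts 30% of the training labels symmetrically, splits the
classes into four binary tasks, and saves the archive in the
train/test-images/labels NPZ dialect.
"""

import numpy as np

from dscnl import (NoiseSpec, generate_synthetic_dataset,
                   inject_symmetric_noise, split_tasks, write_npz_dataset)

train = generate_synthetic_dataset(n_classes=8, n_per_class=200,
                                   image_size=32, separability=1.0, seed=7)
test = generate_synthetic_dataset(8, 50, 32, 1.0, seed=8, split="test")
train = inject_symmetric_noise(train, NoiseSpec(rate=0.3, seed=7))

before = np.bincount(train.true_labels)
after = np.bincount(train.noisy_labels)
print("per-class counts before noise:", before.tolist())
print("per-class counts after noise: ", after.tolist())
print(f"realised noise fraction: {train.noise_fraction:.3f} "
      "(exactly round(0.3*N)/N by construction)")

tasks = split_tasks(train, [{0, 1}, {2, 3}, {4, 5}, {6, 7}])
print("task sizes (by observed label):",
      [len(ix) for ix in tasks.task_indices])

write_npz_dataset(train, test, "scratch_stream.npz")
print("wrote scratch_stream.npz — both label vectors and uint8 images")
# Counts move toward the uniform mixture (1-rho)B_c + rho(N-B_c)/(K-1):
# noise drains large classes and feeds small ones, while the total N and
# the exact corrupted-sample count stay fixed.
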