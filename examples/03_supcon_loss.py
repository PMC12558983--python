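"""The supervised contrastive loss and its closed-form sanity checks.

For 2N views with unit-norm projections z and labels y:
    L = sum_i -1/|P(i)| sum_{p in P(i)} log softmax_a(z_i . z_a / tau)[p]
"""

import numpy as np

from purecl import MultiviewBatch, supcon_loss, supcon_loss_oracle
from purecl.nn import Tensor

rng = np.random.default_rng(0)
n = 4
z = rng.standard_normal((2 * n, 8))
z /= np.linalg.norm(z, axis=1, keepdims=True)
labels = np.repeat([0, 0, 1, 1], 2)

batch = MultiviewBatch(Tensor(z), labels, temperature=0.07)
fast = supcon_loss(batch, reduction="sum").item()
slow = supcon_loss_oracle(batch, reduction="sum")
print(f"vectorized: {fast:.6f}   triple-loop oracle: {slow:.6f}   "
      f"|diff| = {abs(fast - slow):.2e}")

ident = MultiviewBatch(Tensor(np.tile(z[:1], (2 * n, 1))), labels, 0.5)
print(f"identical projections, per anchor: "
      f"{supcon_loss(ident).item():.6f}  (log(2N-1) = {np.log(2 * n - 1):.6f})")
# With all projections equal every softmax is uniform over the 2N-1 other
# views, so each anchor contributes exactly log(2N-1).
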