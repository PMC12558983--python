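"""Run the feature-purification encoder and inspect its contracts.

The encoder stacks five residual stages; multi-scale attention modules
after stages 1-2 capture low-level interference features, which are
subtracted from (or, after the schedule switch, added to) the deeper
stage-3/4 features before the final stage pools to a 2048-d unit vector.
"""

import numpy as np

from purecl import FeaturePurificationEncoder, FilterMode, filter_mode_for_epoch
from purecl.nn import Tensor

encoder = FeaturePurificationEncoder(0)
x = np.random.default_rng(1).random((2, 3, 64, 64), dtype=np.float32)

emb_sub = encoder(Tensor(x), FilterMode.SUBTRACT)
emb_add = encoder(Tensor(x), FilterMode.ADD)
print(f"embedding shape: {emb_sub.shape}, norms: "
      f"{np.linalg.norm(emb_sub.data, axis=1).round(6)}")
cos = (emb_sub.data * emb_add.data).sum(axis=1)
print(f"cosine(subtract, add) per image: {cos.round(4)}  (< 1: the mode matters)")
for wmap in encoder.attention1.last_weight_maps:
    print(f"attention weight map: shape {wmap.shape}, "
          f"range ({wmap.min():.3f}, {wmap.max():.3f})")

print("schedule:", [filter_mode_for_epoch(e, 15).value for e in (0, 14, 15, 16)])
# Epochs 0-14 subtract the interference features ("reverse learning");
# from epoch 15 on they are added back.
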