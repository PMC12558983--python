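"""Build W-Paste positive pairs and verify the perturbation is local.

W-Paste cuts two 15x15 rectangles from a sample and fills them with crops
from other samples, yielding two semantically perturbed views of the same
image for contrastive training.
"""

import numpy as np

from purecl import (SyntheticDatasetSpec, WPasteConfig, generate_synthetic_dataset,
                    make_positive_pair, w_paste_detailed)

images = generate_synthetic_dataset(SyntheticDatasetSpec(n_classes=2, n_per_class=4, seed=3))
anchor, pool = images[0], images[1:]
rng = np.random.default_rng(0)

out, records = w_paste_detailed(anchor, pool, WPasteConfig(), rng)
changed = int(np.any(out != anchor.pixels, axis=0).sum())
print(f"pixels changed: {changed} (<= 2 x 15 x 15 = 450)")
for rec in records:
    print(f"  pasted {rec.size} at {rec.target_origin} from donor {rec.donor_index}"
          f" crop {rec.donor_origin}")

pair = make_positive_pair(anchor, pool, WPasteConfig(), rng)
print(f"positive pair: label={pair.label}, views differ on "
      f"{int(np.any(pair.view_a != pair.view_b, axis=0).sum())} pixels")
# Both views keep the anchor's label; only small rectangles differ, so the
# pair represents two plausible corruptions of the same leaf.
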