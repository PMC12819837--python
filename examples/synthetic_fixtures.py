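"""Generate the three synthetic imagery regimes and the doubling policy.

Produces spot-vs-strip lesion images (classification), intertwined
crop/weed scenes with pixel masks (segmentation), and sparse/dense
lesion boxes (detection), then applies the augmentation policy that
doubles every class.  Printed fractions show the structural contrasts
the generators guarantee.
"""

import numpy as np

from seafec import (
    augment_double,
    gen_classification_fixture,
    gen_detection_fixture,
    gen_segmentation_fixture,
    split_samples,
)

cls = gen_classification_fixture(25, image_size=32, seed=0)
spot = np.mean([s.meta["lesion_fraction"] for s in cls if s.label == 0])
strip = np.mean([s.meta["lesion_fraction"] for s in cls if s.label == 1])
print(f"classification: {len(cls)} samples; mean lesion cover "
      f"spots {spot:.3f} < strips {strip:.3f}")

seg = gen_segmentation_fixture(20, image_size=32, weed_fraction=0.05, seed=0)
weed = np.mean([(s.mask == 2).mean() for s in seg])
print(f"segmentation: mean weed pixel share {weed:.3f} (requested 0.050); "
      f"mask classes {np.unique(seg[0].mask).tolist()}")

det_sparse = gen_detection_fixture(10, density="sparse", seed=0)
det_dense = gen_detection_fixture(10, density="dense", seed=0)
print(f"detection: sparse images carry {[len(s.boxes) for s in det_sparse[:5]]} boxes, "
      f"dense images {[len(s.boxes) for s in det_dense[:5]]}")

doubled = augment_double(cls, seed=1)
print(f"doubling policy: {len(cls)} -> {len(doubled)} samples "
      f"({sum(1 for s in doubled if s.label == 0)} per class)")

splits = split_samples(doubled, (0.7, 0.2, 0.1), seed=0)
print("7:2:1 split sizes:", {k: len(v) for k, v in splits.items()})
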