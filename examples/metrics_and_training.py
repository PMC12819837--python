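"""Score predictions with the three metric suites, then smoke-train.

First evaluates hand-sized examples with the classification,
segmentation and detection metrics; then trains the attention-branch
classifier on the spot-vs-strip fixture until it fits it, demonstrating
that the surgered network optimises end to end.
"""

import numpy as np

from seafec import (
    SurgeryPlan,
    build_seafec_resnet18,
    classification_metrics,
    detection_map,
    gen_classification_fixture,
    segmentation_metrics,
    smoke_train,
)
from seafec.fixtures import samples_to_arrays

rep = classification_metrics([1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
                             [1, 1, 1, 0, 0, 1, 0, 0, 0, 0], n_classes=2)
print("classification:", {k: round(v, 3) for k, v in rep.metrics.items()})

t = np.array([[0, 0], [1, 1]])
p = np.array([[0, 1], [1, 1]])
print("segmentation on a 2x2 toy case:",
      {k: round(v, 3) for k, v in segmentation_metrics(t, p, 2).metrics.items()},
      "(IoU 1/2 and 2/3 -> mIoU 7/12)")

det = detection_map(
    gt_boxes=[np.array([[0, 0, 10, 10], [20, 20, 30, 30]], float)],
    gt_labels=[np.array([0, 0])],
    pred_boxes=[np.array([[50, 50, 60, 60], [0, 0, 10, 11], [20, 20, 30, 29]], float)],
    pred_scores=[np.array([0.9, 0.8, 0.7])],
    pred_labels=[np.array([0, 0, 0])],
)
print("detection (top-scored box misses, next two hit):",
      {k: round(v, 3) for k, v in det.metrics.items()})

samples = gen_classification_fixture(40, image_size=32, seed=0)
images, labels = samples_to_arrays(samples)
model = build_seafec_resnet18(SurgeryPlan("resnet18", "scarf", num_classes=2, seed=42))
hist = smoke_train(model, images, labels, epochs=30, seed=42, stop_at_accuracy=1.0)
print(f"smoke training (scarf variant, {len(labels)} images): "
      f"fit in {hist.epochs} epochs, losses {[round(l, 3) for l in hist.losses]}")
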