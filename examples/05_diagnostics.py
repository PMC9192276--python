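"""Score a diagnostic read: confusion-matrix metrics and ROC/AUC.

The counts A/B/C/D are true positives, true negatives, false positives and
false negatives of a reader calling lesions on reconstructed images; the ROC
curve sweeps a score threshold and its area summarizes ranking ability.
"""

import numpy as np

from ctsurf import ConfusionMatrix, confusion_metrics, roc_curve

m = confusion_metrics(ConfusionMatrix(A=90, B=80, C=10, D=20))
acc, spe, sen = m.as_percentages()
print(f"accuracy {acc:.2f}%  specificity {spe:.2f}%  sensitivity {sen:.2f}%")

# a synthetic reader study: positives score higher on average
rng = np.random.default_rng(0)
labels = rng.integers(0, 2, size=300)
scores = labels + rng.normal(scale=0.8, size=300)
roc = roc_curve(scores, labels)
print(f"AUC = {roc.auc:.3f} over {len(labels)} cases "
      "(0.5 = chance ranking, 1.0 = perfect separation)")
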