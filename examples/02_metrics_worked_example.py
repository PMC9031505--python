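"""Segmentation and volumetry metrics from hand-set confusion counts.

With TP=3, FP=1, FN=1 every pixel-overlap metric can be checked by hand:
sensitivity 3/4, the tables' "specificity" TP/(TP+FP) 3/4 (conventionally
precision; the conventional specificity TN/(TN+FP) is reported separately),
F1 3/4, Jaccard 3/5.  Volume similarity compares only the predicted and
labeled pixel totals, so balanced FP and FN give VS = 1 even with imperfect
overlap.
"""

from strokevol.evaluation import (
    ConfusionCounts,
    f1,
    jaccard,
    sensitivity,
    specificity_as_printed,
    true_specificity,
    volume_similarity,
)

c = ConfusionCounts(tp=3, fp=1, fn=1, tn=95)
print(f"sensitivity            TP/(TP+FN) = {sensitivity(c):.2f}")
print(f"specificity (printed)  TP/(TP+FP) = {specificity_as_printed(c):.2f}")
print(f"true specificity       TN/(TN+FP) = {true_specificity(c):.4f}")
print(f"F1 score                          = {f1(c):.2f}")
print(f"Jaccard index          TP/(TP+FP+FN) = {jaccard(c):.2f}")
print(f"volume similarity      1-|FN-FP|/(2TP+FP+FN) = {volume_similarity(c):.2f}")
# FP == FN here, so predicted and labeled volumes agree exactly: VS = 1.0
# while Jaccard is only 0.6 — VS measures volume agreement, not localization.
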