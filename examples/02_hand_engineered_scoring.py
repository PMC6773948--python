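"""Train and apply the hand-engineered cellularity scorer.

Trains the SVM cell classifier and isotonic calibration on a small seeded
benchmark, scores held-out patches, and prints predicted vs true
cellularity. Expect errors of a few percentage points at this scale.
"""

import numpy as np

from tcquant import benchmark_patches, score_patch_hand_engineered, train_hand_engineered

train = benchmark_patches(20, seed=101)
test = benchmark_patches(8, seed=202)

models = train_hand_engineered(train)

errors = []
print("patch        predicted   true")
for patch in test:
    score = score_patch_hand_engineered(patch.rgb, models, patch.patch_id)
    errors.append(abs(score.value - patch.true_tc_percent))
    print(f"{patch.patch_id}   {score.value:7.1f}%  {patch.true_tc_percent:5.1f}%")
print(f"\nmean absolute error: {np.mean(errors):.2f} percentage points")

# The scorer segments nuclei, classifies each as lymphocyte/epithelial/
# malignant, dilates the malignant mask by the 2.5 um cytoplasm radius,
# measures the covered area fraction and calibrates it to a 0-100% score.
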