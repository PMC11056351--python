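"""One-vs-rest evaluation tables from a confusion matrix.

Per-class accuracy counts true negatives, so with several classes its
macro mean sits above pooled accuracy whenever any sample is wrong.
"""

import numpy as np

import scmpmixer.metrics as me

# a 4-class test run: rows = true class, columns = predicted class
counts = np.array([
    [523, 40, 0, 60],
    [1, 617, 0, 2],
    [10, 2, 582, 26],
    [66, 8, 1, 549],
])
cm = me.ConfusionMatrix(counts, ["EO", "L", "M", "N"])

frame = me.report(cm)
print(frame.to_string(index=False))
print(f"pooled (plain) accuracy: {me.pooled_accuracy(cm):.2f}%")
# The MACRO row is the unweighted mean of the per-class rows, computed on
# unrounded values and rounded half-up to two decimals only for display.
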