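"""Build the full-scale SC-MP-Mixer and inspect its structure.

One forward pass shows the multipath token bookkeeping: the two Swin
branches contribute 28*28 = 784 and 14*14 = 196 tokens of width 256,
concatenating to the 980x256 matrix that global average pooling reduces
before the softmax head.
"""

import numpy as np

import scmpmixer as sm

model = sm.build_model(sm.paper_config(num_classes=4, seed=0))
x = np.random.default_rng(0).random((1, 224, 224, 3), dtype=np.float32)

features = model.forward_features(x)
probs = model.head.forward(features)

print(f"input:               {x.shape}")
print(f"token matrix to GAP: {features.shape}  "
      f"(branch tokens {model.mpst.token_counts})")
print(f"class probabilities: {np.round(probs, 4)} (sum {probs.sum():.4f})")

summary = sm.architecture_summary(model)
print(f"parameters: {summary['parameters']:,} "
      f"by component {summary['parameters_by_component']}")
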