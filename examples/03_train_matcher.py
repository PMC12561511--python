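"""Train the curvature-feature matcher on a handful of synthetic pairs.

Training minimizes the symmetric negative log-likelihood of ground-truth
keypoint correspondences under the temperature-softmax match matrix. The
loss should fall well below the uniform-matching baseline ln(N); the
temperature is learned jointly.
"""

import numpy as np

import spinereg as sr

pairs = [sr.make_pair(sr.PairSpec(seed=100 + i)) for i in range(32)]
triples = sr.training_triples_from_pairs(pairs, n_crops=3, seed=0)
print(f"{len(triples)} training crops from {len(pairs)} pairs")

model = sr.train(triples, sr.small_encoder_config(),
                 sr.small_training_config(epochs=20))
for epoch, lr, loss in model.history[::3] + [model.history[-1]]:
    print(f"  epoch {epoch:2d}  lr {lr:.1e}  loss {loss:.3f}")
print(f"learned softmax temperature: {model.temperature:.3f}")

sr.save_model(model, "matcher.npz")
print("wrote matcher.npz")
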