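"""Pool a bag of instance embeddings with gated attention.

Builds a tiny synthetic bag in which two instances carry a distinctive
signal, scores every instance with the gated attention mechanism, and
prints the weights and the pooled slide-level vector.
"""

import numpy as np

from ssmil import Bag, GatedAttentionParams, pool

rng = np.random.default_rng(0)

# 8 background instances near the origin, 2 "tumor" instances offset in
# embedding space
H = rng.normal(0, 0.3, size=(10, 4))
H[3] += [3, 0, 0, 0]
H[7] += [3, 0, 0, 0]
bag = Bag(slide_id="demo", instances=H)

params = GatedAttentionParams.random(embedding_dim=4, attention_dim=8, rng=rng)
enc = pool(bag, params)

print("attention weights (sum = %.3f):" % enc.attention.sum())
for k, a in enumerate(enc.attention):
    print(f"  instance {k}: {a:.3f}" + ("   <- offset instance" if k in (3, 7) else ""))
print("pooled z:", np.round(enc.z, 3))
print()
print("The weights are a softmax over gated scores, so they are positive and")
print("sum to one; z is the attention-weighted average of the instances and")
print("therefore lies inside their convex hull. With random (untrained)")
print("parameters the weights are roughly uniform — training moves them.")
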