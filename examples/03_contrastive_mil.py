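"""Train contrastive MIL on synthetic bags and probe the representations.

Generates a cohort of slides as bags of Gaussian-mixture embeddings
(shared + class-unique microanatomy clusters), trains the attention
aggregator contrastively WITHOUT using any label, then evaluates the
label-free slide representations with a frozen linear probe.
"""

import numpy as np

from ssmil import (SyntheticBagConfig, auc, generate_bags, make_folds,
                   train_head, train_ssmil)
from ssmil.attention import attention_weights
from ssmil.contrastive import SSMILSchedule
from ssmil.evaluate import HeadSchedule

cfg = SyntheticBagConfig(n_slides=80, instances_per_slide=100, embed_dim=32,
                         n_shared_clusters=6, n_unique_clusters_per_class=2,
                         unique_fraction=0.2, effect_size=4.0, seed=7)
bags = generate_bags(cfg)
by = {b.slide_id: b for b in bags}
fold = make_folds([b.slide_id for b in bags], [b.label for b in bags], seed=7)[0]
train = [by[i] for i in fold.train_ids]
val = [by[i] for i in fold.val_ids]
test = [by[i] for i in fold.test_ids]

model, log = train_ssmil(train, val,
                         schedule=SSMILSchedule(epochs=120, seed=7, eval_every=5))
print(f"contrastive loss: {log['train_loss'][0]:.3f} -> {log['train_loss'][-1]:.3f} "
      f"(best epoch {log['best_epoch']})")

probe, _ = train_head(train, val, "frozen", "classification",
                      ssmil_model=model, schedule=HeadSchedule(seed=7))
test_auc = auc(probe.predict(test), [b.label for b in test])
print(f"frozen-probe test AUC: {test_auc:.3f}  (labels never touched the backbone)")

# does the trained attention favor the class-unique microanatomy?
params = model.attention.to_params()
uq, sh = [], []
for b in bags:
    a = attention_weights(b, params)
    mask = b.instance_clusters >= cfg.n_shared_clusters
    uq.append(a[mask].mean())
    sh.append(a[~mask].mean())
print(f"mean attention weight, unique vs shared instances: "
      f"{np.mean(uq):.5f} vs {np.mean(sh):.5f} "
      f"(ratio {np.mean(uq)/np.mean(sh):.2f})")
print()
print("A ratio above 1 confirms the central mechanism: to separate slides,")
print("the contrastive objective pushes attention onto instances unique to")
print("each slide's class, not the microanatomy shared by everyone.")
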