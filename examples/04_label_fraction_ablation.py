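"""Label-fraction ablation: supervised vs fine-tuned vs frozen.

Runs the cross-validated evaluation grid on a moderate-effect synthetic
cohort with 25/50/75% of training labels and prints the Table-style
summary (mean +- sd over folds).
"""

from ssmil import SyntheticBagConfig, generate_bags
from ssmil.contrastive import SSMILSchedule
from ssmil.evaluate import HeadSchedule, run_ablation, summarize_ablation

cfg = SyntheticBagConfig(n_slides=60, instances_per_slide=80, embed_dim=32,
                         n_shared_clusters=6, n_unique_clusters_per_class=2,
                         unique_fraction=0.2, effect_size=2.5, seed=3)
bags = generate_bags(cfg)

table = run_ablation(bags, regimes=("supervised", "fine_tune", "frozen"),
                     fractions=(0.25, 0.5, 0.75), seed=3, fold_subset=(0,),
                     ssmil_schedule=SSMILSchedule(epochs=80, seed=3, eval_every=5),
                     head_schedule=HeadSchedule(seed=3))
print(summarize_ablation(table).to_string(index=False))
print()
print("Expected structure: AUC grows with the label fraction; the frozen")
print("probe trails fine-tuning, which adapts the pretrained attention to")
print("the labels. (At this miniature cohort size individual cells are")
print("noisy - the acceptance studies average 5 seeds x 2 folds.)")
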