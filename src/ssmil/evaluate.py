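"""Downstream evaluation protocol for slide-level representations.

Five-fold cross-validation with 60/20/20 train/validation/test splits whose
test sets partition the cohort; three training regimes —

* ``supervised``  — gated attention MIL trained from scratch on labels;
* ``fine_tune``   — contrastively pretrained attention, new output layer,
                    all parameters trainable;
* ``frozen``      — slide representations fixed, only a new linear layer
                    is trained;

a label-fraction ablation (25/50/75/100% of training labels, nested under a
fixed seed); and the metrics the protocol reports: sensitivity, specificity
and AUC for classification, squared Pearson correlation for regression.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from ._autodiff import Tensor, softmax
from .attention import Bag, GatedAttentionPooling
from .contrastive import SSMILModel, SSMILSchedule, represent_bags, train_ssmil
from .nn import Adam, Linear, Module, cross_entropy, mse_loss

__all__ = [
    "FoldSplit", "make_folds", "subsample_labels",
    "HeadSchedule", "ABMILPredictor", "FrozenProbe", "train_head",
    "auc", "sensitivity_specificity", "r_squared",
    "run_ablation", "summarize_ablation",
]

REGIMES = ("supervised", "fine_tune", "frozen")


# ------------------------------------------------------------------- folds

@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def make_folds(slide_ids: Sequence[str], labels: Sequence | None = None,
               seed: int = 0, n_folds: int = 5) -> list[FoldSplit]:
    """5 splits with ~60/20/20 proportions and partitioning test sets.

    The cohort is cut into ``n_folds`` groups (class-stratified when labels
    allow); fold i uses group i as test, group i+1 as validation and the
    remaining groups as training, so test sets are mutually exclusive and
    jointly exhaustive.
    """
    ids = np.asarray(slide_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} slides, got {len(ids)}")
    y = None if labels is None else np.asarray(labels)
    stratify = (y is not None and y.dtype.kind in "biu"
                and np.min(np.bincount(y.astype(int))) >= n_folds)
    if stratify:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        groups = [test for _, test in splitter.split(ids, y)]
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        groups = [test for _, test in splitter.split(ids)]
    folds = []
    for i in range(n_folds):
        test = groups[i]
        val = groups[(i + 1) % n_folds]
        train = np.concatenate([groups[j] for j in range(n_folds)
                                if j not in (i, (i + 1) % n_folds)])
        folds.append(FoldSplit(fold_id=i,
                               train_ids=tuple(ids[sorted(train)]),
                               val_ids=tuple(ids[sorted(val)]),
                               test_ids=tuple(ids[sorted(test)])))
    return folds


def subsample_labels(train_ids: Sequence[str], labels: Sequence,
                     fraction: float, seed: int = 0) -> list[str]:
    """Stratified subset of the training ids; nested across fractions.

    Under a fixed seed the 25% subset is contained in the 50% subset, which
    is contained in the 75% subset, because each class keeps a single seeded
    permutation and takes a prefix of it.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    ids = np.asarray(train_ids)
    y = np.asarray(labels)
    if fraction == 1.0:
        return list(ids)
    chosen: list[str] = []
    if y.dtype.kind in "biu":
        for cls in np.unique(y):
            members = ids[y == cls]
            if members.size == 0:
                raise ValueError(f"class {cls} absent from training set")
            rng = np.random.default_rng(np.random.SeedSequence([seed, int(cls)]))
            perm = rng.permutation(members.size)
            k = max(1, int(round(fraction * members.size)))
            chosen.extend(members[perm[:k]])
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(ids.size)
        k = max(1, int(round(fraction * ids.size)))
        chosen.extend(ids[perm[:k]])
    order = {s: i for i, s in enumerate(ids)}
    return sorted(chosen, key=order.get)


# ------------------------------------------------------------------ metrics

def auc(scores: Sequence[float], binary_labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative),
    ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def sensitivity_specificity(scores: Sequence[float], labels: Sequence[int],
                            threshold: float = 0.5) -> tuple[float, float]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("need both classes present")
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    return tp / (tp + fn), tn / (tn + fp)


def r_squared(predictions: Sequence[float], targets: Sequence[float],
              mode: str = "pearson") -> float:
    """Squared Pearson correlation (default) or coefficient of determination."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(t) == 0:
        raise ValueError("targets are constant; correlation undefined")
    if mode == "pearson":
        if np.ptp(p) == 0:
            raise ValueError("predictions are constant; correlation undefined")
        r = np.corrcoef(p, t)[0, 1]
        return float(r * r)
    if mode == "determination":
        ss_res = float(((t - p) ** 2).sum())
        ss_tot = float(((t - t.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown mode {mode!r}")


# -------------------------------------------------------------------- heads

@dataclass
class HeadSchedule:
    """Supervised / fine-tune / frozen-probe training schedule."""

    epochs: int = 500             # linear-head fits (cheap, convex, slow)
    patience: int = 100
    full_model_epochs: int = 300  # supervised / fine-tune stage 2
    full_model_patience: int = 60
    supervised_lr: float = 3e-3   # from-scratch training
    finetune_lr: float = 1e-3     # lower, to preserve the pretrained attention
    head_lr: float = 1e-2         # frozen linear probe: convex fit, run to
                                  # convergence so head init noise vanishes
    # a fine-tune checkpoint replaces the warm-start probe solution only when
    # it improves validation loss by a meaningful margin; guards against
    # checkpoint churn on small validation sets
    finetune_min_delta: float = 0.01
    weight_decay: float = 1e-5
    batch_size: int = 70
    seed: int = 0


class ABMILPredictor(Module):
    """Gated attention MIL with a linear output head (2 logits or 1 score)."""

    def __init__(self, embedding_dim: int, task: str, attention_dim: int = 128,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        if task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        self.task = task
        self.attention = GatedAttentionPooling(embedding_dim, attention_dim, rng)
        self.head = Linear(embedding_dim, 2 if task == "classification" else 1, rng)

    def logits(self, bags: Sequence[Bag]) -> Tensor:
        sizes = {b.size for b in bags}
        if len(sizes) == 1:
            stacked = np.stack([b.instances for b in bags])
            z, _ = self.attention.forward_batch(stacked)
            return self.head(z)
        outs = []
        for b in bags:
            z, _ = self.attention.forward(b.instances)
            outs.append(self.head(z.reshape(1, -1)))
        from .contrastive import _stack_rows

        return _stack_rows(outs)

    def predict(self, bags: Sequence[Bag]) -> np.ndarray:
        """Positive-class probability (classification) or real score."""
        out = self.logits(list(bags))
        if self.task == "classification":
            return softmax(out, axis=1).data[:, 1]
        return out.data[:, 0]


class FrozenProbe:
    """Linear layer on fixed contrastive-MIL slide representations."""

    def __init__(self, ssmil_model: SSMILModel, task: str,
                 rng: np.random.Generator | None = None):
        self.ssmil_model = ssmil_model
        self.task = task
        self.head = Linear(ssmil_model.embedding_dim,
                           2 if task == "classification" else 1,
                           rng if rng is not None else np.random.default_rng(0))

    def parameters(self):
        return self.head.parameters()  # the backbone stays untouched

    def representations(self, bags: Sequence[Bag]) -> np.ndarray:
        return represent_bags(self.ssmil_model, bags)

    def logits_from_reps(self, reps: np.ndarray) -> Tensor:
        return self.head(Tensor(reps))

    def predict(self, bags: Sequence[Bag]) -> np.ndarray:
        out = self.logits_from_reps(self.representations(bags))
        if self.task == "classification":
            return softmax(out, axis=1).data[:, 1]
        return out.data[:, 0]


def _supervised_loss(pred: Tensor, labels: np.ndarray, task: str) -> Tensor:
    if task == "classification":
        return cross_entropy(pred, labels)
    return mse_loss(pred.reshape(pred.shape[0]), labels)


def _fit_linear_head(head: Linear, reps_tr: np.ndarray, reps_va: np.ndarray,
                     labels_tr: np.ndarray, labels_va: np.ndarray, task: str,
                     schedule: "HeadSchedule", log: dict) -> None:
    """Train ``head`` on fixed representations, early stopping on val loss."""
    optimizer = Adam(head.parameters(), lr=schedule.head_lr,
                     weight_decay=schedule.weight_decay)
    best_val, best_state, stale = np.inf, None, 0
    for _ in range(schedule.epochs):
        loss = _supervised_loss(head(Tensor(reps_tr)), labels_tr, task)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        val = _supervised_loss(head(Tensor(reps_va)), labels_va, task).item()
        log["train_loss"].append(loss.item())
        log["val_loss"].append(val)
        if val < best_val - 1e-12:
            best_val, best_state, stale = val, copy.deepcopy(head.state_dict()), 0
        else:
            stale += 1
            if stale >= schedule.patience:
                break
    if best_state is not None:
        head.load_state_dict(best_state)


def train_head(train_bags: Sequence[Bag], val_bags: Sequence[Bag],
               regime: str, task: str,
               ssmil_model: SSMILModel | None = None,
               schedule: HeadSchedule | None = None):
    """Train a predictor in one of the three regimes; early stop on val loss.

    Returns (predictor, log). ``fine_tune`` and ``frozen`` require a trained
    contrastive MIL model; ``frozen`` leaves its parameters bit-identical.
    """
    schedule = schedule or HeadSchedule()
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    if regime in ("fine_tune", "frozen") and ssmil_model is None:
        raise ValueError(f"{regime} regime requires a trained contrastive MIL model")
    labels_tr = np.asarray([b.label for b in train_bags])
    labels_va = np.asarray([b.label for b in val_bags])
    if task == "classification":
        labels_tr = labels_tr.astype(int)
        labels_va = labels_va.astype(int)
    rng = np.random.default_rng(np.random.SeedSequence([schedule.seed, 7]))
    # output heads across regimes share one seeded init so the frozen probe
    # and the fine-tune warm start are exactly paired
    head_rng = np.random.default_rng(np.random.SeedSequence([schedule.seed, 13]))
    dim = train_bags[0].dim
    log: dict = {"train_loss": [], "val_loss": []}

    if regime == "frozen":
        probe = FrozenProbe(ssmil_model, task, head_rng)
        reps_tr = probe.representations(train_bags)
        reps_va = probe.representations(val_bags)
        _fit_linear_head(probe.head, reps_tr, reps_va, labels_tr, labels_va,
                         task, schedule, log)
        return probe, log

    predictor = ABMILPredictor(dim, task,
                               attention_dim=(ssmil_model.attention.attention_dim
                                              if regime == "fine_tune"
                                              else 128),
                               rng=rng)
    predictor.head = Linear(dim, 2 if task == "classification" else 1, head_rng)
    best_val, best_state, stale = np.inf, None, 0
    if regime == "fine_tune":
        # probe-then-fine-tune: start from the contrastively learned attention
        # and a head warm-started on frozen representations, so fine-tuning
        # cannot start by wrecking the pretrained features with a random head
        att_state = {k.split(".", 1)[1]: v
                     for k, v in ssmil_model.state_dict().items()
                     if k.startswith("attention.")}
        predictor.attention.load_state_dict(att_state)
        reps_tr = represent_bags(ssmil_model, train_bags)
        reps_va = represent_bags(ssmil_model, val_bags)
        _fit_linear_head(predictor.head, reps_tr, reps_va, labels_tr, labels_va,
                         task, schedule, {"train_loss": [], "val_loss": []})
        best_val = _supervised_loss(predictor.logits(list(val_bags)),
                                    labels_va, task).item()
        best_state = copy.deepcopy(predictor.state_dict())
    optimizer = Adam(predictor.parameters(),
                     lr=(schedule.finetune_lr if regime == "fine_tune"
                         else schedule.supervised_lr),
                     weight_decay=schedule.weight_decay)
    shuffle_entropy = int(np.random.SeedSequence(
        [schedule.seed, 11]).generate_state(1)[0] % (2 ** 31))
    min_delta = schedule.finetune_min_delta if regime == "fine_tune" else 1e-12
    for epoch in range(schedule.full_model_epochs):
        erng = np.random.default_rng((shuffle_entropy + epoch) % (2 ** 31))
        order = erng.permutation(len(train_bags))
        losses = []
        for start in range(0, len(order), schedule.batch_size):
            idx = order[start:start + schedule.batch_size]
            batch = [train_bags[i] for i in idx]
            loss = _supervised_loss(predictor.logits(batch), labels_tr[idx], task)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        val = _supervised_loss(predictor.logits(list(val_bags)), labels_va, task).item()
        log["train_loss"].append(float(np.mean(losses)))
        log["val_loss"].append(val)
        if val < best_val - min_delta:
            best_val, best_state, stale = val, copy.deepcopy(predictor.state_dict()), 0
        else:
            stale += 1
            if stale >= schedule.full_model_patience:
                break
    if best_state is not None:
        predictor.load_state_dict(best_state)
    return predictor, log


# ----------------------------------------------------------------- protocol

def _metric_row(scores: np.ndarray, labels: np.ndarray, task: str) -> dict:
    if task == "classification":
        sens, spec = sensitivity_specificity(scores, labels)
        return {"sensitivity": sens, "specificity": spec,
                "auc": auc(scores, labels)}
    return {"r2": r_squared(scores, labels)}


def run_ablation(bags: Sequence[Bag], task: str = "classification",
                 regimes: Sequence[str] = REGIMES,
                 fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
                 seed: int = 0,
                 folds: Sequence[FoldSplit] | None = None,
                 fold_subset: Sequence[int] | None = None,
                 ssmil_schedule: SSMILSchedule | None = None,
                 head_schedule: HeadSchedule | None = None,
                 ) -> pd.DataFrame:
    """Full regime x label-fraction x fold grid on one cohort.

    Contrastive MIL is trained once per fold (it never sees labels) and is
    shared by the fine-tune and frozen arms of every label fraction; folds
    are kept consistent across regimes.
    """
    by_id = {b.slide_id: b for b in bags}
    ids = [b.slide_id for b in bags]
    labels = [b.label for b in bags]
    if folds is None:
        folds = make_folds(ids, labels if task == "classification" else None,
                           seed=seed)
    if fold_subset is not None:
        folds = [f for f in folds if f.fold_id in set(fold_subset)]
    ssmil_schedule = ssmil_schedule or SSMILSchedule(epochs=80, seed=seed)
    head_schedule = head_schedule or HeadSchedule(seed=seed)
    needs_ssmil = any(r in ("fine_tune", "frozen") for r in regimes)

    rows = []
    predictions = []
    for fold in folds:
        train = [by_id[i] for i in fold.train_ids]
        val = [by_id[i] for i in fold.val_ids]
        test = [by_id[i] for i in fold.test_ids]
        test_labels = np.asarray([b.label for b in test])
        if task == "classification":
            test_labels = test_labels.astype(int)
        ssmil_model = None
        if needs_ssmil:
            ssmil_model, _ = train_ssmil(train, val, schedule=replace(
                ssmil_schedule, seed=ssmil_schedule.seed + 101 * fold.fold_id))
        for regime in regimes:
            for fraction in fractions:
                kept = set(subsample_labels(fold.train_ids,
                                            [by_id[i].label for i in fold.train_ids],
                                            fraction, seed=seed))
                train_f = [b for b in train if b.slide_id in kept]
                predictor, _ = train_head(
                    train_f, val, regime, task, ssmil_model=ssmil_model,
                    schedule=replace(head_schedule,
                                     seed=head_schedule.seed + 13 * fold.fold_id))
                scores = predictor.predict(test)
                row = {"regime": regime, "fraction": fraction,
                       "fold": fold.fold_id, "n_train": len(train_f)}
                row.update(_metric_row(scores, test_labels, task))
                rows.append(row)
                for b, s in zip(test, scores):
                    predictions.append({"slide_id": b.slide_id, "score": float(s),
                                        "label": b.label, "fold": fold.fold_id,
                                        "regime": regime, "fraction": fraction})
    result = pd.DataFrame(rows)
    result.attrs["predictions"] = predictions  # list of per-slide records
    return result


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd over folds for each regime x fraction cell."""
    metrics = [c for c in table.columns
               if c in ("sensitivity", "specificity", "auc", "r2")]
    agg = table.groupby(["regime", "fraction"])[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
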