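"""Evaluation protocol: fold construction, label subsampling, the three
training regimes, and metric definitions with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssmil.contrastive import SSMILSchedule, train_ssmil
from ssmil.evaluate import (HeadSchedule, auc, make_folds, r_squared,
                            sensitivity_specificity, subsample_labels,
                            train_head)
from ssmil.synthetic import SyntheticBagConfig, generate_bags


def auc_oracle(scores, labels):
    """Exhaustive pair counting with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFolds:
    @pytest.mark.parametrize("n", [5, 23, 100, 1000])
    def test_partition_and_proportions(self, n):
        ids = [f"s{i}" for i in range(n)]
        folds = make_folds(ids, seed=1)
        all_test = [t for f in folds for t in f.test_ids]
        assert sorted(all_test) == sorted(ids)  # exclusive and exhaustive
        for f in folds:
            assert not set(f.train_ids) & set(f.val_ids)
            assert not set(f.train_ids) & set(f.test_ids)
            assert not set(f.val_ids) & set(f.test_ids)
            assert len(f.train_ids) + len(f.val_ids) + len(f.test_ids) == n
            if n >= 100:
                assert abs(len(f.train_ids) / n - 0.6) < 0.02
                assert abs(len(f.val_ids) / n - 0.2) < 0.02
                assert abs(len(f.test_ids) / n - 0.2) < 0.02

    def test_five_slides_minimal_case(self):
        folds = make_folds([f"s{i}" for i in range(5)], seed=0)
        assert all(len(f.test_ids) == 1 for f in folds)

    def test_stratified_balance(self):
        ids = [f"s{i}" for i in range(100)]
        labels = [i % 2 for i in range(100)]
        folds = make_folds(ids, labels, seed=3)
        for f in folds:
            pos = sum(int(s[1:]) % 2 for s in f.test_ids)
            assert abs(pos - len(f.test_ids) / 2) <= 1

    def test_too_few_slides_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], seed=0)

    def test_folds_deterministic(self):
        ids = [f"s{i}" for i in range(50)]
        assert make_folds(ids, seed=9) == make_folds(ids, seed=9)


class TestLabelSubsampling:
    def test_sizes_and_stratification(self):
        ids = [f"s{i}" for i in range(80)]
        labels = [i % 2 for i in range(80)]
        sub = subsample_labels(ids, labels, 0.25, seed=1)
        assert len(sub) == 20
        assert sum(int(s[1:]) % 2 for s in sub) == 10

    def test_identity_at_full_fraction(self):
        ids = [f"s{i}" for i in range(10)]
        assert subsample_labels(ids, [0] * 5 + [1] * 5, 1.0, seed=0) == ids

    def test_nested_under_fixed_seed(self):
        ids = [f"s{i}" for i in range(40)]
        labels = [i % 2 for i in range(40)]
        subsets = [set(subsample_labels(ids, labels, f, seed=7))
                   for f in (0.25, 0.5, 0.75)]
        assert subsets[0] < subsets[1] < subsets[2]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            subsample_labels(["a"], [0], 0.0, seed=0)


class TestMetrics:
    def test_auc_trivial_cases(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_auc_hand_computed(self):
        # pairs: (.35>.1, .35<.4, .8>.1, .8>.4) -> 3 wins of 4
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 5000))
    def test_auc_matches_exhaustive_pair_counting(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, int)
        labels[: rng.integers(1, n)] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            return
        scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=n)  # with ties
        assert auc(scores, labels) == pytest.approx(auc_oracle(scores, labels))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, size=20)
        labels[0], labels[1] = 0, 1
        assert auc(np.exp(scores), labels) == pytest.approx(auc(scores, labels))
        assert auc(3 * scores - 7, labels) == pytest.approx(auc(scores, labels))

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])

    def test_sensitivity_specificity_cases(self):
        assert sensitivity_specificity([0.9, 0.1], [1, 0]) == (1.0, 1.0)
        assert sensitivity_specificity([0.9, 0.9], [1, 0]) == (1.0, 0.0)
        # counts TP=3, FN=1, TN=2, FP=2
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.3, 0.6, 0.7]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        assert sensitivity_specificity(scores, labels) == (0.75, 0.5)

    def test_r_squared_cases(self):
        t = [1.0, 2.0, 3.0]
        assert r_squared(t, t) == pytest.approx(1.0)
        assert r_squared([-x for x in t], t) == pytest.approx(1.0)
        # hand computation: r = cov / (sd_x sd_y) for x=(1,2,3), y=(2,4,7)
        assert r_squared([1, 2, 3], [2, 4, 7]) == pytest.approx(0.98684, abs=1e-4)

    def test_r_squared_determination_mode(self):
        pred = [1.1, 1.9, 3.2]
        targ = [1.0, 2.0, 3.0]
        ss_res = sum((p - t) ** 2 for p, t in zip(pred, targ))
        ss_tot = sum((t - 2.0) ** 2 for t in targ)
        assert r_squared(pred, targ, mode="determination") == pytest.approx(
            1 - ss_res / ss_tot)

    def test_r_squared_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


@pytest.fixture(scope="module")
def trained_setting():
    bags = generate_bags(SyntheticBagConfig(
        n_slides=30, instances_per_slide=40, embed_dim=16,
        n_shared_clusters=4, n_unique_clusters_per_class=2,
        unique_fraction=0.3, effect_size=4.0, seed=31))
    train, val = bags[:20], bags[20:26]
    model, _ = train_ssmil(train, val, schedule=SSMILSchedule(
        epochs=30, batch_size=20, seed=31, eval_every=5))
    return bags, train, val, model


class TestRegimes:
    def test_frozen_leaves_backbone_bit_identical(self, trained_setting):
        bags, train, val, model = trained_setting
        before = {k: v.copy() for k, v in model.state_dict().items()}
        probe, _ = train_head(train, val, "frozen", "classification",
                              ssmil_model=model,
                              schedule=HeadSchedule(epochs=20, seed=1))
        for k, v in model.state_dict().items():
            assert np.array_equal(v, before[k])
        scores = probe.predict(bags[26:])
        assert scores.shape == (4,)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_frozen_without_model_rejected(self, trained_setting):
        bags, train, val, _ = trained_setting
        with pytest.raises(ValueError):
            train_head(train, val, "frozen", "classification")

    def test_finetune_initialization_differs_from_supervised(self, trained_setting):
        _, train, val, model = trained_setting
        sched = HeadSchedule(epochs=0, full_model_epochs=0, seed=2)
        ft, _ = train_head(train, val, "fine_tune", "classification",
                           ssmil_model=model, schedule=sched)
        sup, _ = train_head(train, val, "supervised", "classification",
                            schedule=sched)
        ft_att = {k: v for k, v in ft.state_dict().items() if k.startswith("attention")}
        sup_att = {k: v for k, v in sup.state_dict().items() if k.startswith("attention")}
        total = sum(np.linalg.norm(ft_att[k] - sup_att[k]) for k in ft_att)
        assert total > 0

    def test_supervised_fits_separable_data(self, trained_setting):
        bags, train, val, _ = trained_setting
        sup, log = train_head(train, val, "supervised", "classification",
                              schedule=HeadSchedule(full_model_epochs=120,
                                                    full_model_patience=120,
                                                    seed=3))
        assert log["train_loss"][-1] < 0.1  # loss approaches zero
        assert min(log["train_loss"]) < log["train_loss"][0]

    def test_regression_heads_produce_real_scores(self, trained_setting):
        reg_bags = generate_bags(SyntheticBagConfig(
            n_slides=20, instances_per_slide=40, embed_dim=16,
            n_shared_clusters=4, n_unique_clusters_per_class=1,
            unique_fraction=0.6, effect_size=4.0, task="regression", seed=41))
        model, _ = train_ssmil(reg_bags[:12], reg_bags[12:16],
                               schedule=SSMILSchedule(epochs=10, batch_size=12,
                                                      seed=41, eval_every=5))
        probe, _ = train_head(reg_bags[:12], reg_bags[12:16], "frozen",
                              "regression", ssmil_model=model,
                              schedule=HeadSchedule(epochs=50, seed=4))
        scores = probe.predict(reg_bags[16:])
        assert scores.shape == (4,)
        assert np.isfinite(scores).all()

    def test_unknown_regime_rejected(self, trained_setting):
        _, train, val, model = trained_setting
        with pytest.raises(ValueError):
            train_head(train, val, "probing", "classification", ssmil_model=model)
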