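"""Contrastive MIL: bag-view construction, forward/pooling oracles, training
behavior, and the invariances of the learned slide representation."""

import numpy as np
import pytest

from ssmil.attention import Bag, pool
from ssmil.contrastive import (SSMILModel, SSMILSchedule, forward_view,
                               load_model, make_view_pairs, represent_bags,
                               save_model, slide_representation, subsample_bag,
                               train_ssmil, view_size)
from ssmil.synthetic import SyntheticBagConfig, generate_bags


@pytest.fixture(scope="module")
def bags():
    return generate_bags(SyntheticBagConfig(
        n_slides=24, instances_per_slide=40, embed_dim=16,
        n_shared_clusters=4, n_unique_clusters_per_class=2,
        unique_fraction=0.25, effect_size=4.0, seed=77))


@pytest.fixture
def model(bags):
    return SSMILModel(embedding_dim=16, attention_dim=8, mil_projection_dim=8,
                      rng=np.random.default_rng(5))


class TestBagViews:
    @pytest.mark.parametrize("K,fraction,expected", [
        (1000, 0.25, 250), (4, 0.25, 1), (1, 0.25, 1), (10, 1.0, 10),
        (250, 0.25, 62), (7, 0.5, 4),
    ])
    def test_view_size_rule(self, K, fraction, expected):
        assert view_size(K, fraction) == expected

    def test_subsample_with_replacement(self, bags):
        # with 10 draws from 4 instances duplicates are certain eventually
        small = Bag("s", np.arange(8).reshape(4, 2))
        seen_duplicate = any(
            len(set(subsample_bag(small, 1.0, seed=s).instance_indices)) < 4
            for s in range(10))
        assert seen_duplicate

    def test_subsample_deterministic(self, bags):
        v1 = subsample_bag(bags[0], 0.25, seed=3)
        v2 = subsample_bag(bags[0], 0.25, seed=3)
        v3 = subsample_bag(bags[0], 0.25, seed=4)
        assert np.array_equal(v1.instance_indices, v2.instance_indices)
        assert not np.array_equal(v1.instance_indices, v3.instance_indices)

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError):
            subsample_bag(Bag("s", np.zeros((0, 3))), 0.25, seed=0)

    def test_pairs_per_slide(self, bags):
        pairs = make_view_pairs(bags, epoch_seed=1)
        assert len(pairs) == len(bags)
        assert all(p[0].slide_id == p[1].slide_id == b.slide_id
                   for p, b in zip(pairs, bags))
        # 2 views per slide, each of size round(K/4)
        assert all(v.instance_indices.size == view_size(b.size)
                   for p, b in zip(pairs, bags) for v in p)

    def test_pairs_reproducible_within_and_differ_across_epochs(self, bags):
        p1 = make_view_pairs(bags, epoch_seed=5)
        p2 = make_view_pairs(bags, epoch_seed=5)
        p3 = make_view_pairs(bags, epoch_seed=6)
        assert all(np.array_equal(a[0].instance_indices, b[0].instance_indices)
                   for a, b in zip(p1, p2))
        assert any(not np.array_equal(a[0].instance_indices, b[0].instance_indices)
                   for a, b in zip(p1, p3))

    def test_fewer_than_two_slides_rejected(self, bags):
        with pytest.raises(ValueError):
            make_view_pairs(bags[:1], epoch_seed=0)


class TestForward:
    def test_full_bag_view_equals_pool_projection(self, bags, model):
        bag = bags[0]
        full = subsample_bag(bag, 1.0, seed=0)
        full.instance_indices = np.arange(bag.size)
        out = forward_view(model, bag, full)
        z, _ = model.attention.forward(bag.instances)
        expected = model.projection(z.reshape(1, -1)).data[0]
        assert out == pytest.approx(expected, abs=1e-12)

    def test_identical_instances_give_identical_view_projections(self, model):
        bag = Bag("s", np.tile(np.arange(16.0), (30, 1)))
        v1 = subsample_bag(bag, 0.25, seed=1)
        v2 = subsample_bag(bag, 0.25, seed=2)
        assert forward_view(model, bag, v1) == pytest.approx(
            forward_view(model, bag, v2), abs=1e-12)

    def test_duplicated_index_counts_twice(self, bags, model):
        bag = bags[1]
        view = subsample_bag(bag, 0.25, seed=9)
        view.instance_indices[1] = view.instance_indices[0]  # force duplicate
        out = forward_view(model, bag, view)
        # oracle: pool the explicitly expanded instance list
        expanded = Bag("x", bag.instances[view.instance_indices])
        enc = pool(expanded, model.attention.to_params())
        expected = model.projection(
            __import__("ssmil")._autodiff.Tensor(enc.z.reshape(1, -1))).data[0]
        assert out == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_index_rejected(self, bags, model):
        view = subsample_bag(bags[0], 0.25, seed=0)
        view.instance_indices[0] = bags[0].size
        with pytest.raises(IndexError):
            forward_view(model, bags[0], view)


class TestTraining:
    def test_zero_epochs_returns_model_unchanged(self, bags, model):
        before = {k: v.copy() for k, v in model.state_dict().items()}
        out, log = train_ssmil(bags[:12], bags[12:16], model=model,
                               schedule=SSMILSchedule(epochs=0))
        assert out is model
        for k, v in out.state_dict().items():
            assert np.array_equal(v, before[k])
        assert log["train_loss"] == []

    def test_loss_decreases_and_views_of_same_slide_align(self, bags):
        train, val, held = bags[:14], bags[14:18], bags[18:]
        model, log = train_ssmil(train, val, schedule=SSMILSchedule(
            epochs=40, batch_size=14, seed=3, eval_every=5))
        assert log["train_loss"][-1] < log["train_loss"][0]
        # on held-out slides, same-slide views are closer than cross-slide
        rng_seeds = (101, 202)
        zs = []
        for b in held:
            pair = [forward_view(model, b, subsample_bag(b, 0.25, seed=s))
                    for s in rng_seeds]
            zs.append(pair)
        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        same = np.mean([cos(p[0], p[1]) for p in zs])
        cross = np.mean([cos(zs[i][0], zs[j][1])
                         for i in range(len(zs)) for j in range(len(zs)) if i != j])
        assert same > cross

    def test_train_val_overlap_rejected(self, bags):
        with pytest.raises(ValueError):
            train_ssmil(bags[:4], bags[3:6], schedule=SSMILSchedule(epochs=1))


class TestRepresentation:
    def test_singleton_bag_representation_is_instance(self, model):
        bag = Bag("s", np.arange(16.0).reshape(1, 16))
        rep = slide_representation(model, bag)
        assert rep == pytest.approx(bag.instances[0], abs=1e-12)

    def test_deterministic_and_matches_functional_oracle(self, bags, model):
        rep1 = slide_representation(model, bags[2])
        rep2 = slide_representation(model, bags[2])
        assert np.array_equal(rep1, rep2)
        enc = pool(bags[2], model.attention.to_params())
        assert rep1 == pytest.approx(enc.z, abs=1e-9)

    def test_permutation_invariance(self, bags, model):
        bag = bags[3]
        rng = np.random.default_rng(0)
        shuffled = Bag(bag.slide_id, bag.instances[rng.permutation(bag.size)])
        assert slide_representation(model, shuffled) == pytest.approx(
            slide_representation(model, bag), abs=1e-6)

    def test_represent_bags_shape(self, bags, model):
        reps = represent_bags(model, bags[:5])
        assert reps.shape == (5, 16)


def test_model_round_trip(tmp_path, bags, model):
    save_model(tmp_path / "m.json", model)
    back = load_model(tmp_path / "m.json")
    for k, v in back.state_dict().items():
        assert np.array_equal(v, model.state_dict()[k])
    assert np.array_equal(represent_bags(back, bags[:3]),
                          represent_bags(model, bags[:3]))
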