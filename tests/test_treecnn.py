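"""Tree-CNN: adaptive classifier, affinity routing, growth and isolation."""
import numpy as np
import pytest

from lesionforge.exceptions import StateError, ValidationError
from lesionforge.treecnn import (AdaptiveCNN, AdaptiveCNNConfig, GrowthPolicy,
                                 TreeCNN, TreeNode, build_adaptive_cnn, classify,
                                 copy_and_branch, grow_tree, leaf_classes,
                                 load_tree, save_tree, softmax_affinity,
                                 validate_tree)

from conftest import class_images

POLICY = GrowthPolicy(seed=0, epochs=15, input_size=32)


@pytest.fixture(scope="module")
def two_class_data():
    return {0: class_images(30, 0.08, 0, seed=1),
            1: class_images(30, 0.45, 1, seed=2)}


@pytest.fixture(scope="module")
def grown_tree(two_class_data):
    tree = TreeCNN(POLICY)
    tree.fit({c: imgs[:25] for c, imgs in two_class_data.items()})
    return tree


class TestAdaptiveCNN:
    def test_softmax_rows_sum_to_one(self, two_class_data):
        model = build_adaptive_cnn(AdaptiveCNNConfig(n_outputs=3, input_size=32, seed=0))
        probs = model.predict_proba(two_class_data[0][:5])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_untrained_outputs_deterministic_in_seed(self, two_class_data):
        cfg = AdaptiveCNNConfig(n_outputs=2, input_size=32, seed=9)
        a = build_adaptive_cnn(cfg).predict_proba(two_class_data[0][:3])
        b = build_adaptive_cnn(cfg).predict_proba(two_class_data[0][:3])
        assert np.array_equal(a, b)

    def test_separable_classes_learned(self, two_class_data):
        model = build_adaptive_cnn(AdaptiveCNNConfig(n_outputs=2, input_size=32, seed=0))
        images = two_class_data[0][:25] + two_class_data[1][:25]
        labels = [0] * 25 + [1] * 25
        model.fit(images, labels, epochs=15, seed=0)
        assert model.accuracy(images, labels) >= 0.90

    def test_incompatible_input_size_rejected(self):
        with pytest.raises(ValidationError, match="divisible"):
            AdaptiveCNNConfig(n_outputs=2, input_size=30).validate()


class TestSoftmaxAffinity:
    def test_rows_sum_to_one(self, grown_tree, two_class_data):
        new = {5: class_images(20, 0.2, 5, seed=9)}
        aff = softmax_affinity(grown_tree.root, new, POLICY)
        assert aff.shape == (1, 2)
        assert np.allclose(aff.sum(axis=1), 1.0, atol=1e-5)

    def test_twin_class_attracted_to_its_visual_sibling(self, grown_tree):
        twin = {7: class_images(20, 0.08, 7, seed=3)}   # same regime as class 0
        aff = softmax_affinity(grown_tree.root, twin, POLICY)
        child_of_0 = grown_tree.root.labels_transform[0]
        assert int(np.argmax(aff[0])) == child_of_0

    def test_empty_sample_rejected(self, grown_tree):
        with pytest.raises(ValidationError, match="empty"):
            softmax_affinity(grown_tree.root, {9: []}, POLICY)

    def test_untrained_node_rejected(self, two_class_data):
        node = TreeNode(node_id="x", children=[TreeNode("a", leaf_class=0),
                                               TreeNode("b", leaf_class=1)])
        with pytest.raises(StateError):
            softmax_affinity(node, {2: two_class_data[0][:2]}, POLICY)


class TestGrowTree:
    def test_fresh_root_with_two_classes(self, two_class_data):
        tree = TreeCNN(POLICY).fit({c: v[:20] for c, v in two_class_data.items()})
        root = tree.root
        assert len(root.children) == 2
        assert all(child.is_leaf for child in root.children)
        assert root.labels_transform == {0: 0, 1: 1}
        validate_tree(root)

    def test_grow_conserves_class_multiset(self, two_class_data):
        tree = TreeCNN(POLICY).fit({c: v[:20] for c, v in two_class_data.items()})
        tree.grow({3: class_images(20, 0.22, 3, seed=6)})
        assert sorted(leaf_classes(tree.root)) == [0, 1, 3]
        validate_tree(tree.root)

    def test_duplicate_class_rejected(self, grown_tree, two_class_data):
        with pytest.raises(ValidationError, match="already present"):
            grow_tree(grown_tree.root, {0: two_class_data[0][:5]}, POLICY)

    def test_forced_affinity_routes_into_child(self, two_class_data, monkeypatch):
        tree = TreeCNN(POLICY).fit({c: v[:20] for c, v in two_class_data.items()})
        monkeypatch.setattr("lesionforge.treecnn.softmax_affinity",
                            lambda node, samples, policy: np.array([[0.95, 0.05]]))
        grow_tree(tree.root, {2: class_images(20, 0.08, 2, seed=4)}, POLICY)
        child0 = tree.root.children[0]
        assert not child0.is_leaf
        assert sorted(leaf_classes(child0)) == [0, 2]
        validate_tree(tree.root)

    def test_forced_low_affinity_creates_new_child(self, two_class_data, monkeypatch):
        tree = TreeCNN(POLICY).fit({c: v[:20] for c, v in two_class_data.items()})
        monkeypatch.setattr("lesionforge.treecnn.softmax_affinity",
                            lambda node, samples, policy: np.array([[0.5, 0.5]]))
        # threshold 2/(2+1) = 0.667 > 0.5 -> new leaf child
        grow_tree(tree.root, {2: class_images(20, 0.22, 2, seed=4)}, POLICY)
        assert len(tree.root.children) == 3
        assert sorted(leaf_classes(tree.root)) == [0, 1, 2]
        validate_tree(tree.root)

    def test_forced_double_affinity_merges_lower_into_higher(self, two_class_data,
                                                             monkeypatch):
        tree = TreeCNN(POLICY).fit({c: v[:20] for c, v in two_class_data.items()})
        monkeypatch.setattr("lesionforge.treecnn.softmax_affinity",
                            lambda node, samples, policy: np.array([[0.7, 0.9]]))
        grow_tree(tree.root, {2: class_images(20, 0.3, 2, seed=4)}, POLICY)
        # child 0 (lower affinity) merged into child 1; new class joins the merge
        assert len(tree.root.children) == 1
        assert sorted(leaf_classes(tree.root)) == [0, 1, 2]
        validate_tree(tree.root)


class TestIncrementalIsolation:
    def test_scripted_two_grow_sequence(self):
        a = class_images(30, 0.08, 0, seed=1)
        b = class_images(30, 0.45, 1, seed=2)
        twin0 = class_images(30, 0.08, 2, seed=3)
        twin1 = class_images(30, 0.45, 3, seed=4)
        tree = TreeCNN(POLICY)
        tree.fit({0: a, 1: b})
        tree.grow({2: twin0})
        root = tree.root
        validate_tree(root)
        branches = [c for c in root.children if not c.is_leaf]
        assert len(branches) == 1 and sorted(leaf_classes(branches[0])) == [0, 2]
        snapshot = {k: v.copy() for k, v in
                    branches[0].classifier.network.state_dict().items()}
        tree.grow({3: twin1})
        validate_tree(root)
        assert sorted(leaf_classes(root)) == [0, 1, 2, 3]
        # class 3 went under the class-1 child; the [0,2] branch is untouched
        assert 3 not in leaf_classes(branches[0])
        now = branches[0].classifier.network.state_dict()
        assert all(np.array_equal(snapshot[k], now[k]) for k in snapshot)

    def test_lookup_tables_compose_invertibly(self, grown_tree):
        root = grown_tree.root
        for cls in leaf_classes(root):
            node = root
            while not node.is_leaf:
                node = node.children[node.labels_transform[cls]]
            assert node.leaf_class == cls


class TestCopyAndBranch:
    def test_extends_outputs_and_preserves_old_logits(self, grown_tree, two_class_data):
        node = grown_tree.root
        ext = copy_and_branch(node, 1, seed=5)
        assert ext.classifier.n_outputs == node.classifier.n_outputs + 1
        probe = two_class_data[0][:4]
        old = node.classifier.logits(probe)
        new = ext.classifier.logits(probe)
        assert np.allclose(old, new[:, :old.shape[1]], atol=1e-6)

    def test_source_untouched_after_copy_is_retrained(self, grown_tree, two_class_data):
        node = grown_tree.root
        before = {k: v.copy() for k, v in node.classifier.network.state_dict().items()}
        ext = copy_and_branch(node, 1, seed=5)
        images = two_class_data[0][:10] + two_class_data[1][:10]
        ext.classifier.fit(images, [0] * 10 + [1] * 10, epochs=3, seed=0)
        after = node.classifier.network.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_warm_start_converges_faster_than_scratch(self, two_class_data):
        """Copied shared weights reach the accuracy bar in fewer epochs than a
        fresh network (majority over 5 seeds)."""
        new_cls = class_images(30, 0.22, 2, seed=8)
        wins = 0
        for seed in range(5):
            base = build_adaptive_cnn(AdaptiveCNNConfig(n_outputs=2, input_size=32,
                                                        seed=seed))
            base.fit(two_class_data[0][:20] + two_class_data[1][:20],
                     [0] * 20 + [1] * 20, epochs=10, seed=seed)
            warm = base.extend_outputs(1, seed=seed)
            cold = build_adaptive_cnn(AdaptiveCNNConfig(n_outputs=3, input_size=32,
                                                        seed=seed + 100))
            images = (two_class_data[0][:20] + two_class_data[1][:20] + new_cls[:20])
            labels = [0] * 20 + [1] * 20 + [2] * 20

            def epochs_to(model, bar=0.9, cap=12):
                for ep in range(1, cap + 1):
                    model.fit(images, labels, epochs=1, seed=seed + ep)
                    if model.accuracy(images, labels) >= bar:
                        return ep
                return cap + 1

            wins += epochs_to(warm) <= epochs_to(cold)
        assert wins >= 3

    def test_zero_new_outputs_rejected(self, grown_tree):
        with pytest.raises(ValidationError):
            copy_and_branch(grown_tree.root, 0)


class TestClassify:
    def test_single_leaf_tree_always_returns_its_class(self, two_class_data):
        leaf = TreeNode(node_id="only", leaf_class=4)
        assert classify(leaf, two_class_data[0][0]) == 4

    def test_holdout_accuracy_on_separable_classes(self, grown_tree, two_class_data):
        test = two_class_data[0][25:] + two_class_data[1][25:]
        labels = [0] * 5 + [1] * 5
        assert grown_tree.score(test, labels) >= 0.85

    def test_root_misrouting_is_final(self, two_class_data):
        """A root-level misroute can never be recovered deeper in the tree."""
        tree = TreeCNN(POLICY)
        tree.fit({0: class_images(25, 0.08, 0, seed=1)[:20],
                  1: class_images(25, 0.45, 1, seed=2)[:20]})
        tree.grow({2: class_images(25, 0.08, 2, seed=3)[:20]})
        root = tree.root
        for img in class_images(10, 0.08, 0, seed=12):
            label, path = classify(root, img, return_path=True)
            first_child = root.children[
                int(np.argmax(root.classifier.predict_proba([img])[0]))]
            if label == 0:   # a correct final label implies a correct first hop
                assert 0 in leaf_classes(first_child)

    def test_untrained_path_raises_state_error(self, two_class_data):
        node = TreeNode(node_id="r", children=[TreeNode("a", leaf_class=0),
                                               TreeNode("b", leaf_class=1)])
        with pytest.raises(StateError):
            classify(node, two_class_data[0][0])


def test_tree_serialisation_round_trip(tmp_path, grown_tree, two_class_data):
    save_tree(grown_tree.root, tmp_path)
    back = load_tree(tmp_path)
    validate_tree(back)
    probe = two_class_data[0][:5] + two_class_data[1][:5]
    assert [classify(back, img) for img in probe] == \
           [classify(grown_tree.root, img) for img in probe]
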