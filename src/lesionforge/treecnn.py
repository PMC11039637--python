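"""Adaptive CNN classifier and the Tree-CNN incremental learning algorithm.

The classifier tree has a CNN at the root and at every branch node, each
trained to route an input image to one of its children; leaves carry exactly
one global class each.  New classes are placed by *softmax affinity*: a
small sample (~10%) of the new class's images is pushed through a node's
classifier and the mean softmax per existing child decides whether the class
joins a child (growing that subtree), forces two similar children to merge,
or becomes a new child.  Every node keeps a ``labels_transform`` lookup
table mapping global class labels to its local output indices; composing the
tables along a root-to-leaf path is invertible, so the reached leaf recovers
the global label.

Weight sharing across increments uses *copy-and-branch*: a retrained node
starts from a copy of its previous weights with freshly initialised output
units appended, so earlier tasks are preserved and convergence is faster
than training from scratch.  Nodes that are not on the path of any new class
are never touched.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .exceptions import StateError, ValidationError
from .image import LabeledImage
from .nn import (Adam, BatchNorm2D, Conv2D, Dense, Dropout, Flatten,
                 MaxPool2D, Network, ReLU, softmax, softmax_cross_entropy)

__all__ = [
    "AdaptiveCNNConfig", "AdaptiveCNN", "GrowthPolicy", "TreeNode",
    "build_adaptive_cnn", "softmax_affinity", "grow_tree", "copy_and_branch",
    "classify", "leaf_classes", "validate_tree", "TreeCNN",
    "save_tree", "load_tree",
]


@dataclass(frozen=True)
class AdaptiveCNNConfig:
    """Architecture of one node's CNN: conv(+BN)+ReLU+pool blocks, flatten,
    dropout, dense, softmax head."""

    n_outputs: int
    input_size: int = 32
    input_channels: int = 3
    conv_blocks: tuple[tuple[int, int], ...] = ((8, 3), (16, 3))
    use_batchnorm: bool = True
    drop_rates: tuple[float, ...] = (0.3,)
    dense_units: int = 32
    seed: int = 0

    def validate(self) -> None:
        if self.n_outputs < 2:
            raise ValidationError(f"n_outputs must be >= 2, got {self.n_outputs}")
        if not self.conv_blocks:
            raise ValidationError("at least one conv block is required")
        depth = 2 ** len(self.conv_blocks)
        if self.input_size % depth:
            raise ValidationError(
                f"input_size {self.input_size} not divisible by pooling depth {depth}"
            )


class AdaptiveCNN:
    """A softmax classifier over ``n_outputs`` local indices."""

    def __init__(self, cfg: AdaptiveCNNConfig) -> None:
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        layers: list = []
        ch, size = cfg.input_channels, cfg.input_size
        for count, ksize in cfg.conv_blocks:
            layers.append(Conv2D(ch, count, ksize, rng))
            if cfg.use_batchnorm:
                layers.append(BatchNorm2D(count))
            layers.append(ReLU())
            layers.append(MaxPool2D(2))
            ch, size = count, size // 2
        layers.append(Flatten())
        for rate in cfg.drop_rates:
            layers.append(Dropout(rate))
        layers.append(Dense(ch * size * size, cfg.dense_units, rng))
        layers.append(ReLU())
        layers.append(Dense(cfg.dense_units, cfg.n_outputs, rng))
        self.network = Network(layers)
        self.trained = False

    @property
    def n_outputs(self) -> int:
        return self.cfg.n_outputs

    def _to_batch(self, images: Sequence[LabeledImage]) -> np.ndarray:
        arrs = []
        for img in images:
            if img.height != self.cfg.input_size or img.width != self.cfg.input_size:
                raise ValidationError(
                    f"image {img.height}x{img.width} does not match classifier input "
                    f"{self.cfg.input_size}"
                )
            px = img.pixels.astype(np.float32) / 255.0
            if px.ndim == 2:
                px = px[:, :, None]
            arrs.append(px.transpose(2, 0, 1))
        return np.stack(arrs)

    def logits(self, images: Sequence[LabeledImage]) -> np.ndarray:
        return self.network.forward(self._to_batch(images), training=False)

    def predict_proba(self, images: Sequence[LabeledImage]) -> np.ndarray:
        """Softmax probabilities, rows summing to one."""
        return softmax(self.logits(images))

    def fit(self, images: Sequence[LabeledImage], labels: Sequence[int],
            epochs: int = 20, learning_rate: float = 1e-3, batch_size: int = 16,
            seed: int = 0) -> List[float]:
        labels = np.asarray(labels, dtype=int)
        if labels.min() < 0 or labels.max() >= self.n_outputs:
            raise ValidationError("labels must be local indices in [0, n_outputs)")
        x = self._to_batch(images)
        ss = np.random.SeedSequence(seed)
        rng_shuffle, rng_drop = (np.random.default_rng(s) for s in ss.spawn(2))
        self.network.set_rng(rng_drop)
        opt = Adam(self.network, learning_rate=learning_rate)
        history = []
        n = x.shape[0]
        for _ in range(epochs):
            perm = rng_shuffle.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = perm[start:start + batch_size]
                logits = self.network.forward(x[idx], training=True)
                loss, dlogits = softmax_cross_entropy(logits, labels[idx])
                self.network.backward(dlogits)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.trained = True
        return history

    def accuracy(self, images: Sequence[LabeledImage], labels: Sequence[int]) -> float:
        pred = self.predict_proba(images).argmax(axis=1)
        return float(np.mean(pred == np.asarray(labels)))

    def extend_outputs(self, n_new: int, seed: int = 0) -> "AdaptiveCNN":
        """Copy-and-branch at model level: shared layers copied verbatim, the
        final dense layer gains ``n_new`` freshly initialised output units."""
        if n_new < 1:
            raise ValidationError(f"n_new_outputs must be >= 1, got {n_new}")
        new_cfg = AdaptiveCNNConfig(**{**vars(self.cfg),
                                       "n_outputs": self.cfg.n_outputs + n_new})
        clone = AdaptiveCNN(new_cfg)
        state = self.network.state_dict()
        head_idx = len(self.network.layers) - 1
        rng = np.random.default_rng(seed)
        old_head = self.network.layers[head_idx]
        W_old, b_old = old_head.params["W"], old_head.params["b"]
        scale = np.sqrt(2.0 / W_old.shape[0])
        W_new = np.concatenate(
            [W_old, (rng.standard_normal((W_old.shape[0], n_new)) * scale
                     ).astype(np.float32)], axis=1)
        b_new = np.concatenate([b_old, np.zeros(n_new, dtype=np.float32)])
        state[f"{head_idx}.W"] = W_new
        state[f"{head_idx}.b"] = b_new
        clone.network.load_state_dict(state)
        clone.trained = self.trained
        return clone

    def clone(self) -> "AdaptiveCNN":
        other = AdaptiveCNN(self.cfg)
        other.network.load_state_dict(self.network.state_dict())
        other.trained = self.trained
        return other


def build_adaptive_cnn(cfg: AdaptiveCNNConfig) -> AdaptiveCNN:
    return AdaptiveCNN(cfg)


@dataclass(frozen=True)
class GrowthPolicy:
    """How the tree grows: sampling, routing threshold, merging, training."""

    max_children_per_node: int = 10
    sample_fraction: float = 0.10
    merge_enabled: bool = True
    seed: int = 0
    affinity_threshold: Optional[float] = None   # None -> 2 / (n_outputs + 1)
    max_depth: int = 2
    # per-node training knobs
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 16
    input_size: int = 32
    input_channels: int = 3
    conv_blocks: tuple[tuple[int, int], ...] = ((8, 3), (16, 3))
    use_batchnorm: bool = True
    drop_rates: tuple[float, ...] = (0.3,)
    dense_units: int = 32
    # optional high-loss sample pruning (off by default)
    loss_filter_threshold: Optional[float] = None

    def validate(self) -> None:
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValidationError("sample_fraction must be in (0,1]")
        if self.max_children_per_node < 2:
            raise ValidationError("max_children_per_node must be >= 2")
        if self.max_depth < 2:
            raise ValidationError("max_depth must be >= 2")


@dataclass
class TreeNode:
    node_id: str
    classifier: Optional[AdaptiveCNN] = None
    children: List["TreeNode"] = field(default_factory=list)
    labels_transform: Dict[int, int] = field(default_factory=dict)
    leaf_class: Optional[int] = None
    # root-only bookkeeping
    training_data: Dict[int, List[LabeledImage]] = field(default_factory=dict)
    grow_count: int = 0
    _id_counter: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def next_id(self) -> str:
        self._id_counter += 1
        return f"{self.node_id}.n{self._id_counter}"


def leaf_classes(node: TreeNode) -> List[int]:
    if node.is_leaf:
        return [] if node.leaf_class is None else [node.leaf_class]
    out: List[int] = []
    for child in node.children:
        out.extend(leaf_classes(child))
    return out


def validate_tree(root: TreeNode) -> None:
    """Leaf-class bijection plus lookup-table totality/invertibility."""
    classes = leaf_classes(root)
    if len(classes) != len(set(classes)):
        raise ValidationError(f"duplicate leaf classes: {sorted(classes)}")

    def _check(node: TreeNode) -> None:
        if node.is_leaf:
            if node.leaf_class is None:
                raise ValidationError(f"leaf {node.node_id} has no class")
            if node.classifier is not None:
                raise ValidationError(f"leaf {node.node_id} must not hold a classifier")
            return
        reachable = set(leaf_classes(node))
        if set(node.labels_transform) != reachable:
            raise ValidationError(
                f"node {node.node_id}: labels_transform keys {sorted(node.labels_transform)} "
                f"!= reachable classes {sorted(reachable)}"
            )
        used = set(node.labels_transform.values())
        if used != set(range(len(node.children))):
            raise ValidationError(
                f"node {node.node_id}: lookup maps onto {sorted(used)}, expected "
                f"0..{len(node.children) - 1}"
            )
        for idx, child in enumerate(node.children):
            child_set = {c for c, i in node.labels_transform.items() if i == idx}
            if child_set != set(leaf_classes(child)):
                raise ValidationError(
                    f"node {node.node_id}: child {idx} lookup entries inconsistent"
                )
            _check(child)

    _check(root)


def _rebuild_lookup(node: TreeNode) -> None:
    node.labels_transform = {
        cls: idx
        for idx, child in enumerate(node.children)
        for cls in leaf_classes(child)
    }
    for child in node.children:
        if not child.is_leaf:
            _rebuild_lookup(child)


def softmax_affinity(node: TreeNode, samples_by_class: Dict[int, Sequence[LabeledImage]],
                     policy: GrowthPolicy) -> np.ndarray:
    """Mean softmax per (new class x existing child); rows sum to one.

    Row order follows ``sorted(samples_by_class)``; column order follows
    ``node.children``.
    """
    if node.classifier is None or not node.classifier.trained:
        raise StateError(f"node {node.node_id} has no trained classifier")
    rng = np.random.default_rng(policy.seed)
    rows = []
    for cls in sorted(samples_by_class):
        images = list(samples_by_class[cls])
        if not images:
            raise ValidationError(f"empty sample for class {cls}")
        n_take = max(1, int(round(policy.sample_fraction * len(images))))
        idx = rng.choice(len(images), size=min(n_take, len(images)), replace=False)
        sample = [images[i] for i in idx]
        rows.append(node.classifier.predict_proba(sample).mean(axis=0))
    return np.vstack(rows)


def copy_and_branch(node: TreeNode, n_new_outputs: int, seed: int = 0) -> TreeNode:
    """New node whose classifier copies the source's shared weights and
    appends ``n_new_outputs`` freshly initialised output units; the source is
    left untouched."""
    if node.classifier is None or not node.classifier.trained:
        raise StateError(f"node {node.node_id} has no trained classifier to copy")
    return TreeNode(
        node_id=node.node_id,
        classifier=node.classifier.extend_outputs(n_new_outputs, seed=seed),
        children=list(node.children),
        labels_transform=dict(node.labels_transform),
        leaf_class=node.leaf_class,
    )


def _node_seed(policy: GrowthPolicy, root: TreeNode, node_id: str) -> int:
    digest = zlib.crc32(node_id.encode())  # process-independent, unlike hash()
    return int(np.random.SeedSequence(
        [policy.seed, root.grow_count, digest]
    ).generate_state(1)[0] % (2 ** 31))


def _train_node(node: TreeNode, root: TreeNode, policy: GrowthPolicy) -> None:
    """(Re)train a routing node on all images reachable beneath it."""
    images: List[LabeledImage] = []
    labels: List[int] = []
    for cls, idx in node.labels_transform.items():
        for img in root.training_data[cls]:
            images.append(img)
            labels.append(idx)
    n_out = len(node.children)
    if n_out < 2:
        node.classifier = None   # a single child needs no routing decision
        return
    seed = _node_seed(policy, root, node.node_id)
    prev = node.classifier
    if prev is not None and prev.trained and n_out > prev.n_outputs:
        node.classifier = prev.extend_outputs(n_out - prev.n_outputs, seed=seed)
    elif prev is None or prev.n_outputs != n_out:
        node.classifier = AdaptiveCNN(AdaptiveCNNConfig(
            n_outputs=n_out, input_size=policy.input_size,
            input_channels=policy.input_channels, conv_blocks=policy.conv_blocks,
            use_batchnorm=policy.use_batchnorm, drop_rates=policy.drop_rates,
            dense_units=policy.dense_units, seed=seed))
    if policy.loss_filter_threshold is not None and node.classifier.trained:
        # optional pruning: drop samples whose current loss exceeds the threshold
        probs = node.classifier.predict_proba(images)
        per_sample = -np.log(probs[np.arange(len(labels)), labels] + 1e-12)
        keep = per_sample <= policy.loss_filter_threshold
        if keep.any():
            images = [im for im, k in zip(images, keep) if k]
            labels = [la for la, k in zip(labels, keep) if k]
    node.classifier.fit(images, labels, epochs=policy.epochs,
                        learning_rate=policy.learning_rate,
                        batch_size=policy.batch_size, seed=seed)


def _leaf(root: TreeNode, cls: int) -> TreeNode:
    return TreeNode(node_id=root.next_id(), leaf_class=cls)


def _route_into_child(root: TreeNode, child: TreeNode, cls: int,
                      retrain: set) -> None:
    """Place a new class under an existing child, converting a leaf child
    into a branch node when necessary."""
    if child.is_leaf:
        old_cls = child.leaf_class
        child.leaf_class = None
        child.children = [_leaf(root, old_cls), _leaf(root, cls)]
    else:
        child.children.append(_leaf(root, cls))
    retrain.add(id(child))


def _merge_children(root: TreeNode, lower: TreeNode, higher: TreeNode,
                    retrain: set) -> TreeNode:
    """Merge the lower-affinity child into the higher one; the merged node
    holds both children's leaf classes."""
    lower_leaves = ([_leaf(root, lower.leaf_class)] if lower.is_leaf
                    else list(lower.children))
    if higher.is_leaf:
        old_cls = higher.leaf_class
        higher.leaf_class = None
        higher.children = [_leaf(root, old_cls)]
        higher.classifier = None
    higher.children.extend(lower_leaves)
    root.children.remove(lower)
    retrain.add(id(higher))
    return higher


def grow_tree(tree: TreeNode, new_classes: Dict[int, Sequence[LabeledImage]],
              policy: GrowthPolicy = GrowthPolicy()) -> TreeNode:
    """Incrementally add ``new_classes`` to the tree (see module docstring).

    Only the root and the branch nodes that receive a new class are
    retrained; every other node's weights are left bit-identical.
    """
    policy.validate()
    if not new_classes:
        raise ValidationError("new_classes must be non-empty")
    existing = set(leaf_classes(tree))
    dupes = existing & set(new_classes)
    if dupes:
        raise ValidationError(f"classes already present in the tree: {sorted(dupes)}")
    for cls, images in new_classes.items():
        if not images:
            raise ValidationError(f"class {cls} has no images")

    tree.grow_count += 1
    rng = np.random.default_rng(
        np.random.SeedSequence([policy.seed, tree.grow_count]).generate_state(1)[0])
    retrain: set = set()

    if not tree.children:
        for cls in sorted(new_classes):
            tree.children.append(_leaf(tree, cls))
    else:
        affinity = softmax_affinity(tree, new_classes, policy)
        for row, cls in zip(affinity, sorted(new_classes)):
            n_out = len(tree.children)
            tau = (policy.affinity_threshold if policy.affinity_threshold is not None
                   else 2.0 / (n_out + 1))
            candidates = [i for i in np.argsort(-row) if row[i] >= tau]
            if policy.merge_enabled and len(candidates) >= 2:
                i, j = candidates[0], candidates[1]
                if row[i] == row[j] and rng.random() < 0.5:
                    i, j = j, i
                target = _merge_children(tree, lower=tree.children[j],
                                         higher=tree.children[i], retrain=retrain)
                _route_into_child(tree, target, cls, retrain)
            elif candidates:
                _route_into_child(tree, tree.children[candidates[0]], cls, retrain)
            elif len(tree.children) < policy.max_children_per_node:
                tree.children.append(_leaf(tree, cls))
            else:
                _route_into_child(tree, tree.children[int(np.argmax(row))], cls, retrain)

    for cls, images in new_classes.items():
        tree.training_data[cls] = list(images)
    _rebuild_lookup(tree)

    def _retrain_marked(node: TreeNode) -> None:
        for child in node.children:
            if not child.is_leaf:
                if id(child) in retrain:
                    _train_node(child, tree, policy)
                _retrain_marked(child)

    _retrain_marked(tree)
    _train_node(tree, tree, policy)   # the root learns every class's routing
    validate_tree(tree)
    return tree


def classify(tree: TreeNode, image: LabeledImage,
             return_path: bool = False) -> int | tuple[int, List[str]]:
    """Root-to-leaf descent by argmax softmax; returns the reached leaf's
    global class (optionally with the visited node ids)."""
    node = tree
    path = [node.node_id]
    while not node.is_leaf:
        if len(node.children) == 1:
            node = node.children[0]
            path.append(node.node_id)
            continue
        if node.classifier is None or not node.classifier.trained:
            raise StateError(f"node {node.node_id} on the path is untrained")
        probs = node.classifier.predict_proba([image])[0]
        node = node.children[int(np.argmax(probs))]
        path.append(node.node_id)
    if node.leaf_class is None:
        raise StateError(f"leaf {node.node_id} has no class")
    return (node.leaf_class, path) if return_path else node.leaf_class


class TreeCNN:
    """Model-style facade over the tree: ``fit`` performs the first grow,
    ``grow`` adds classes incrementally, ``predict`` classifies."""

    def __init__(self, policy: GrowthPolicy = GrowthPolicy()) -> None:
        self.policy = policy
        self.root = TreeNode(node_id="root")

    def fit(self, images_by_class: Dict[int, Sequence[LabeledImage]]) -> "TreeCNN":
        grow_tree(self.root, images_by_class, self.policy)
        return self

    grow = fit

    def predict(self, image: LabeledImage) -> int:
        return classify(self.root, image)

    def score(self, images: Sequence[LabeledImage], labels: Sequence[int]) -> float:
        preds = [self.predict(img) for img in images]
        return float(np.mean(np.asarray(preds) == np.asarray(labels)))

    def summary(self) -> str:
        lines = ["Tree-CNN", "========",
                 f"classes: {sorted(leaf_classes(self.root))}",
                 f"root children: {len(self.root.children)}",
                 f"grow operations: {self.root.grow_count}"]
        return "\n".join(lines)


# -- serialisation ----------------------------------------------------------

def _topology(node: TreeNode) -> dict:
    return {
        "node_id": node.node_id,
        "leaf_class": node.leaf_class,
        "labels_transform": {str(k): v for k, v in node.labels_transform.items()},
        "has_classifier": node.classifier is not None,
        "cfg": None if node.classifier is None else vars(node.classifier.cfg),
        "children": [_topology(c) for c in node.children],
    }


def save_tree(root: TreeNode, out_dir: str | Path) -> None:
    """Directory layout: topology.json + one weight file per routing node."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "topology.json").write_text(json.dumps(_topology(root), indent=2))

    def _dump(node: TreeNode) -> None:
        if node.classifier is not None:
            safe = node.node_id.replace(".", "_")
            np.savez(out / f"{safe}.npz", **node.classifier.network.state_dict())
        for child in node.children:
            _dump(child)

    _dump(root)


def load_tree(in_dir: str | Path) -> TreeNode:
    src = Path(in_dir)
    topo = json.loads((src / "topology.json").read_text())

    def _build(raw: dict) -> TreeNode:
        node = TreeNode(
            node_id=raw["node_id"],
            leaf_class=raw["leaf_class"],
            labels_transform={int(k): v for k, v in raw["labels_transform"].items()},
            children=[_build(c) for c in raw["children"]],
        )
        if raw["has_classifier"]:
            cfg_raw = dict(raw["cfg"])
            cfg_raw["conv_blocks"] = tuple(tuple(b) for b in cfg_raw["conv_blocks"])
            cfg_raw["drop_rates"] = tuple(cfg_raw["drop_rates"])
            node.classifier = AdaptiveCNN(AdaptiveCNNConfig(**cfg_raw))
            safe = raw["node_id"].replace(".", "_")
            with np.load(src / f"{safe}.npz") as data:
                node.classifier.network.load_state_dict({k: data[k] for k in data.files})
            node.classifier.trained = True
        return node

    return _build(topo)
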