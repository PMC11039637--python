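"""Fully convolutional encoder-decoder segmenter (FCEDN) and its
hyperparameter encoding.

An architecture is a flat real vector ``X_i = {P_i1, ..., P_ik}`` with one
gene per tunable field.  The default layout has ``k = 22`` genes: four
encoder convolutions and four decoder transposed convolutions (kernel count
and kernel size each), two max-pool and two unpool stages (pool size each),
and one dropout rate per side.  Gene ranges follow the published search
menu: kernel counts 20-200, kernel sizes 3-5, dropout 0.2-0.4.  Pool-size
genes are bounded 2-4 so that two pooling stages can evenly divide
desk-scale inputs (64/128 px); see the methods note.

Decoding clips every gene to its bounds, rounds integer genes, and repairs
the unpool factors to mirror the encoder pool factors in reverse so the
decoder restores the input resolution exactly — the defining property of the
architecture (output size equals input size).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .exceptions import StructuralError, ValidationError
from .image import LabeledImage
from .nn import (Adam, Conv2D, Dropout, MaxPool2D, Network, ReLU, Sigmoid,
                 TransposedConv2D, Unpool2D, smoothed_jaccard_loss)

__all__ = [
    "LayerSpec", "NetworkSpec", "Gene", "VectorLayout", "SearchSpace",
    "HyperparameterVector", "TrainConfig", "default_layout", "default_network_spec",
    "encode", "decode", "build_network", "train_network", "predict_mask",
    "FCEDN", "SegmentationResults", "save_checkpoint", "load_checkpoint",
]

KERNEL_COUNT_RANGE = (20, 200)
KERNEL_SIZE_RANGE = (3, 5)
POOL_SIZE_RANGE = (2, 4)
DROP_RATE_RANGE = (0.2, 0.4)
LAYER_COUNT_RANGE = (2, 10)

_CONV_LIKE = ("conv", "transposed_conv")
_KINDS = ("conv", "transposed_conv", "max_pool", "unpool", "dropout", "relu", "output")


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    kernel_count: Optional[int] = None
    kernel_size: Optional[int] = None
    drop_rate: Optional[float] = None

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown layer kind {self.kind!r}")
        if self.kind in _CONV_LIKE:
            if not KERNEL_SIZE_RANGE[0] <= (self.kernel_size or 0) <= KERNEL_SIZE_RANGE[1]:
                raise ValidationError(
                    f"{self.kind} kernel_size must be in {KERNEL_SIZE_RANGE}, "
                    f"got {self.kernel_size}"
                )
            if not KERNEL_COUNT_RANGE[0] <= (self.kernel_count or 0) <= KERNEL_COUNT_RANGE[1]:
                raise ValidationError(
                    f"{self.kind} kernel_count must be in {KERNEL_COUNT_RANGE}, "
                    f"got {self.kernel_count}"
                )
        if self.kind in ("max_pool", "unpool"):
            if self.kernel_size is None or self.kernel_size < 2:
                raise ValidationError(f"{self.kind} needs a pool size >= 2")
        if self.kind == "dropout":
            if self.drop_rate is None or not (
                DROP_RATE_RANGE[0] <= self.drop_rate <= DROP_RATE_RANGE[1]
            ):
                raise ValidationError(
                    f"drop_rate must be in {DROP_RATE_RANGE}, got {self.drop_rate}"
                )


@dataclass(frozen=True)
class NetworkSpec:
    encoder: tuple[LayerSpec, ...]
    decoder: tuple[LayerSpec, ...]
    input_height: int = 64
    input_width: int = 64
    input_channels: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "encoder", tuple(self.encoder))
        object.__setattr__(self, "decoder", tuple(self.decoder))

    def _count(self, kind: str) -> int:
        return sum(layer.kind == kind for layer in self.encoder + self.decoder)

    def pool_sizes(self) -> list[int]:
        return [l.kernel_size for l in self.encoder if l.kind == "max_pool"]

    def unpool_sizes(self) -> list[int]:
        return [l.kernel_size for l in self.decoder if l.kind == "unpool"]

    def validate(self) -> None:
        for layer in self.encoder + self.decoder:
            layer.validate()
        n_conv, n_tconv = self._count("conv"), self._count("transposed_conv")
        n_pool, n_unpool = self._count("max_pool"), self._count("unpool")
        lo, hi = LAYER_COUNT_RANGE
        for name, n in (("conv", n_conv), ("transposed_conv", n_tconv),
                        ("max_pool", n_pool), ("unpool", n_unpool)):
            if not lo <= n <= hi:
                raise ValidationError(f"{name} layer count {n} outside [{lo},{hi}]")
        if n_conv != n_tconv:
            raise ValidationError(
                f"conv count {n_conv} must equal transposed_conv count {n_tconv}"
            )
        if n_pool != n_unpool:
            raise ValidationError(
                f"max_pool count {n_pool} must equal unpool count {n_unpool}"
            )

    def to_json(self) -> str:
        return json.dumps({
            "encoder": [vars(l) for l in self.encoder],
            "decoder": [vars(l) for l in self.decoder],
            "input_height": self.input_height,
            "input_width": self.input_width,
            "input_channels": self.input_channels,
        })

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        raw = json.loads(text)
        return cls(
            encoder=tuple(LayerSpec(**d) for d in raw["encoder"]),
            decoder=tuple(LayerSpec(**d) for d in raw["decoder"]),
            input_height=raw["input_height"],
            input_width=raw["input_width"],
            input_channels=raw["input_channels"],
        )


@dataclass(frozen=True)
class Gene:
    name: str
    section: str        # "encoder" | "decoder"
    layer_index: int
    field: str          # "kernel_count" | "kernel_size" | "drop_rate"
    lower: float
    upper: float
    integer: bool


# canonical layer composition behind the 22-gene layout:
# encoder  conv relu conv relu pool conv relu conv relu pool dropout
# decoder  unpool tconv relu tconv relu unpool tconv relu tconv relu dropout output
_ENC_KINDS = ("conv", "relu", "conv", "relu", "max_pool",
              "conv", "relu", "conv", "relu", "max_pool", "dropout")
_DEC_KINDS = ("unpool", "transposed_conv", "relu", "transposed_conv", "relu",
              "unpool", "transposed_conv", "relu", "transposed_conv", "relu",
              "dropout", "output")


@dataclass(frozen=True)
class VectorLayout:
    genes: tuple[Gene, ...]
    encoder_kinds: tuple[str, ...] = _ENC_KINDS
    decoder_kinds: tuple[str, ...] = _DEC_KINDS

    def __len__(self) -> int:
        return len(self.genes)


def default_layout() -> VectorLayout:
    """The 22-gene layout: 4 conv + 4 transposed conv (count & size each),
    2 pools + 2 unpools (size each), 2 dropouts (rate each)."""
    genes: list[Gene] = []

    def _conv(section: str, idx: int, tag: str) -> None:
        genes.append(Gene(f"{tag}_nk", section, idx, "kernel_count",
                          *KERNEL_COUNT_RANGE, True))
        genes.append(Gene(f"{tag}_ks", section, idx, "kernel_size",
                          *KERNEL_SIZE_RANGE, True))

    _conv("encoder", 0, "cv1")
    _conv("encoder", 2, "cv2")
    genes.append(Gene("mp1_ps", "encoder", 4, "kernel_size", *POOL_SIZE_RANGE, True))
    _conv("encoder", 5, "cv3")
    _conv("encoder", 7, "cv4")
    genes.append(Gene("mp2_ps", "encoder", 9, "kernel_size", *POOL_SIZE_RANGE, True))
    genes.append(Gene("dl1_dr", "encoder", 10, "drop_rate", *DROP_RATE_RANGE, False))

    genes.append(Gene("un1_ps", "decoder", 0, "kernel_size", *POOL_SIZE_RANGE, True))
    _conv("decoder", 1, "tcv1")
    _conv("decoder", 3, "tcv2")
    genes.append(Gene("un2_ps", "decoder", 5, "kernel_size", *POOL_SIZE_RANGE, True))
    _conv("decoder", 6, "tcv3")
    _conv("decoder", 8, "tcv4")
    genes.append(Gene("dl2_dr", "decoder", 10, "drop_rate", *DROP_RATE_RANGE, False))
    return VectorLayout(genes=tuple(genes))


@dataclass(frozen=True)
class SearchSpace:
    lower: np.ndarray
    upper: np.ndarray
    integer: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lower >= self.upper):
            raise ValidationError("every gene needs lower < upper")

    def __len__(self) -> int:
        return len(self.lower)

    @classmethod
    def from_layout(cls, layout: VectorLayout) -> "SearchSpace":
        return cls(
            lower=np.array([g.lower for g in layout.genes], dtype=float),
            upper=np.array([g.upper for g in layout.genes], dtype=float),
            integer=np.array([g.integer for g in layout.genes], dtype=bool),
        )

    def clip(self, values: np.ndarray) -> np.ndarray:
        return np.clip(values, self.lower, self.upper)

    def round_clip(self, values: np.ndarray) -> np.ndarray:
        """Integer genes rounded to nearest, then everything clipped."""
        out = np.asarray(values, dtype=float).copy()
        out[self.integer] = np.round(out[self.integer])
        return self.clip(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, len(self)))


@dataclass(frozen=True)
class HyperparameterVector:
    values: np.ndarray
    layout: VectorLayout

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) != len(self.layout):
            raise StructuralError(
                f"vector length {len(self.values)} does not match layout "
                f"length {len(self.layout)}"
            )


def encode(spec: NetworkSpec, layout: VectorLayout) -> HyperparameterVector:
    """Flatten a network spec into its gene vector (layout order)."""
    enc_kinds = tuple(l.kind for l in spec.encoder)
    dec_kinds = tuple(l.kind for l in spec.decoder)
    if enc_kinds != layout.encoder_kinds:
        idx = next(i for i, (a, b) in enumerate(
            zip(enc_kinds, layout.encoder_kinds)) if a != b) if len(
            enc_kinds) == len(layout.encoder_kinds) else min(
            len(enc_kinds), len(layout.encoder_kinds))
        raise StructuralError(f"encoder composition mismatch at layer {idx}")
    if dec_kinds != layout.decoder_kinds:
        idx = next(i for i, (a, b) in enumerate(
            zip(dec_kinds, layout.decoder_kinds)) if a != b) if len(
            dec_kinds) == len(layout.decoder_kinds) else min(
            len(dec_kinds), len(layout.decoder_kinds))
        raise StructuralError(f"decoder composition mismatch at layer {idx}")
    values = []
    for gene in layout.genes:
        section = spec.encoder if gene.section == "encoder" else spec.decoder
        values.append(float(getattr(section[gene.layer_index], gene.field)))
    return HyperparameterVector(values=np.array(values), layout=layout)


def decode(vector: HyperparameterVector | np.ndarray, space: SearchSpace,
           layout: VectorLayout, input_height: int = 64, input_width: int = 64,
           input_channels: int = 3) -> NetworkSpec:
    """Round/clip genes and assemble a valid :class:`NetworkSpec`.

    Unpool factors are repaired to mirror the encoder pool factors in
    reverse order (spatial-symmetry constraint repair).
    """
    values = vector.values if isinstance(vector, HyperparameterVector) else np.asarray(vector)
    if len(values) != len(layout):
        raise StructuralError(
            f"vector length {len(values)} does not match layout length {len(layout)}"
        )
    values = space.round_clip(values)

    enc_fields: list[dict] = [dict() for _ in layout.encoder_kinds]
    dec_fields: list[dict] = [dict() for _ in layout.decoder_kinds]
    for gene, val in zip(layout.genes, values):
        target = enc_fields if gene.section == "encoder" else dec_fields
        target[gene.layer_index][gene.field] = int(val) if gene.integer else float(val)

    encoder = tuple(LayerSpec(kind=k, **f) for k, f in zip(layout.encoder_kinds, enc_fields))
    pool_sizes = [l.kernel_size for l in encoder if l.kind == "max_pool"]
    mirrored = iter(reversed(pool_sizes))
    decoder = tuple(
        LayerSpec(kind=k, **{**f, "kernel_size": next(mirrored)}) if k == "unpool"
        else LayerSpec(kind=k, **f)
        for k, f in zip(layout.decoder_kinds, dec_fields)
    )
    spec = NetworkSpec(encoder=encoder, decoder=decoder, input_height=input_height,
                       input_width=input_width, input_channels=input_channels)
    spec.validate()
    return spec


def default_network_spec(input_height: int = 64, input_width: int = 64,
                         input_channels: int = 3) -> NetworkSpec:
    """The fixed default architecture: mid-range genes of the 22-gene layout."""
    layout = default_layout()
    space = SearchSpace.from_layout(layout)
    mid = (space.lower + space.upper) / 2.0
    # modest kernel counts keep the default net desk-trainable
    mid[[g.field == "kernel_count" for g in layout.genes]] = 32
    mid[[g.field == "kernel_size" and g.name.endswith("ks") for g in layout.genes]] = 3
    mid[np.array([g.field == "kernel_size" and "ps" in g.name for g in layout.genes])] = 2
    return decode(mid, space, layout, input_height, input_width, input_channels)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 15
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    max_images: Optional[int] = None
    loss_epsilon: float = 1.0

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValidationError(f"epochs must be >= 0, got {self.epochs}")
        for name in ("batch_size", "learning_rate", "loss_epsilon"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.max_images is not None and self.max_images < 1:
            raise ValidationError("max_images must be >= 1 or None")


class FCEDN:
    """The trainable encoder-decoder segmentation model.

    Statsmodels-style usage::

        model = FCEDN(spec, seed=0)
        res = model.fit(images, TrainConfig(epochs=15))
        print(res.summary())
        mask = model.predict_mask(image)
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        spec.validate()
        pool = int(np.prod(spec.pool_sizes()))
        unpool = int(np.prod(spec.unpool_sizes()))
        if pool != unpool:
            raise ValidationError(
                f"pool product {pool} must equal unpool product {unpool} for the "
                f"output to match the input size"
            )
        if spec.input_height % pool or spec.input_width % pool:
            raise ValidationError(
                f"input {spec.input_height}x{spec.input_width} must be divisible "
                f"by the pool-size product {pool}"
            )
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers = []
        ch = spec.input_channels
        for layer_spec in spec.encoder + spec.decoder:
            k = layer_spec.kind
            if k == "conv":
                layers.append(Conv2D(ch, layer_spec.kernel_count, layer_spec.kernel_size, rng))
                ch = layer_spec.kernel_count
            elif k == "transposed_conv":
                layers.append(TransposedConv2D(ch, layer_spec.kernel_count,
                                               layer_spec.kernel_size, rng))
                ch = layer_spec.kernel_count
            elif k == "relu":
                layers.append(ReLU())
            elif k == "max_pool":
                layers.append(MaxPool2D(layer_spec.kernel_size))
            elif k == "unpool":
                layers.append(Unpool2D(layer_spec.kernel_size))
            elif k == "dropout":
                layers.append(Dropout(layer_spec.drop_rate))
            elif k == "output":
                layers.append(Conv2D(ch, 1, 1, rng))
                layers.append(Sigmoid())
        if spec.decoder and spec.decoder[-1].kind != "output":
            layers.append(Conv2D(ch, 1, 1, rng))
            layers.append(Sigmoid())
        self.network = Network(layers)

    # -- data plumbing -----------------------------------------------------
    def _check_image(self, image: LabeledImage) -> None:
        if (image.height, image.width) != (self.spec.input_height, self.spec.input_width):
            raise ValidationError(
                f"image size {image.height}x{image.width} does not match model input "
                f"{self.spec.input_height}x{self.spec.input_width}"
            )

    def _to_batch(self, images: Sequence[LabeledImage]) -> np.ndarray:
        arrs = []
        for img in images:
            self._check_image(img)
            px = img.pixels.astype(np.float32) / 255.0
            if px.ndim == 2:
                px = px[:, :, None]
            if px.shape[2] != self.spec.input_channels:
                raise ValidationError(
                    f"image has {px.shape[2]} channels, model expects "
                    f"{self.spec.input_channels}"
                )
            arrs.append(px.transpose(2, 0, 1))
        return np.stack(arrs)

    @property
    def n_params(self) -> int:
        return self.network.n_params()

    # -- training ----------------------------------------------------------
    def fit(self, images: Sequence[LabeledImage],
            cfg: TrainConfig = TrainConfig()) -> "SegmentationResults":
        cfg.validate()
        for i, img in enumerate(images):
            if img.mask is None:
                raise ValidationError(f"training image {i} has no mask")
        if cfg.max_images is not None:
            images = list(images)[: cfg.max_images]
        x = self._to_batch(images)
        y = np.stack([img.mask.astype(np.float32) for img in images])[:, None]

        ss = np.random.SeedSequence(cfg.seed)
        rng_shuffle, rng_drop = (np.random.default_rng(s) for s in ss.spawn(2))
        self.network.set_rng(rng_drop)
        opt = Adam(self.network, learning_rate=cfg.learning_rate)
        history: list[float] = []
        n = x.shape[0]
        for _ in range(cfg.epochs):
            perm = rng_shuffle.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                probs = self.network.forward(x[idx], training=True)
                loss, dprobs = smoothed_jaccard_loss(probs, y[idx], eps=cfg.loss_epsilon)
                self.network.backward(dprobs)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return SegmentationResults(model=self, history=history, config=cfg,
                                   n_images=n)

    # -- inference ---------------------------------------------------------
    def predict_proba(self, images: LabeledImage | Sequence[LabeledImage]) -> np.ndarray:
        single = isinstance(images, LabeledImage)
        batch = [images] if single else list(images)
        probs = self.network.forward(self._to_batch(batch), training=False)[:, 0]
        return probs[0] if single else probs

    def predict_mask(self, image: LabeledImage, threshold: float = 0.5) -> np.ndarray:
        """Binary mask: probability >= threshold (so threshold 0 -> all ones)."""
        return (self.predict_proba(image) >= threshold).astype(np.uint8)


@dataclass
class SegmentationResults:
    """Fit results: per-epoch loss history plus evaluation helpers."""

    model: FCEDN
    history: List[float]
    config: TrainConfig
    n_images: int

    @property
    def final_loss(self) -> Optional[float]:
        return self.history[-1] if self.history else None

    def evaluate(self, images: Sequence[LabeledImage], threshold: float = 0.5,
                 eps: float = 0.0):
        from .metrics import (accuracy, confusion, dice, f1, jaccard,
                              metric_report, sensitivity, specificity)
        rows = []
        for i, img in enumerate(images):
            pred = self.model.predict_mask(img, threshold)
            c = confusion(pred, img.mask)
            row = {"image": str(i), "accuracy": accuracy(c),
                   "jaccard": jaccard(pred, img.mask, eps),
                   "dice": dice(pred, img.mask, eps)}
            try:
                row["sensitivity"] = sensitivity(c)
                row["specificity"] = specificity(c)
                row["f1"] = f1(c)
            except Exception:
                pass
            rows.append(row)
        return metric_report(rows)

    def summary(self) -> str:
        lines = [
            "FCEDN segmentation fit",
            "======================",
            f"parameters:      {self.model.n_params}",
            f"training images: {self.n_images}",
            f"epochs:          {len(self.history)}",
        ]
        if self.history:
            lines += [
                f"initial loss:    {self.history[0]:.4f}",
                f"final loss:      {self.history[-1]:.4f}",
            ]
        return "\n".join(lines)


def build_network(spec: NetworkSpec, seed: int = 0) -> FCEDN:
    """Construct the trainable model for ``spec`` (functional facade)."""
    return FCEDN(spec, seed=seed)


def train_network(model: FCEDN, data: Sequence[LabeledImage],
                  cfg: TrainConfig) -> tuple[FCEDN, List[float]]:
    """Train in place; returns ``(model, per-epoch loss history)``."""
    res = model.fit(data, cfg)
    return model, res.history


def predict_mask(model: FCEDN, image: LabeledImage, threshold: float = 0.5) -> np.ndarray:
    return model.predict_mask(image, threshold)


def save_checkpoint(model: FCEDN, path: str | Path) -> None:
    """Single self-describing file: spec as a JSON header plus the weights."""
    state = model.network.state_dict()
    np.savez(path, __spec__=np.array(model.spec.to_json()),
             __seed__=np.array(model.seed), **state)


def load_checkpoint(path: str | Path) -> FCEDN:
    with np.load(path, allow_pickle=False) as data:
        spec = NetworkSpec.from_json(str(data["__spec__"]))
        model = FCEDN(spec, seed=int(data["__seed__"]))
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    model.network.load_state_dict(state)
    return model
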