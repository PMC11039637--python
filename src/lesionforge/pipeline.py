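"""End-to-end orchestration: generate -> preprocess -> optimize -> train ->
segment -> classify -> evaluate.

A :class:`RunConfig` names an ordered subset of stages plus per-stage config
blocks; :func:`run` executes them, writing one artifact directory and a
manifest (config hash, seed, stage inputs) per stage, and returns a
:class:`RunReport` whose metric tables aggregate accuracy / sensitivity /
Jaccard / Dice per split.  ``(config, seed)`` fully determine every number
in the report.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .exceptions import ValidationError
from .fcedn import (FCEDN, SearchSpace, TrainConfig, decode, default_layout,
                    default_network_spec, save_checkpoint)
from .image import LabeledImage
from .preprocess import PreprocessConfig, run_pipeline
from .spasa import (ArchitectureObjective, FitnessContext, OptimizerConfig,
                    optimize)
from .synthetic import LesionSpec, generate_dataset, write_dataset
from .treecnn import GrowthPolicy, TreeCNN, save_tree

__all__ = ["RunConfig", "RunReport", "run", "evaluate_run", "split_dataset"]

logger = logging.getLogger("lesionforge")

STAGES = ("generate", "preprocess", "optimize", "train_seg", "segment",
          "train_cls", "grow", "classify", "evaluate")

# a stage is satisfied if ANY of its alternatives ran earlier
_DEPS: dict[str, list[str]] = {
    "preprocess": ["generate"],
    "optimize": ["generate"],
    "train_seg": ["generate"],
    "segment": ["train_seg"],
    "train_cls": ["generate"],
    "grow": ["train_cls"],
    "classify": ["train_cls"],
    "evaluate": ["segment", "classify"],
}


@dataclass(frozen=True)
class GenerateConfig:
    n: int = 60
    height: int = 64
    width: int = 64
    foreground_fraction: float = 0.20
    hair_count: int = 3
    impulse_noise_prob: float = 0.02
    speckle_variance: float = 0.01
    # classification: per-class lesion sizes make classes visually separable;
    # empty means a single segmentation class at foreground_fraction
    class_fractions: tuple[float, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    stages: tuple[str, ...] = ("generate", "preprocess", "optimize", "train_seg",
                               "segment", "evaluate")
    seed: int = 0
    out_dir: str = "lesionforge_run"
    log_level: str = "INFO"
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    generate: GenerateConfig = GenerateConfig()
    preprocess: PreprocessConfig = PreprocessConfig(target_height=64, target_width=64)
    optimizer: OptimizerConfig = OptimizerConfig(population_size=5, iterations=3)
    fitness_train: TrainConfig = TrainConfig(epochs=5, max_images=16)
    final_train: TrainConfig = TrainConfig(epochs=8)
    growth: GrowthPolicy = GrowthPolicy()
    grow_classes: tuple[int, ...] = ()   # class ids introduced by the `grow` stage

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in STAGES:
                raise ValidationError(f"unknown stage {stage!r}; valid: {STAGES}")
        seen: list[str] = []
        for stage in self.stages:
            needs = _DEPS.get(stage, [])
            if needs and not any(dep in seen for dep in needs):
                raise ValidationError(
                    f"stage {stage!r} requires one of {needs} to run first"
                )
            seen.append(stage)
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValidationError(f"split must sum to 1, got {self.split}")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        blocks = {
            "generate": GenerateConfig, "preprocess": PreprocessConfig,
            "optimizer": OptimizerConfig, "fitness_train": TrainConfig,
            "final_train": TrainConfig, "growth": GrowthPolicy,
        }
        for key, klass in blocks.items():
            if key in raw and isinstance(raw[key], dict):
                block = dict(raw[key])
                for fname, f in ((f.name, f) for f in dataclasses.fields(klass)):
                    if fname in block and isinstance(block[fname], list):
                        block[fname] = tuple(
                            tuple(v) if isinstance(v, list) else v for v in block[fname])
                raw[key] = klass(**block)
        for key in ("stages", "split", "grow_classes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    values: Dict[str, float] = field(default_factory=dict)
    artifacts: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash,
            "seed": self.seed,
            "values": self.values,
            "tables": {k: v.to_dict(orient="records") for k, v in self.tables.items()},
            "artifacts": self.artifacts,
        }, indent=2, default=float)

    def summary(self) -> str:
        lines = [f"run {self.config_hash} (seed {self.seed})"]
        for key, val in self.values.items():
            lines.append(f"  {key}: {val:.4f}" if isinstance(val, float)
                         else f"  {key}: {val}")
        return "\n".join(lines)


def split_dataset(images: Sequence[LabeledImage], split: tuple[float, float, float],
                  seed: int) -> tuple[list, list, list]:
    """Seeded train/validation/test partition (default 80/10/10)."""
    n = len(images)
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    idx = {
        "train": perm[:n_train],
        "val": perm[n_train:n_train + n_val],
        "test": perm[n_train + n_val:],
    }
    return ([images[i] for i in idx["train"]],
            [images[i] for i in idx["val"]],
            [images[i] for i in idx["test"]])


def _segmentation_rows(preds: Sequence[np.ndarray],
                       truths: Sequence[np.ndarray]) -> list[dict]:
    rows = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        c = M.confusion(p, t)
        row = {"image": str(i), "accuracy": M.accuracy(c),
               "jaccard": M.jaccard(p, t), "dice": M.dice(p, t)}
        for name, fn in (("sensitivity", M.sensitivity), ("specificity", M.specificity),
                         ("precision", M.precision), ("f1", M.f1), ("mcc", M.mcc)):
            try:
                row[name] = fn(c)
            except Exception:
                row[name] = np.nan
        rows.append(row)
    return rows


def evaluate_run(predictions_dir: str | Path, truth_dir: str | Path) -> RunReport:
    """Compare prediction masks with ground truth by matching file stems."""
    pred_dir, true_dir = Path(predictions_dir), Path(truth_dir)
    preds = {p.stem: p for p in sorted(pred_dir.glob("*.png"))}
    truths = {p.stem: p for p in sorted(true_dir.glob("*.png"))}
    common = sorted(set(preds) & set(truths))
    unmatched = sorted(set(preds) ^ set(truths))
    rows = []
    for stem in common:
        p = (iio.imread(preds[stem]) > 127).astype(np.uint8)
        t = (iio.imread(truths[stem]) > 127).astype(np.uint8)
        row = _segmentation_rows([p], [t])[0]
        row["image"] = stem
        rows.append(row)
    report = RunReport(config_hash="evaluate-only", seed=0)
    report.tables["segmentation"] = M.metric_report(rows)
    if unmatched:
        report.tables["unmatched"] = pd.DataFrame({"stem": unmatched})
    return report


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages in order (see module docstring)."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    state: dict = {}

    for stage in config.stages:
        logger.info("stage %s starting", stage)
        stage_dir = out_root / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        _STAGE_FNS[stage](config, state, stage_dir, report)
        report.artifacts[stage] = str(stage_dir)
        (stage_dir / "manifest.json").write_text(json.dumps({
            "stage": stage, "seed": config.seed, "config_hash": config.config_hash(),
        }, indent=2))
        logger.info("stage %s done", stage)

    (out_root / "report.json").write_text(report.to_json())
    for name, table in report.tables.items():
        table.to_csv(out_root / f"{name}.csv", index=False)
    return report


# -- individual stages -------------------------------------------------------

def _stage_generate(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    g = cfg.generate
    specs = [LesionSpec(height=g.height, width=g.width, foreground_fraction=frac,
                        hair_count=g.hair_count, impulse_noise_prob=g.impulse_noise_prob,
                        speckle_variance=g.speckle_variance, class_id=i)
             for i, frac in enumerate(g.class_fractions)] or [
        LesionSpec(height=g.height, width=g.width,
                   foreground_fraction=g.foreground_fraction)]
    images = generate_dataset(g.n, specs, seed=cfg.seed)
    state["images"] = images
    write_dataset(images, out)


def _stage_preprocess(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    processed = [run_pipeline(img, cfg.preprocess) for img in state["images"]]
    state["images"] = processed
    write_dataset(processed, out)


def _split(cfg: RunConfig, state: dict) -> tuple[list, list, list]:
    if "splits" not in state:
        state["splits"] = split_dataset(state["images"], cfg.split, cfg.seed)
    return state["splits"]


def _stage_optimize(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    train, val, _ = _split(cfg, state)
    layout = default_layout()
    space = SearchSpace.from_layout(layout)
    ctx = FitnessContext(train_images=train, eval_images=val,
                         train_cfg=replace(cfg.fitness_train, seed=cfg.seed))
    objective = ArchitectureObjective(ctx, space, layout)
    best, best_fitness, trace = optimize(space, objective,
                                         replace(cfg.optimizer, seed=cfg.seed))
    first = train[0]
    spec = decode(best, space, layout, input_height=first.height,
                  input_width=first.width)
    state["best_spec"] = spec
    state["trace"] = trace
    report.values["best_fitness"] = float(best_fitness)
    report.values["architectures_trained"] = float(objective.n_trained)
    genome = space.round_clip(best)
    trace_df = pd.DataFrame({
        "iteration": np.arange(len(trace)), "best_fitness": trace,
    })
    report.tables["optimize_trace"] = trace_df
    trace_df.assign(**{f"gene_{g.name}": v for g, v in zip(layout.genes, genome)}).to_csv(
        out / "trace.csv", index=False)
    (out / "best_spec.json").write_text(spec.to_json())


def _stage_train_seg(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    train, val, _ = _split(cfg, state)
    first = train[0]
    spec = state.get("best_spec") or default_network_spec(
        input_height=first.height, input_width=first.width)
    model = FCEDN(spec, seed=cfg.seed)
    res = model.fit(train, replace(cfg.final_train, seed=cfg.seed))
    state["seg_model"] = model
    report.values["train_loss_initial"] = res.history[0] if res.history else np.nan
    report.values["train_loss_final"] = res.final_loss or np.nan
    if val:
        table = res.evaluate(val)
        report.tables["validation_segmentation"] = table
        mean = table[table["image"] == "mean"]
        report.values["val_jaccard"] = float(mean["jaccard"].iloc[0])
        baseline = [M.jaccard(np.zeros_like(im.mask), im.mask) for im in val]
        report.values["baseline_jaccard"] = float(np.mean(baseline))
    save_checkpoint(model, out / "model.npz")


def _stage_segment(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    _, _, test = _split(cfg, state)
    model: FCEDN = state["seg_model"]
    preds = []
    (out / "truth").mkdir(exist_ok=True)
    for i, img in enumerate(test):
        pred = model.predict_mask(img)
        preds.append(pred)
        iio.imwrite(out / f"pred_{i:04d}.png", (pred * 255).astype(np.uint8))
        iio.imwrite(out / "truth" / f"pred_{i:04d}.png",
                    (img.mask * 255).astype(np.uint8))
    state["predictions"] = preds
    state["test_truths"] = [img.mask for img in test]


def _by_class(images: Sequence[LabeledImage]) -> Dict[int, list]:
    groups: Dict[int, list] = {}
    for img in images:
        groups.setdefault(img.label, []).append(img)
    return groups


def _resize_for_cls(images: Sequence[LabeledImage], size: int) -> list:
    from .preprocess import resize_bilinear
    pcfg = PreprocessConfig(target_height=size, target_width=size)
    return [resize_bilinear(img, pcfg) for img in images]


def _stage_train_cls(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    train, _, test = _split(cfg, state)
    size = cfg.growth.input_size
    groups = _by_class(_resize_for_cls(train, size))
    initial = {c: imgs for c, imgs in groups.items() if c not in set(cfg.grow_classes)}
    tree = TreeCNN(replace(cfg.growth, seed=cfg.seed))
    tree.fit(initial)
    state["tree"] = tree
    state["cls_test"] = _resize_for_cls(test, size)
    save_tree(tree.root, out)


def _stage_grow(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    train, _, _ = _split(cfg, state)
    tree: TreeCNN = state["tree"]
    size = cfg.growth.input_size
    groups = _by_class(_resize_for_cls(train, size))
    new = {c: imgs for c, imgs in groups.items() if c in set(cfg.grow_classes)}
    if new:
        tree.grow(new)
    save_tree(tree.root, out)


def _stage_classify(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    tree: TreeCNN = state["tree"]
    test = state["cls_test"]
    known = set()
    from .treecnn import leaf_classes
    known = set(leaf_classes(tree.root))
    test = [img for img in test if img.label in known]
    if not test:
        return
    preds = [tree.predict(img) for img in test]
    labels = [img.label for img in test]
    acc = float(np.mean(np.asarray(preds) == np.asarray(labels)))
    report.values["classification_accuracy"] = 100.0 * acc
    pd.DataFrame({"label": labels, "prediction": preds}).to_csv(
        out / "predictions.csv", index=False)


def _stage_evaluate(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    if "predictions" in state:
        rows = _segmentation_rows(state["predictions"], state["test_truths"])
        table = M.metric_report(rows)
        report.tables["test_segmentation"] = table
        mean = table[table["image"] == "mean"]
        report.values["test_accuracy"] = float(mean["accuracy"].iloc[0])
        report.values["test_jaccard"] = float(mean["jaccard"].iloc[0])
        report.values["test_dice"] = float(mean["dice"].iloc[0])
        table.to_csv(out / "segmentation_metrics.csv", index=False)


_STAGE_FNS = {
    "generate": _stage_generate,
    "preprocess": _stage_preprocess,
    "optimize": _stage_optimize,
    "train_seg": _stage_train_seg,
    "segment": _stage_segment,
    "train_cls": _stage_train_cls,
    "grow": _stage_grow,
    "classify": _stage_classify,
    "evaluate": _stage_evaluate,
}
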