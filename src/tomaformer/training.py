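"""Training loop, dataset split, evaluation aggregation, checkpointing.

Training minimizes the composite L_t objective with Adadelta (learning
rate 1.00, decay rho 0.95) over seeded mini-batches; after every epoch
the model is scored on the held-out split and the best-by-validation-mIoU
and last checkpoints are kept. Runs are fully seed-deterministic: the
split, the weight init, the batch order and the arithmetic are all
functions of the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np

from . import losses, metrics
from .losses import LossConfig
from .model import ConvTransformerSegmenter, ModelConfig, save_checkpoint, load_checkpoint
from .nn import Adadelta, Tensor, no_grad


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Run configuration.

    ``iterations_per_epoch=None`` means one pass over the training split
    per epoch; a fixed count (e.g. 512) oversamples with replacement.
    """

    epochs: int = 200
    batch_size: int = 16
    iterations_per_epoch: int | None = None
    split_fraction: float = 0.75
    optimizer: str = "adadelta"
    learning_rate: float = 1.0
    decay: float = 0.95
    seed: int = 0
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "adadelta":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def split_dataset(items, split_fraction: float, seed: int):
    """Seed-deterministic shuffle, then floor(n * fraction) items to train
    and the remainder to the held-out part; both parts must be nonempty."""
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    n_train = int(np.floor(n * split_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"split_fraction {split_fraction} leaves an empty part for n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    train = [items[i] for i in perm[:n_train]]
    heldout = [items[i] for i in perm[n_train:]]
    return train, heldout


def _to_batch(items) -> tuple[Tensor, np.ndarray]:
    images = np.stack([im.transpose(2, 0, 1) for im, _ in items])
    masks = np.stack([m for _, m in items])
    return Tensor(images), losses.one_hot(masks)


def evaluate_model(model: ConvTransformerSegmenter, dataset,
                   iou_threshold: float = 0.5) -> metrics.MetricReport:
    """Run the model over a dataset and aggregate one MetricReport.

    Confusions are summed over images, detection boxes pooled with image
    ids (matching never crosses images), and AUC computed over the pooled
    pixels.
    """
    model.eval()
    c = model.config.n_classes
    confusion = np.zeros((c, c), dtype=np.int64)
    pred_boxes, truth_boxes = [], []
    all_probs, all_truth = [], []
    for i, (image, mask) in enumerate(dataset):
        pred, probs = model.predict(image)
        confusion += metrics.confusion_matrix(pred, mask, c)
        pred_boxes += metrics.masks_to_instances(pred, probs, image_id=i)
        truth_boxes += metrics.masks_to_instances(mask, image_id=i)
        all_probs.append(probs.reshape(-1, c))
        all_truth.append(mask.ravel())
    classwise, mean_iou, mean_dice = metrics.iou_and_dice(confusion)
    _, map_score = metrics.average_precision(pred_boxes, truth_boxes, iou_threshold)
    auc = (metrics.pixel_auc(np.concatenate(all_probs), np.concatenate(all_truth))
           if all_probs else None)
    return metrics.MetricReport(classwise, mean_iou, mean_dice, map_score,
                                auc, confusion)


def train(config: TrainConfig, dataset, out_dir=None):
    """Train a model on (image, mask) pairs; returns (model, log).

    With fewer than two items the whole dataset doubles as its own
    validation set (the overfitting regime used by the convergence
    smoke test); otherwise it is split by ``split_fraction``.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    if len(dataset) >= 2:
        train_set, heldout = split_dataset(dataset, config.split_fraction, config.seed)
    else:
        train_set = heldout = list(dataset)

    model = ConvTransformerSegmenter(config.model, seed=config.seed)
    optimizer = Adadelta(model.parameters(), lr=config.learning_rate,
                         rho=config.decay)
    n_iters = (config.iterations_per_epoch if config.iterations_per_epoch
               else max(1, int(np.ceil(len(train_set) / config.batch_size))))
    rng = np.random.default_rng(config.seed + 1)

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    best_miou = -np.inf
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for it in range(n_iters):
            if config.iterations_per_epoch:
                pick = rng.integers(0, len(train_set), size=config.batch_size)
            else:
                pick = order[it * config.batch_size:(it + 1) * config.batch_size]
                if pick.size == 0:
                    break
            batch = [train_set[i] for i in pick]
            x, target = _to_batch(batch)
            logits, _ = model(x)
            l_t, l_s1, l_s2 = losses.total_loss(target, logits, config.loss)
            if not np.isfinite(l_t.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, iteration {it} "
                    f"(batch indices {pick.tolist()}, seed {config.seed})")
            model.zero_grad()
            l_t.backward()
            optimizer.step()
            epoch_losses.append(l_t.item())

        report = evaluate_model(model, heldout)
        with no_grad():
            x, target = _to_batch(heldout)
            model.eval()
            logits, _ = model(x)
            val_loss = losses.total_loss(target, logits, config.loss)[0].item()
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_miou": report.mean_iou,
            "time": time.time(),
            "config_hash": config.model.hash(),
        }
        log.append(record)
        if out_dir is not None:
            with open(out_dir / "log.jsonl", "a") as fh:
                fh.write(json.dumps(record) + "\n")
                fh.flush()
            save_checkpoint(model, out_dir / "last.npz")
            if report.mean_iou >= best_miou:
                save_checkpoint(model, out_dir / "best.npz")
        if report.mean_iou >= best_miou:
            best_miou = report.mean_iou
    return model, log


def evaluate_checkpoint(path, dataset, iou_threshold: float = 0.5):
    """Load a checkpoint (config-hash verified) and evaluate it."""
    model = load_checkpoint(path)
    return evaluate_model(model, dataset, iou_threshold)
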