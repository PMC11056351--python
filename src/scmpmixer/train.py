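"""Training loop, checkpointing, evaluation and the ablation driver.

The loop minimizes categorical cross-entropy with Adam, shuffles the
training set each epoch (seeded), records per-epoch train/validation loss
and accuracy, and retains the parameter snapshot with the highest
validation accuracy. Evaluation always runs in inference mode (dropout
off, batch-norm running statistics), so reports are deterministic and
batch-size invariant.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as me
from .data import ImageSet, TrainConfig, to_onehot
from .model import (ModelConfig, SCMPMixer, VARIANTS, build_model,
                    variant_config)
from .nn import Adam, attach_rng
from .nn import functional as F
from .swin_core import SwinBlockConfig

logger = logging.getLogger(__name__)


@dataclass
class RunRecord:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = -1.0

    @property
    def epochs(self) -> int:
        return len(self.train_loss)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def predict_probs(model: SCMPMixer, images: np.ndarray,
                  batch_size: int = 16) -> np.ndarray:
    """Batched deterministic inference; class probabilities per image."""
    model.set_training(False)
    chunks = [model.forward(images[i:i + batch_size])
              for i in range(0, len(images), batch_size)]
    return np.concatenate(chunks, axis=0)


def _loss_and_acc(model, images, labels, num_classes, batch_size):
    probs = predict_probs(model, images, batch_size)
    loss = F.cross_entropy(to_onehot(labels, num_classes), probs)
    acc = float(np.mean(np.argmax(probs, axis=1) == labels))
    return loss, acc


def train(model: SCMPMixer, subsets, cfg: TrainConfig):
    """Train on (train, val) subsets; returns (RunRecord, best state dict).

    The best state is the deep-copied parameter/buffer snapshot at the
    epoch with the highest validation accuracy.
    """
    cfg.validate()
    train_set, val_set = subsets[0], subsets[1]
    c = model.cfg.num_classes
    rng = np.random.default_rng(cfg.seed)
    attach_rng(model, np.random.default_rng(cfg.seed + 1))
    opt = Adam(model.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2,
               cfg.adam_eps)
    record = RunRecord()
    best_state = model.state_dict()
    y_train = to_onehot(train_set.labels, c)
    n = len(train_set)
    for epoch in range(cfg.epochs):
        model.set_training(True)
        perm = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = train_set.images[idx], y_train[idx]
            probs = model.forward(xb)
            loss = F.cross_entropy(yb, probs)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, "
                    f"batch starting {start}; aborting")
            dlogits = (probs - yb) / len(idx)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int(np.sum(np.argmax(probs, axis=1)
                                        == train_set.labels[idx]))
        val_loss, val_acc = _loss_and_acc(model, val_set.images,
                                          val_set.labels, c, cfg.batch_size)
        record.train_loss.append(epoch_loss / n)
        record.train_acc.append(epoch_correct / n)
        record.val_loss.append(val_loss)
        record.val_acc.append(val_acc)
        if val_acc > record.best_val_acc:
            record.best_val_acc = val_acc
            record.best_epoch = epoch
            best_state = model.state_dict()
        logger.info("epoch %d/%d train_loss %.4f train_acc %.3f "
                    "val_loss %.4f val_acc %.3f", epoch + 1, cfg.epochs,
                    record.train_loss[-1], record.train_acc[-1],
                    val_loss, val_acc)
    return record, best_state


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SCMPMixer, state: dict | None = None):
    """Parameters as .npz plus a JSON sidecar holding the architecture."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **(state if state is not None else model.state_dict()))
    cfg = dataclasses.asdict(model.cfg)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))
    return path


def load_checkpoint(path) -> SCMPMixer:
    path = Path(path)
    raw = json.loads(path.with_suffix(".json").read_text())
    raw["swin"] = SwinBlockConfig(**raw["swin"])
    for key in ("mpcm_patches", "upsample_strides", "mpst_grids"):
        raw[key] = tuple(raw[key])
    model = build_model(ModelConfig(**raw))
    with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


# ---------------------------------------------------------------------------
# evaluation / ablation
# ---------------------------------------------------------------------------

def evaluate(model: SCMPMixer, test_set: ImageSet, batch_size: int = 16,
             out_dir=None):
    """Deterministic inference on a test subset.

    Returns ``(report frame, ConfusionMatrix, predictions frame)``; when
    ``out_dir`` is given also writes metrics.csv/json, the confusion
    matrix CSV and a per-image predictions CSV there.
    """
    c = model.cfg.num_classes
    if c != len(test_set.class_names):
        raise ValueError(
            f"model has {c} classes but data has "
            f"{len(test_set.class_names)} ({test_set.class_names})")
    probs = predict_probs(model, test_set.images, batch_size)
    predicted = np.argmax(probs, axis=1)  # ties -> lowest class index
    cm = me.confusion_matrix(test_set.labels, predicted, c,
                             test_set.class_names)
    frame = me.report(cm, out_dir=out_dir)
    predictions = pd.DataFrame({
        "index": np.arange(len(predicted)),
        "true": [test_set.class_names[i] for i in test_set.labels],
        "predicted": [test_set.class_names[i] for i in predicted],
    })
    if out_dir is not None:
        predictions.to_csv(Path(out_dir) / "predictions.csv", index=False)
    return frame, cm, predictions


def ablate(subsets, model_cfg: ModelConfig, train_cfg: TrainConfig,
           out_dir=None) -> pd.DataFrame:
    """Train and evaluate all seven architecture variants under one seed.

    One variant's failure is recorded (error column) without aborting the
    rest. Returns a comparison table with the macro metrics per variant.
    """
    train_set, val_set, test_set = subsets
    rows = []
    for variant in VARIANTS:
        try:
            model = build_model(variant_config(model_cfg, variant))
            record, best_state = train(model, (train_set, val_set), train_cfg)
            model.load_state_dict(best_state)
            frame, _, _ = evaluate(model, test_set, train_cfg.batch_size)
            macro = frame[frame["class"] == "MACRO"].iloc[0]
            rows.append({"variant": variant, "acc": macro["acc"],
                         "pr": macro["pr"], "re": macro["re"],
                         "f1": macro["f1"], "error": ""})
        except Exception as exc:  # noqa: BLE001 - isolate per-variant failures
            logger.exception("variant %s failed", variant)
            rows.append({"variant": variant, "acc": np.nan, "pr": np.nan,
                         "re": np.nan, "f1": np.nan, "error": str(exc)})
    frame = pd.DataFrame(rows, columns=["variant", "acc", "pr", "re", "f1",
                                        "error"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "ablation.csv", index=False)
    return frame
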