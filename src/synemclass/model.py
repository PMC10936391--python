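"""Patch classifiers and the two-phase transfer-training schedule.

Both tasks — synapse vs non-synapse detection and excitatory vs inhibitory
valence prediction — share one binary-classifier contract: a convolutional
body producing a spatial feature map, global average pooling, and a
*bias-free* linear head mapping pooled features to 2 logits.  The missing
bias is deliberate: it makes the class-activation identity exact (see
:mod:`synemclass.cam_analysis`).

Training runs in two sessions.  First the body is frozen and only the
randomly initialised head is fitted; the best head (by validation
accuracy, ties to the earliest epoch) seeds the second session, in which
every layer is unfrozen and fine-tuned at a lower learning rate.  The
final model is the checkpoint with the highest validation accuracy over
both sessions.

Class-index convention, enforced here and nowhere else:
0 = inhibitory / non-synapse, 1 = excitatory / synapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _nn
from .reconstruct_io import Patch

__all__ = [
    "LABEL_TO_INDEX", "INDEX_TO_LABEL", "ModelConfig", "TrainReport",
    "SmallCNN", "build_model", "train_two_phase", "predict_patch",
    "predict_patches", "patch_features", "parameter_checksum",
    "save_checkpoint", "load_checkpoint",
]

#: the one place where class indices are defined
LABEL_TO_INDEX = {"inhibitory": 0, "excitatory": 1,
                  "nonsynapse": 0, "synapse": 1}
INDEX_TO_LABEL = {"valence": {0: "inhibitory", 1: "excitatory"},
                  "detect": {0: "nonsynapse", 1: "synapse"}}


@dataclass
class ModelConfig:
    backbone: str = "small_cnn"
    n_classes: int = 2
    pretrained: bool = False
    input_size: int = 128          # 512 for the resnext50 path
    epochs_phase1: int = 100
    epochs_phase2: int = 200
    optimizer: str = "adam"        # adam | sgd
    lr_phase1: float = 1e-1
    lr_phase2: float = 3e-3
    momentum: float = 0.9          # sgd only
    batch_size: int = 8
    augment: bool = True           # horizontal/vertical flips only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("binary tasks only: n_classes must be 2")
        if self.epochs_phase1 < 1 or self.epochs_phase2 < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def head_in_features(self) -> int:
        # small_cnn: 32 learned channels + 1 constant (intercept) channel
        return {"resnext50": 2048, "small_cnn": 33}[self.backbone]


@dataclass
class TrainReport:
    history: pd.DataFrame          # epoch, phase, train_loss/acc, val_loss/acc
    best_epoch: int                # global epoch index of the selected model
    best_val_accuracy: float
    phase_boundary: int            # first epoch index of phase 2
    # body-parameter checksums at schedule milestones (freeze audit trail)
    body_checksum_start: float = 0.0
    body_checksum_phase1_end: float = 0.0
    body_checksum_end: float = 0.0


class SmallCNN:
    """Three strided convolutions -> 33-channel feature map -> GAP -> head.

    On a 128 x 128 input the feature map is 33 x 8 x 8 (32 learned
    channels plus one constant-one channel); any input size divisible by
    16 works.  The constant channel lets the strictly bias-free head
    express an intercept — its weight on that channel is a spatially
    uniform offset — so the class-activation identity stays exact while
    the classifier keeps the capacity of an ordinary logistic head.
    """

    backbone = "small_cnn"
    n_learned_channels = 32

    def __init__(self, rng: np.random.Generator, n_classes: int = 2):
        self.body = _nn.Sequential(
            _nn.Conv2d(1, 8, 7, stride=4, pad=3, rng=rng),
            _nn.ReLU(),
            _nn.Conv2d(8, 16, 3, stride=2, pad=1, rng=rng),
            _nn.ReLU(),
            _nn.Conv2d(16, 32, 3, stride=2, pad=1, rng=rng),
            _nn.ReLU(),
        )
        self.head = _nn.Linear(33, n_classes, rng=rng, bias=False)

    # -- forward passes -------------------------------------------------
    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-GAP spatial feature map, shape (N, 33, H', W')."""
        f = self.body.forward(x, train=train)
        ones = np.ones((f.shape[0], 1) + f.shape[2:], dtype=f.dtype)
        return np.concatenate([f, ones], axis=1)

    def gap_features(self, x: np.ndarray) -> np.ndarray:
        return _nn.global_avg_pool(self.features(x))

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.features(x, train=train)
        self._spatial = f.shape[2:]
        return self.head.forward(_nn.global_avg_pool(f), train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dgap = self.head.backward(dlogits)
        # the constant channel has no upstream parameters: drop its grad
        dgap = dgap[:, : self.n_learned_channels]
        self.body.backward(_nn.gap_backward(dgap, self._spatial))

    # -- parameter access ------------------------------------------------
    @property
    def body_params(self):
        return self.body.params

    @property
    def head_params(self):
        return self.head.params

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.body.params + self.head.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.body.params + self.head.params, state):
            p[:] = s


def build_model(cfg: ModelConfig):
    """Construct the configured backbone.

    ``resnext50`` follows the full-scale recipe (ImageNet-pretrained
    ResNeXt-50 with its classifier replaced by a bias-free 2048 -> 2
    linear head) and requires the optional ``torch``/``torchvision``
    extra; ``small_cnn`` is the self-contained CPU backbone used
    throughout the tests.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.backbone == "small_cnn":
        return SmallCNN(rng, n_classes=cfg.n_classes)
    if cfg.backbone == "resnext50":
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the resnext50 backbone requires the optional torch extra "
                "(pip install synemclass[torch]); use backbone='small_cnn' "
                "for the pure-numpy path"
            ) from exc
        raise NotImplementedError(
            "torch backend detected but the resnext50 wrapper is not "
            "bundled in this build"
        )
    raise ValueError(f"unknown backbone {cfg.backbone!r}")


# ---------------------------------------------------------------- data prep

def patches_to_array(patches: list[Patch], input_size: int) -> np.ndarray:
    """Stack patches into (N, 1, S, S), resizing and standardising.

    Grayscale intensities are expected in [0, 1] and are standardised with
    the fixed affine (x - 0.5) / 0.25 so train and test share one scale.
    """
    from skimage.transform import resize

    imgs = []
    for p in patches:
        img = np.asarray(p.image, dtype=np.float64)
        if img.ndim != 2 or img.shape[0] != img.shape[1]:
            raise ValueError(f"expected square 2-D patch, got {img.shape}")
        if img.shape[0] != input_size:
            img = resize(img, (input_size, input_size), anti_aliasing=True)
        imgs.append((img - 0.5) / 0.25)
    return np.stack(imgs)[:, None, :, :]


def labels_to_array(patches: list[Patch]) -> np.ndarray:
    try:
        return np.array([LABEL_TO_INDEX[p.label] for p in patches])
    except KeyError as exc:
        raise ValueError(f"patch label {exc} has no class index") from exc


def parameter_checksum(params: list[np.ndarray]) -> float:
    """Order-sensitive checksum for freeze-contract assertions."""
    return float(sum((i + 1) * float(np.sum(p)) + float(np.sum(p * p))
                     for i, p in enumerate(params)))


# ---------------------------------------------------------------- training

def _make_opt(cfg, params, grads, lr):
    if cfg.optimizer == "adam":
        return _nn.Adam(params, grads, lr=lr)
    if cfg.optimizer == "sgd":
        return _nn.SGD(params, grads, lr=lr, momentum=cfg.momentum)
    raise ValueError(f"unknown optimizer {cfg.optimizer!r}")


def _augment(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    x = x.copy()
    flip_lr = rng.random(len(x)) < 0.5
    flip_ud = rng.random(len(x)) < 0.5
    x[flip_lr] = x[flip_lr, :, :, ::-1]
    x[flip_ud] = x[flip_ud, :, ::-1, :]
    return x


def _evaluate(model, x, y, batch_size=32) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        logits = model.logits(x[i : i + batch_size])
        loss, _ = _nn.cross_entropy_grad(logits, y[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_two_phase(
    model,
    train_patches: list[Patch],
    val_patches: list[Patch],
    cfg: ModelConfig,
) -> TrainReport:
    """Freeze/unfreeze transfer schedule; leaves ``model`` at the best
    checkpoint (max validation accuracy, earliest epoch on ties)."""
    if not train_patches or not val_patches:
        raise ValueError("train and validation splits must be non-empty")
    xtr = patches_to_array(train_patches, cfg.input_size)
    ytr = labels_to_array(train_patches)
    xva = patches_to_array(val_patches, cfg.input_size)
    yva = labels_to_array(val_patches)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rows = []
    best = {"acc": -1.0, "epoch": -1, "state": model.state()}

    def run_epoch(epoch, phase, opt, head_only):
        order = rng.permutation(len(xtr))
        losses, correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = _augment(xtr[idx], rng) if cfg.augment else xtr[idx]
            yb = ytr[idx]
            if head_only:
                # frozen body: no backward pass through it is ever taken
                feats = _nn.global_avg_pool(model.features(xb))
                logits = model.head.forward(feats, train=True)
                loss, dlog = _nn.cross_entropy_grad(logits, yb)
                model.head.backward(dlog)
            else:
                logits = model.logits(xb, train=True)
                loss, dlog = _nn.cross_entropy_grad(logits, yb)
                model.backward(dlog)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _evaluate(model, xva, yva)
        rows.append(dict(epoch=epoch, phase=phase,
                         train_loss=float(np.sum(losses) / len(xtr)),
                         train_acc=correct / len(xtr),
                         val_loss=val_loss, val_acc=val_acc))
        if val_acc > best["acc"]:
            best.update(acc=val_acc, epoch=epoch, state=model.state())

    body_checksum_start = parameter_checksum(model.body_params)
    opt1 = _make_opt(cfg, model.head_params, model.head.grads, cfg.lr_phase1)
    for e in range(cfg.epochs_phase1):
        run_epoch(e, 1, opt1, head_only=True)

    body_checksum_phase1_end = parameter_checksum(model.body_params)

    # phase 2 starts from the phase-1 best checkpoint
    model.load_state(best["state"])
    opt2 = _make_opt(cfg, model.body_params + model.head_params,
                     model.body.grads + model.head.grads, cfg.lr_phase2)
    for e in range(cfg.epochs_phase1, cfg.epochs_phase1 + cfg.epochs_phase2):
        run_epoch(e, 2, opt2, head_only=False)

    body_checksum_end = parameter_checksum(model.body_params)
    model.load_state(best["state"])
    return TrainReport(
        history=pd.DataFrame(rows),
        best_epoch=best["epoch"],
        best_val_accuracy=best["acc"],
        phase_boundary=cfg.epochs_phase1,
        body_checksum_start=body_checksum_start,
        body_checksum_phase1_end=body_checksum_phase1_end,
        body_checksum_end=body_checksum_end,
    )


# ---------------------------------------------------------------- inference

def predict_patches(model, patches: list[Patch], input_size: int,
                    batch_size: int = 32) -> np.ndarray:
    """Class probabilities, shape (N, 2), rows summing to 1."""
    x = patches_to_array(patches, input_size)
    out = []
    for i in range(0, len(x), batch_size):
        out.append(_nn.softmax(model.logits(x[i : i + batch_size])))
    return np.concatenate(out)


def predict_patch(model, patch: Patch, input_size: int = 128) -> np.ndarray:
    return predict_patches(model, [patch], input_size)[0]


def patch_features(model, patches: list[Patch], input_size: int,
                   batch_size: int = 32) -> np.ndarray:
    """Penultimate (post-GAP) features, shape (N, head_in_features)."""
    x = patches_to_array(patches, input_size)
    return np.concatenate([model.gap_features(x[i : i + batch_size])
                           for i in range(0, len(x), batch_size)])


def save_checkpoint(model, path) -> None:
    np.savez(path, *(model.state()), backbone=model.backbone)


def load_checkpoint(path, cfg: ModelConfig):
    data = np.load(path, allow_pickle=False)
    model = build_model(cfg)
    state = [data[f"arr_{i}"] for i in range(len(model.state()))]
    model.load_state(state)
    return model
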