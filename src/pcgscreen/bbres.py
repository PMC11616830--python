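"""Binary Bayesian ResNet window classifier.

A residual CNN maps one log-mel window to a murmur (or outcome) logit.  The
Bayesian variant keeps in-block dropout active at inference and runs T
stochastic forward passes; the mean of the positive-class probabilities is the
point prediction and their standard deviation the Monte-Carlo uncertainty.
With ``dropout_rate = 0`` (or MC inference off) the model degenerates exactly
to the deterministic baseline ResNet.

Training uses class-weightable binary cross-entropy and Adam, with the best
checkpoint selected on validation loss.  Batches, dropout masks and weight
initialisation are all driven by the config seed, so runs are reproducible
bit-for-bit on fixed hardware.  Window labels are inherited from the patient
(default binary target: Present or Unknown murmur = positive), and train /
validation patients must be disjoint — leakage raises.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io_formats import ValidationError
from .nn import Adam, Context, ResNet, bce_with_logits, make_resnet, sigmoid


@dataclass
class BBResConfig:
    """Model and training configuration.

    The optimiser, learning rate, epoch count, dropout rate and MC pass count
    are package defaults, not canonical values; they are configurable and
    recorded in every checkpoint.
    """

    backbone: str = "resnet18_lite"
    dropout_rate: float = 0.2
    dropout_in_blocks: bool = True
    mc_passes: int = 20
    pretrained_init: bool = False
    weights_path: str | None = None
    in_channels: int = 1
    input_pool: tuple[int, int] | None = None
    lite_width: int = 8
    lr: float = 3e-3
    epochs: int = 8
    batch_size: int = 64
    weight_decay: float = 1e-4
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.mc_passes < 1:
            raise ValidationError("mc_passes must be >= 1")


@dataclass
class WindowPrediction:
    """Per-window MC summary with provenance."""

    p_mean: float
    p_std: float
    patient_id: str
    recording_index: int
    offset_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mean <= 1.0 or self.p_std < 0:
            raise ValidationError("invalid window prediction")


def build_bbres(config: BBResConfig) -> ResNet:
    """Construct the window classifier for a config.

    With ``pretrained_init`` the weights are loaded from ``weights_path`` (a
    ``state_dict`` NPZ); without one the network keeps its He/random
    initialisation.
    """
    model = make_resnet(
        config.backbone,
        in_channels=config.in_channels,
        input_pool=config.input_pool,
        dropout_rate=config.dropout_rate,
        dropout_in_blocks=config.dropout_in_blocks,
        lite_width=config.lite_width,
        seed=config.seed,
    )
    if config.pretrained_init:
        if not config.weights_path:
            raise ValidationError(
                "pretrained_init requires weights_path pointing at a state-dict NPZ"
            )
        with np.load(config.weights_path) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
    return model


def _as_batch(windows: np.ndarray, in_channels: int) -> np.ndarray:
    """(N, H, W) -> (N, C, H, W), tiling channels when the stem expects more."""
    x = np.asarray(windows, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    if x.shape[1] == 1 and in_channels > 1:
        x = np.repeat(x, in_channels, axis=1)
    if x.shape[1] != in_channels:
        raise ValidationError(
            f"expected {in_channels} input channels, got {x.shape[1]}"
        )
    return x


def train_bbres(
    model: ResNet,
    windows: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    config: BBResConfig,
    val_patients: set[str] | frozenset[str],
) -> tuple[ResNet, dict]:
    """Train the window classifier; returns ``(model, history)``.

    ``windows`` is (N, H, W); ``labels`` the binary window targets inherited
    from each window's patient; ``groups`` the patient id per window.
    ``val_patients`` selects the validation split at patient granularity —
    validation patients must not appear in the training portion.
    """
    labels = np.asarray(labels, dtype=np.float64)
    groups = np.asarray(groups)
    if windows.shape[0] != labels.size or labels.size != groups.size:
        raise ValidationError("windows, labels and groups must align")
    val_mask = np.isin(groups, list(val_patients))
    train_mask = ~val_mask
    train_patients = set(groups[train_mask])
    overlap = train_patients & set(val_patients)
    if overlap:
        raise ValidationError(f"patient leakage between train and val: {sorted(overlap)[:5]}")
    if train_mask.sum() == 0 or val_mask.sum() == 0:
        raise ValidationError("empty train or validation split")
    y_tr = labels[train_mask]
    if len(np.unique(y_tr)) < 2:
        raise ValidationError("training windows contain a single class")

    x_tr = _as_batch(windows[train_mask], config.in_channels)
    x_va = _as_batch(windows[val_mask], config.in_channels)
    y_va = labels[val_mask]

    if config.class_weighting:
        pos = y_tr.mean()
        w_tr = np.where(y_tr == 1, 0.5 / max(pos, 1e-9), 0.5 / max(1 - pos, 1e-9))
    else:
        w_tr = None

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    history: dict = {"train_loss": [], "val_loss": [], "config": asdict(config)}
    best_val = np.inf
    best_state = model.state_dict()

    n = x_tr.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            ctx = Context(training=True, rng=rng)
            logits = model.forward(x_tr[idx], ctx)
            loss, dlogits = bce_with_logits(
                logits, y_tr[idx], None if w_tr is None else w_tr[idx]
            )
            opt.zero_grad()
            model.backward(dlogits.astype(np.float32))
            opt.step()
            epoch_loss += loss * idx.size
        history["train_loss"].append(epoch_loss / n)

        val_logits = _forward_in_batches(model, x_va, Context(training=False))
        val_loss, _ = bce_with_logits(val_logits, y_va)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    history["best_val_loss"] = float(best_val)
    return model, history


def _forward_in_batches(
    model: ResNet, x: np.ndarray, ctx: Context, batch: int = 256
) -> np.ndarray:
    outs = [model.forward(x[i : i + batch], ctx) for i in range(0, x.shape[0], batch)]
    return np.concatenate(outs)


def predict_window_mc(
    model: ResNet,
    windows: np.ndarray,
    T: int,
    rng: np.random.Generator | None = None,
    *,
    in_channels: int = 1,
    mc_dropout: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo prediction for a stack of windows.

    Runs ``T`` forward passes with dropout active (batch norm in eval mode) and
    returns ``(p_mean, p_std)`` over the positive-class probabilities.  When the
    model has no active dropout — rate 0, MC mode off, or ``T = 1`` — all passes
    coincide and the std is exactly zero.
    """
    if T < 1:
        raise ValidationError("T must be >= 1")
    x = _as_batch(windows, in_channels)
    has_dropout = mc_dropout and any(d.rate > 0 for d in model.dropout_modules())
    if not has_dropout or T == 1:
        probs = sigmoid(_forward_in_batches(model, x, Context(training=False)))
        return probs, np.zeros_like(probs)
    rng = rng or np.random.default_rng(0)
    passes = np.empty((T, x.shape[0]), dtype=np.float64)
    for t in range(T):
        ctx = Context(training=False, mc_dropout=True, rng=rng)
        passes[t] = sigmoid(_forward_in_batches(model, x, ctx))
    return passes.mean(axis=0), passes.std(axis=0)


def save_checkpoint(model: ResNet, config: BBResConfig, path: str | Path) -> None:
    """Persist weights (NPZ) plus the config/seed as sidecar JSON."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    cfg = asdict(config)
    cfg["n_parameters"] = model.n_parameters()
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path: str | Path) -> tuple[ResNet, BBResConfig]:
    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(".json").read_text())
    cfg_raw.pop("n_parameters", None)
    if cfg_raw.get("input_pool") is not None:
        cfg_raw["input_pool"] = tuple(cfg_raw["input_pool"])
    config = BBResConfig(**cfg_raw)
    model = make_resnet(
        config.backbone,
        in_channels=config.in_channels,
        input_pool=config.input_pool,
        dropout_rate=config.dropout_rate,
        dropout_in_blocks=config.dropout_in_blocks,
        lite_width=config.lite_width,
        seed=config.seed,
    )
    with np.load(path.with_suffix(".npz")) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model, config
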