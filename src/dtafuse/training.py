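"""Training loop: Adam on mean-squared-error with best-validation checkpointing.

The benchmark configuration trains for 600 epochs at learning rate 1e-4
with batch size 512/1024; the desk-scale synthetic preset uses far smaller
budgets.  Each epoch logs train and validation MSE; the returned model
carries the weights of the epoch with the lowest validation MSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .metrics import EvaluationReport, evaluate_predictions
from .model import Batch, DTAModel, PreparedRecord, collate
from .nn import Adam

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 600
    learning_rate: float = 1e-4
    batch_size: int = 512
    seed: int = 0
    log_every: int = 10

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch size >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_mse) + 1),
            "train_mse": self.train_mse,
            "val_mse": [v if v is not None else np.nan for v in self.val_mse],
        })


def _epoch_loss(model: DTAModel, prepared, indices, batch_size, optimizer, rng) -> float:
    order = rng.permutation(indices)
    total, count = 0.0, 0
    for start in range(0, len(order), batch_size):
        batch = collate(prepared, order[start: start + batch_size])
        out = model(batch)
        err = out.affinity - ag.Tensor(batch.labels)
        loss = (err ** 2).mean()
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                "non-finite training loss; inspect learning rate "
                f"({optimizer.lr}) and initialisation seed"
            )
        model.zero_grad()
        loss.backward()
        optimizer.step()
        total += float(loss.data) * batch.size
        count += batch.size
    return total / count


def train(model: DTAModel, prepared: list[PreparedRecord], train_idx, val_idx,
          config: TrainConfig) -> tuple[DTAModel, TrainHistory]:
    """Minimise MSE with Adam; return the best-validation checkpoint."""
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise ValueError("empty training set")
    val_idx = np.asarray(val_idx) if val_idx is not None else np.array([], dtype=int)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_state, best_val = None, np.inf
    model.train()
    for epoch in range(1, config.epochs + 1):
        train_mse = _epoch_loss(model, prepared, train_idx, config.batch_size,
                                optimizer, rng)
        history.train_mse.append(train_mse)
        if val_idx.size:
            preds = model.predict([prepared[i] for i in val_idx])
            val_mse = float(np.mean((preds - [prepared[i].affinity for i in val_idx]) ** 2))
            model.train()
            history.val_mse.append(val_mse)
            if val_mse < best_val:
                best_val = val_mse
                best_state = model.state_dict()
                history.best_epoch = epoch
        else:
            history.val_mse.append(None)
        if epoch % config.log_every == 0 or epoch == 1:
            logger.info("epoch %d: train MSE %.4f val MSE %s", epoch, train_mse,
                        f"{history.val_mse[-1]:.4f}" if history.val_mse[-1] is not None else "-")
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def evaluate_model(model: DTAModel, prepared: list[PreparedRecord], indices) -> EvaluationReport:
    indices = np.asarray(indices)
    preds = model.predict([prepared[i] for i in indices])
    labels = np.asarray([prepared[i].affinity for i in indices])
    return evaluate_predictions(preds, labels)


def save_checkpoint(model: DTAModel, path):
    """Write model weights plus config to an .npz checkpoint."""
    state = model.state_dict()
    import json

    np.savez(path, __config__=json.dumps(model.config.to_dict()), **state)


def load_checkpoint(path) -> DTAModel:
    from .model import ModelConfig
    import json

    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = DTAModel(config)
    model.load_state_dict(state)
    model.eval()
    return model
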