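"""Joint end-to-end training of the dual-branch network.

The loss is a weighted sum of two mean-squared errors: one on predicted
vs. realized cell-type proportions and one on predicted vs. ground-truth
per-type expression profiles.  Because log2-space GEP errors are orders of
magnitude larger than proportion errors, the proportion term carries a large
default weight so that both branches learn jointly.  GEP columns of cell
types absent from a pseudobulk sample carry no supervision signal and are
masked out of the loss.
"""

from __future__ import annotations


import logging
from dataclasses import dataclass

import numpy as np

from .model import DeconvolutionModel
from . import nn

log = logging.getLogger(__name__)

__all__ = ["TrainConfig", "loss", "loss_and_grads", "train"]


@dataclass
class TrainConfig:
    lambda_p: float = 3000.0
    lambda_G: float = 1.0
    learning_rate: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 30
    early_stop_patience: int = 5
    init_output_bias: bool = True  # seed GEP bias with the training-mean profile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_p < 0 or self.lambda_G < 0 or self.lambda_p + self.lambda_G == 0:
            raise ValueError("loss weights must be non-negative and not both zero")


def loss(p_hat, p, G_hat, G, mask, lambda_p: float = 3000.0, lambda_G: float = 1.0) -> float:
    """Weighted two-term MSE; absent-type GEP columns are excluded via mask."""
    val, _, _ = loss_and_grads(p_hat, p, G_hat, G, mask, lambda_p, lambda_G, need_grads=False)
    return val


def loss_and_grads(p_hat, p, G_hat, G, mask, lambda_p, lambda_G, need_grads=True):
    """Return (loss, dL/dp_hat, dL/dG_hat).

    ``p_hat, p``: (B, c); ``G_hat, G``: (B, g, c); ``mask``: (B, c) booleans
    flagging cell types actually present in each pseudobulk sample.
    """
    p_hat = np.asarray(p_hat)
    if p_hat.shape != np.shape(p):
        raise ValueError(f"proportion shapes disagree: {p_hat.shape} vs {np.shape(p)}")
    if np.shape(G_hat) != np.shape(G):
        raise ValueError(f"GEP shapes disagree: {np.shape(G_hat)} vs {np.shape(G)}")
    dp = p_hat - p
    p_term = float(np.mean(dp * dp))

    mask = np.asarray(mask, dtype=bool)
    g = G_hat.shape[1]
    n_masked = int(mask.sum()) * g
    dG = (G_hat - G) * mask[:, None, :]
    if n_masked > 0:
        g_term = float(np.sum(dG * dG)) / n_masked
    else:
        g_term = 0.0
    total = lambda_p * p_term + lambda_G * g_term
    if not need_grads:
        return total, None, None
    gp = (2.0 * lambda_p / dp.size) * dp
    gG = (2.0 * lambda_G / max(n_masked, 1)) * dG
    return total, gp, gG


def _epoch_loss(model, data, cfg: TrainConfig) -> float:
    tot, n = 0.0, 0
    for i in range(0, data["x"].shape[0], cfg.batch_size):
        sl = slice(i, i + cfg.batch_size)
        p_hat, G_hat = model.forward(data["x"][sl], train=False)
        v = loss(p_hat, data["p"][sl], G_hat, data["G"][sl], data["mask"][sl],
                 cfg.lambda_p, cfg.lambda_G)
        b = data["x"][sl].shape[0]
        tot += v * b
        n += b
    return tot / n


def _as_arrays(pbset) -> dict[str, np.ndarray]:
    """Accept either a PseudobulkSet or a dict of arrays."""
    if isinstance(pbset, dict):
        return pbset
    return {
        "x": np.asarray(pbset.b_input, dtype=np.float32),
        "p": np.asarray(pbset.p_target, dtype=np.float32),
        "G": np.asarray(pbset.G_target, dtype=np.float32),
        "mask": np.asarray(pbset.type_mask, dtype=bool),
    }


def train(model: DeconvolutionModel, train_set, val_set, config: TrainConfig,
          callback=None):
    """Adam optimization of both branches; returns (model, history).

    The best-validation parameters are restored before returning.  Training
    aborts with a diagnostic if the loss becomes non-finite.  ``callback``,
    if given, is invoked as ``callback(epoch, model)`` after each epoch.
    """
    tr = _as_arrays(train_set)
    va = _as_arrays(val_set)
    rng = np.random.default_rng(config.seed)
    if config.init_output_bias:
        mask = tr["mask"][:, None, :]
        mean_profile = (tr["G"] * mask).sum(axis=(0, 2)) / np.maximum(mask.sum(axis=(0, 2)), 1)
        model.initialize_output_bias(mean_profile)
    opt = nn.FlatAdam(model.layers, lr=config.learning_rate)
    n = tr["x"].shape[0]
    history: list[dict] = []
    best_val = np.inf
    best_state = None
    patience = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        running, seen = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            p_hat, G_hat = model.forward(tr["x"][idx], train=True)
            lval, gp, gG = loss_and_grads(
                p_hat, tr["p"][idx], G_hat, tr["G"][idx], tr["mask"][idx],
                config.lambda_p, config.lambda_G)
            if not np.isfinite(lval):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={lval!r}")
            model.backward(gp, gG)
            opt.step(model.gradients())
            running += lval * len(idx)
            seen += len(idx)
        train_loss = running / seen
        val_loss = _epoch_loss(model, va, config)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        log.info("epoch %d: train %.5f val %.5f", epoch, train_loss, val_loss)
        if callback is not None:
            callback(epoch, model)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            patience = 0
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                log.info("early stop at epoch %d (best val %.5f)", epoch, best_val)
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
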