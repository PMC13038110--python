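"""Dual-branch deconvolution network.

A bulk expression vector (``g`` genes, log2 CPM space) is lifted by a shared
linear layer into a ``feature_dim``-long feature vector.  Two heads consume
the shared features:

* a 5-layer MLP with SiLU activations and a terminal softmax predicts the
  cell-type proportion vector ``p`` on the simplex;
* a 1-D U-Net (4 down blocks that double channels and halve length, 4 up
  blocks that do the opposite, with skip concatenation) predicts the
  per-cell-type expression profiles ``G``; the channel axis of its output
  indexes cell types, and a per-channel linear map followed by ReLU projects
  the length-``feature_dim`` sequence back onto the ``g`` genes.

The network is implemented on top of the NumPy layers in :mod:`duodecon.nn`
with explicit forward/backward passes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = ["ModelConfig", "DeconvolutionModel", "DeconvolutionResult", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    n_genes: int
    n_types: int
    feature_dim: int = 4096
    mlp_dims: tuple[int, ...] | None = None  # defaults to (4096, 1024, 256, 64, n_types)
    unet_depth: int = 4
    base_channels: int = 8
    kernel_size: int = 3
    proportion_activation: str = "softmax"  # or "none"
    gep_activation: str = "relu"            # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mlp_dims is None:
            self.mlp_dims = (4096, 1024, 256, 64, self.n_types)
        self.mlp_dims = tuple(self.mlp_dims)
        if self.n_genes < 1 or self.n_types < 1:
            raise ValueError("n_genes and n_types must be positive")
        if self.feature_dim % (2 ** self.unet_depth) != 0:
            raise ValueError(
                f"feature_dim={self.feature_dim} must be divisible by 2^unet_depth={2**self.unet_depth}"
            )
        if self.mlp_dims[-1] != self.n_types:
            raise ValueError("final MLP width must equal the number of cell types")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")


@dataclass
class DeconvolutionResult:
    """Predictions for one sample: proportions on the simplex and a g x c GEP."""

    p_hat: np.ndarray
    G_hat: np.ndarray


class DeconvolutionModel:
    """The dual-branch network with explicit backpropagation."""

    def __init__(self, config: ModelConfig, dtype=np.float32) -> None:
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        c, g, fdim = config.n_types, config.n_genes, config.feature_dim
        bc, k, depth = config.base_channels, config.kernel_size, config.unet_depth

        L: dict[str, nn.Layer] = {}
        L["fc_in"] = nn.Linear(g, fdim, rng, dtype)

        # proportion head
        self.mlp_chain: list[str] = []
        widths = (fdim,) + config.mlp_dims
        for i in range(len(config.mlp_dims)):
            L[f"mlp{i}"] = nn.Linear(widths[i], widths[i + 1], rng, dtype)
            self.mlp_chain.append(f"mlp{i}")
            if i < len(config.mlp_dims) - 1:
                L[f"mlp{i}_act"] = nn.SiLU()
                self.mlp_chain.append(f"mlp{i}_act")
        if config.proportion_activation == "softmax":
            L["p_out"] = nn.Softmax()
            self.mlp_chain.append("p_out")
        elif config.proportion_activation != "none":
            raise ValueError(f"unknown proportion_activation {config.proportion_activation!r}")

        # U-Net stem
        L["stem_conv"] = nn.Conv1d(1, bc, k, rng, dtype)
        L["stem_bn"] = nn.BatchNorm1d(bc, dtype)
        L["stem_act"] = nn.ReLU()

        # down path: pool, then two (conv, bn, relu) rounds; channels double
        ch = bc
        for d in range(depth):
            L[f"down{d}_pool"] = nn.MaxPool1d()
            L[f"down{d}_conv0"] = nn.Conv1d(ch, 2 * ch, k, rng, dtype)
            L[f"down{d}_bn0"] = nn.BatchNorm1d(2 * ch, dtype)
            L[f"down{d}_act0"] = nn.ReLU()
            L[f"down{d}_conv1"] = nn.Conv1d(2 * ch, 2 * ch, k, rng, dtype)
            L[f"down{d}_bn1"] = nn.BatchNorm1d(2 * ch, dtype)
            L[f"down{d}_act1"] = nn.ReLU()
            ch *= 2

        # up path: transposed conv halves channels/doubles length, skip concat
        for u in range(depth):
            L[f"up{u}_tconv"] = nn.ConvTranspose1d(ch, ch // 2, rng, dtype)
            L[f"up{u}_conv0"] = nn.Conv1d(ch, ch // 2, k, rng, dtype)  # input = concat(skip, up)
            L[f"up{u}_bn0"] = nn.BatchNorm1d(ch // 2, dtype)
            L[f"up{u}_act0"] = nn.ReLU()
            L[f"up{u}_conv1"] = nn.Conv1d(ch // 2, ch // 2, k, rng, dtype)
            L[f"up{u}_bn1"] = nn.BatchNorm1d(ch // 2, dtype)
            L[f"up{u}_act1"] = nn.ReLU()
            ch //= 2

        L["head_conv"] = nn.Conv1d(bc, c, k, rng, dtype)
        L["out_proj"] = nn.Linear(fdim, g, rng, dtype)
        if config.gep_activation == "relu":
            L["g_out"] = nn.ReLU()
        elif config.gep_activation != "none":
            raise ValueError(f"unknown gep_activation {config.gep_activation!r}")
        self.layers = L

    # ------------------------------------------------------------------ utils
    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers.values())

    def parameters(self) -> dict[str, np.ndarray]:
        return nn.collect_params(self.layers)

    def gradients(self) -> dict[str, np.ndarray]:
        return nn.collect_grads(self.layers)

    # ---------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(p_hat, G_hat)`` with shapes ``(B, c)`` and ``(B, g, c)``."""
        cfg = self.config
        if x.ndim != 2 or x.shape[1] != cfg.n_genes:
            raise ValueError(
                f"expected input with {cfg.n_genes} genes, received shape {x.shape}"
            )
        L = self.layers
        x = np.asarray(x, dtype=self.dtype)
        f = L["fc_in"].forward(x, train)

        h = f
        for name in self.mlp_chain:
            h = L[name].forward(h, train)
        p_hat = h

        z = f[:, :, None]  # (B, length=feature_dim, channels=1)
        z = L["stem_act"].forward(L["stem_bn"].forward(L["stem_conv"].forward(z, train), train), train)
        skips = []
        for d in range(cfg.unet_depth):
            skips.append(z)
            z = L[f"down{d}_pool"].forward(z, train)
            z = L[f"down{d}_act0"].forward(L[f"down{d}_bn0"].forward(L[f"down{d}_conv0"].forward(z, train), train), train)
            z = L[f"down{d}_act1"].forward(L[f"down{d}_bn1"].forward(L[f"down{d}_conv1"].forward(z, train), train), train)
        for u in range(cfg.unet_depth):
            z = L[f"up{u}_tconv"].forward(z, train)
            skip = skips[cfg.unet_depth - 1 - u]
            z = np.concatenate([skip, z], axis=2)
            z = L[f"up{u}_act0"].forward(L[f"up{u}_bn0"].forward(L[f"up{u}_conv0"].forward(z, train), train), train)
            z = L[f"up{u}_act1"].forward(L[f"up{u}_bn1"].forward(L[f"up{u}_conv1"].forward(z, train), train), train)
        z = L["head_conv"].forward(z, train)                      # (B, fdim, c)
        b = z.shape[0]
        z = np.ascontiguousarray(z.transpose(0, 2, 1))            # (B, c, fdim)
        gmat = L["out_proj"].forward(z.reshape(b * cfg.n_types, cfg.feature_dim), train)
        if "g_out" in L:
            gmat = L["g_out"].forward(gmat, train)
        G_hat = gmat.reshape(b, cfg.n_types, cfg.n_genes).transpose(0, 2, 1)
        return p_hat, G_hat

    # --------------------------------------------------------------- backward
    def backward(self, gp: np.ndarray, gG: np.ndarray) -> None:
        """Backpropagate loss gradients through both heads into all parameters."""
        cfg = self.config
        L = self.layers
        b = gp.shape[0]

        h = gp.astype(self.dtype, copy=False)
        for name in reversed(self.mlp_chain):
            h = L[name].backward(h)
        gf_mlp = h

        gz = np.ascontiguousarray(gG.transpose(0, 2, 1)).reshape(b * cfg.n_types, cfg.n_genes)
        gz = gz.astype(self.dtype, copy=False)
        if "g_out" in L:
            gz = L["g_out"].backward(gz)
        gz = L["out_proj"].backward(gz).reshape(b, cfg.n_types, cfg.feature_dim)
        gz = np.ascontiguousarray(gz.transpose(0, 2, 1))          # (B, fdim, c)
        gz = L["head_conv"].backward(gz)

        skip_grads: list[np.ndarray | None] = [None] * cfg.unet_depth
        for u in reversed(range(cfg.unet_depth)):
            gz = L[f"up{u}_conv1"].backward(L[f"up{u}_bn1"].backward(L[f"up{u}_act1"].backward(gz)))
            gz = L[f"up{u}_conv0"].backward(L[f"up{u}_bn0"].backward(L[f"up{u}_act0"].backward(gz)))
            n_skip = gz.shape[2] // 2
            skip_grads[cfg.unet_depth - 1 - u] = np.ascontiguousarray(gz[:, :, :n_skip])
            gz = L[f"up{u}_tconv"].backward(np.ascontiguousarray(gz[:, :, n_skip:]))
        for d in reversed(range(cfg.unet_depth)):
            gz = L[f"down{d}_conv1"].backward(L[f"down{d}_bn1"].backward(L[f"down{d}_act1"].backward(gz)))
            gz = L[f"down{d}_conv0"].backward(L[f"down{d}_bn0"].backward(L[f"down{d}_act0"].backward(gz)))
            gz = L[f"down{d}_pool"].backward(gz)
            gz = gz + skip_grads[d]
        gz = L["stem_conv"].backward(L["stem_bn"].backward(L["stem_act"].backward(gz)))
        gf_unet = gz[:, :, 0]

        L["fc_in"].backward(gf_mlp + gf_unet)

    def initialize_output_bias(self, mean_profile: np.ndarray,
                               weight_scale: float = 0.1) -> None:
        """Seed the GEP head's final bias with a mean expression profile.

        Starting the output at the cohort-mean profile (a standard
        final-layer prior initialization) means the U-Net learns residual,
        sample-specific expression from the first step instead of spending
        most of the optimization on the static gene-level baseline.  The
        final projection's weights are shrunk by ``weight_scale`` so the
        initial prediction is the profile itself rather than the profile
        plus init noise.
        """
        if mean_profile.shape != (self.config.n_genes,):
            raise ValueError("mean profile must have one value per gene")
        self.layers["out_proj"].params["b"][...] = mean_profile.astype(self.dtype)
        self.layers["out_proj"].params["W"] *= weight_scale

    # -------------------------------------------------------------- inference
    def predict(self, x: np.ndarray, batch_size: int = 64) -> DeconvolutionResult:
        """Deconvolve one sample (1-D input) or a batch (2-D, samples in rows).

        Inference uses running batch-norm statistics, so each sample's output
        is independent of the rest of the batch.
        """
        single = x.ndim == 1
        xb = x[None, :] if single else x
        ps, gs = [], []
        for i in range(0, xb.shape[0], batch_size):
            p, G = self.forward(xb[i : i + batch_size], train=False)
            ps.append(p)
            gs.append(G)
        p_hat = np.concatenate(ps, axis=0)
        G_hat = np.concatenate(gs, axis=0)
        if single:
            return DeconvolutionResult(p_hat[0], G_hat[0])
        return DeconvolutionResult(p_hat, G_hat)

    # ------------------------------------------------------------- state dict
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.parameters().items()}
        for name, layer in self.layers.items():
            if isinstance(layer, nn.BatchNorm1d):
                state[f"{name}.running_mean"] = layer.running_mean.copy()
                state[f"{name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in params.items():
            v[...] = state[k]
        for name, layer in self.layers.items():
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[...] = state[f"{name}.running_mean"]
                layer.running_var[...] = state[f"{name}.running_var"]


def save_checkpoint(path, model: DeconvolutionModel, gene_ids=None, cell_types=None) -> None:
    """Write config, parameters, gene list, and cell-type order to one file.

    The stored cell-type order defines the column semantics of predicted GEPs.
    """
    meta = {
        "config": asdict(model.config),
        "gene_ids": list(gene_ids) if gene_ids is not None else None,
        "cell_types": list(cell_types) if cell_types is not None else None,
    }
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **model.state_dict())


def load_checkpoint(path) -> tuple[DeconvolutionModel, list[str] | None, list[str] | None]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = meta["config"]
    cfg["mlp_dims"] = tuple(cfg["mlp_dims"])
    model = DeconvolutionModel(ModelConfig(**cfg))
    model.load_state_dict(state)
    return model, meta["gene_ids"], meta["cell_types"]
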