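"""Multi-scale volumetric encoder-decoder with a CRF mean-field layer.

The architecture follows the V-net pattern — residual convolution blocks,
strided 2x2x2 convolutions instead of pooling, transposed convolutions on
the way up, skip connections between matching levels — with three additions:

* **Channel-sum residuals.**  Each block's convolution stack (5^3 "same"
  convolutions, each followed by dropout, channel layer-norm and ReLU) is
  summed over channels back to a single channel and added (with
  broadcasting) to the tensor passed into the block.  Inter-block tensors
  are therefore one or two channels wide; the capacity lives inside the
  blocks.
* **Multi-scale raw inputs.**  The raw input volume, average-pooled to each
  level's grid, is concatenated to the output of every downsampling
  convolution, so each encoder level sees the raw image at its own scale.
* **CRF recurrent layer.**  The output logits are refined by unrolled
  dense-CRF mean-field iterations whose appearance kernel is driven by the
  image intensity plus learned deep features tapped from the rear
  convolution of the first encoder level (transformed by a 5^3 convolution
  with layer-norm).

The reference configuration (``model_scale=16``, five levels, channel
schedule 16·(1,2,4,8,16), conv counts (1,2,3,3,3) down / (3,3,2,1) up) has
27,008,316 trainable parameters in the base variant; multi-scale inputs add
88,032 and the CRF layer adds 32,052.

The network operates at half the canonical resolution (2 mm when fed 1 mm
canonical volumes): the input is average-pooled by 2, and the output
probability maps are trilinearly upsampled back for export.
"""

from __future__ import annotations

import csv
import gc
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Adam, Parameter, Tensor, concat
from .dense_crf import Compatibility, KernelBank, VoxelFeatures, crf_inference
from .io_preprocess import AugmentSpec, augment_arrays
from .losses_metrics import LossConfig, composite_loss, soft_dice_loss

__all__ = [
    "NetworkConfig", "ModelGraph", "TrainConfig",
    "downsample_pyramid", "build_model", "count_parameters", "forward",
    "train", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The defaults are the calibrated reference configuration; tests and the
    phantom study shrink ``model_scale`` (and the CRF window) for CPU-scale
    runs without changing the architecture.
    """

    n_levels: int = 5
    model_scale: int = 16
    channels: tuple = None          # derived from model_scale when None
    conv_kernel: int = 5
    convs_per_level: tuple = (1, 2, 3, 3, 3)
    dropout_first: float = 0.2
    dropout_rest: float = 0.5
    input_spacing_mm: float = 2.0
    crf_iters: int = 20
    multi_scale: bool = True
    crf_enabled: bool = True
    crf_radius: int = 2             # mean-field filtering window truncation
    theta_alpha: float = 3.0
    theta_beta: float = 0.1
    theta_gamma: float = 3.0
    theta_delta: float = 1.0
    crf_w1: float = 1.0
    crf_w2: float = 1.0

    def resolved_channels(self) -> tuple:
        if self.channels is not None:
            ch = tuple(self.channels)
        else:
            ch = tuple(self.model_scale * 2 ** i for i in range(self.n_levels))
        if len(ch) != self.n_levels:
            raise ValueError("channel schedule length must equal n_levels")
        if any(b <= a for a, b in zip(ch, ch[1:])):
            raise ValueError("channels must be strictly increasing")
        return ch

    @property
    def variant(self) -> str:
        if self.multi_scale and self.crf_enabled:
            return "full"
        if self.multi_scale:
            return "multiscale"
        if self.crf_enabled:
            return "crf"
        return "base"

    def decoder_convs(self) -> tuple:
        return tuple(reversed(self.convs_per_level[:-1]))


def downsample_pyramid(volume: np.ndarray, n_levels: int):
    """Raw-input pyramid: level 0 is the input, each further level is
    average-pooled by 2 per axis."""
    v = np.asarray(volume, dtype=np.float64)
    squeeze = v.ndim == 3
    if squeeze:
        v = v[None]
    if any(s % 2 ** (n_levels - 1) for s in v.shape[1:]):
        raise ValueError(
            f"spatial dims {v.shape[1:]} not divisible by 2^{n_levels - 1}")
    levels = [v]
    for _ in range(n_levels - 1):
        c, x, y, z = levels[-1].shape
        levels.append(levels[-1].reshape(
            c, x // 2, 2, y // 2, 2, z // 2, 2).mean(axis=(2, 4, 6)))
    if squeeze:
        levels = [lv[0] for lv in levels]
    return levels


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

class ModelGraph:
    """A built network: named parameters plus the forward computation."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.variant = config.variant
        self.params: dict[str, Parameter] = {}
        self._rng = np.random.default_rng(seed)
        self._build()

    # -- parameter helpers -------------------------------------------------
    def _conv_param(self, name, cout, cin, k, std=None):
        # He fan-in by default; the classifier uses a deliberately small
        # scale because its input is a channel-sum residual of magnitude
        # O(sqrt(C)) — unit-scale init saturates the output softmax and
        # kills the gradient at the start of training.
        if std is None:
            std = np.sqrt(2.0 / (cin * k ** 3))
        self.params[f"{name}_w"] = Parameter(
            self._rng.normal(0.0, std, size=(cout, cin, k, k, k)))
        self.params[f"{name}_b"] = Parameter(np.zeros(cout))

    def _upconv_param(self, name, cin, cout):
        std = np.sqrt(2.0 / (cin * 8))
        self.params[f"{name}_w"] = Parameter(
            self._rng.normal(0.0, std, size=(cin, cout, 2, 2, 2)))
        self.params[f"{name}_b"] = Parameter(np.zeros(cout))

    def _ln_param(self, name, c):
        self.params[f"{name}_g"] = Parameter(np.ones(c))
        self.params[f"{name}_beta"] = Parameter(np.zeros(c))

    def _build(self):
        cfg = self.config
        ch = cfg.resolved_channels()
        k = cfg.conv_kernel
        n = cfg.n_levels
        ms = cfg.multi_scale
        enc = cfg.convs_per_level
        dec = cfg.decoder_convs()

        self._enc_in = []
        for i in range(n):
            cin = 1 if i == 0 else (2 if ms else 1)
            self._enc_in.append(cin)
            for j in range(enc[i]):
                self._conv_param(f"enc{i}_conv{j}", ch[i], cin, k)
                self._ln_param(f"enc{i}_ln{j}", ch[i])
                cin = ch[i]
            passed = 1 if i == 0 else (2 if ms else 1)
            if i < n - 1:
                self._conv_param(f"enc{i}_down", 1, passed, 2)
            else:
                self._upconv_param(f"enc{i}_up", passed, 1)

        self._dec_in = []
        for u, i in enumerate(range(n - 2, -1, -1)):
            skip = 1 if i == 0 else (2 if ms else 1)
            cin = skip + 1
            self._dec_in.append(cin)
            for j in range(dec[u]):
                self._conv_param(f"dec{i}_conv{j}", ch[i], cin, k)
                self._ln_param(f"dec{i}_ln{j}", ch[i])
                cin = ch[i]
            if i > 0:
                self._upconv_param(f"dec{i}_up", 1, 1)

        self._conv_param("cls", 2, 1, 1, std=0.01)

        if cfg.crf_enabled:
            self._conv_param("crf_feat", ch[0], ch[0], k)
            self._ln_param("crf_featln", ch[0])
            self.compat = Compatibility.potts(2, trainable=True)
            self.params["crf_mu"] = self.compat.mu
            self.bank = KernelBank.create(
                n_deep=ch[0], w1=cfg.crf_w1, w2=cfg.crf_w2,
                theta_alpha=cfg.theta_alpha, theta_beta=cfg.theta_beta,
                theta_gamma=cfg.theta_gamma, theta_delta=cfg.theta_delta,
                trainable=False)
        else:
            self.compat = None
            self.bank = None

    # -- inventory ---------------------------------------------------------
    def weight_inventory(self):
        """Deterministic (name, shape) list of trainable weights."""
        return [(k, tuple(p.data.shape)) for k, p in self.params.items()
                if p.requires_grad]

    # -- forward -----------------------------------------------------------
    def _conv_block(self, name, x, n_convs, drop, train, rng):
        p = self.params
        h = x
        for j in range(n_convs):
            h = ad.conv3d(h, p[f"{name}_conv{j}_w"], p[f"{name}_conv{j}_b"])
            if train and drop > 0:
                h = ad.dropout(h, drop, rng)
            h = ad.layer_norm(h, p[f"{name}_ln{j}_g"], p[f"{name}_ln{j}_beta"])
            h = h.relu()
        return h

    def _forward_net(self, net_input: np.ndarray, train: bool = False,
                     rng: np.random.Generator | None = None):
        """Run the network on its native-resolution input (X, Y, Z).

        Returns a dict with logits U, pre-CRF z, post-CRF y (all Tensors at
        network resolution).
        """
        cfg = self.config
        n = cfg.n_levels
        enc = cfg.convs_per_level
        dec = cfg.decoder_convs()
        p = self.params
        if rng is None:
            rng = np.random.default_rng(0)

        pyramid = downsample_pyramid(net_input[None], n)
        x = Tensor(pyramid[0])
        fwds = []
        tap = None
        for i in range(n):
            drop = cfg.dropout_first if i == 0 else cfg.dropout_rest
            h = self._conv_block(f"enc{i}", x, enc[i], drop, train, rng)
            if i == 0:
                tap = h
            fwd = h.sum(axis=0, keepdims=True) + x
            fwds.append(fwd)
            if i < n - 1:
                x = ad.down_conv3d(fwd, p[f"enc{i}_down_w"],
                                   p[f"enc{i}_down_b"]).relu()
                if cfg.multi_scale:
                    x = concat([x, Tensor(pyramid[i + 1])], axis=0)
            else:
                up = ad.up_conv3d(fwd, p[f"enc{i}_up_w"],
                                  p[f"enc{i}_up_b"]).relu()

        for u, i in enumerate(range(n - 2, -1, -1)):
            x = concat([fwds[i], up], axis=0)
            h = self._conv_block(f"dec{i}", x, dec[u], cfg.dropout_rest,
                                 train, rng)
            fwd = h.sum(axis=0, keepdims=True) + up
            if i > 0:
                up = ad.up_conv3d(fwd, p[f"dec{i}_up_w"],
                                  p[f"dec{i}_up_b"]).relu()

        U = ad.conv3d(fwd, p["cls_w"], p["cls_b"])
        z = U.softmax(axis=0)

        if cfg.crf_enabled:
            d = ad.conv3d(tap, p["crf_feat_w"], p["crf_feat_b"])
            d = ad.layer_norm(d, p["crf_featln_g"], p["crf_featln_beta"]).relu()
            features = VoxelFeatures.from_image(net_input, deep=d)
            y = crf_inference(U, features, self.bank, self.compat,
                              n_iter=cfg.crf_iters, radius=cfg.crf_radius,
                              normalize_messages=True)
        else:
            y = z
        return {"U": U, "z": z, "y": y}


def build_model(config: NetworkConfig, seed: int = 0) -> ModelGraph:
    """Assemble a network variant; validates the configuration."""
    config.resolved_channels()
    if len(config.convs_per_level) != config.n_levels:
        raise ValueError("convs_per_level length must equal n_levels")
    return ModelGraph(config, seed=seed)


def count_parameters(graph: ModelGraph) -> int:
    """Total element count of all trainable weights (deterministic)."""
    return int(sum(p.data.size for p in graph.params.values()
                   if p.requires_grad))


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

@dataclass
class PredictionPair:
    """Pre-CRF (z) and post-CRF (y) foreground probability maps."""

    z: np.ndarray
    y: np.ndarray


def _pool2(v: np.ndarray) -> np.ndarray:
    x, y, z = v.shape
    return v.reshape(x // 2, 2, y // 2, 2, z // 2, 2).mean(axis=(1, 3, 5))


def _upsample2(v: np.ndarray) -> np.ndarray:
    return ndimage.zoom(v, 2, order=1, mode="nearest", grid_mode=True)


def _check_input(volume: np.ndarray, cfg: NetworkConfig):
    s = volume.shape
    if len(s) != 3 or len(set(s)) != 1:
        raise ValueError(f"expected a cubic 3D volume, got shape {s}")
    need = 2 ** cfg.n_levels
    if s[0] % need:
        raise ValueError(
            f"volume side {s[0]} must be divisible by {need} "
            f"for a {cfg.n_levels}-level network")


def forward(graph: ModelGraph, volume) -> PredictionPair:
    """Deterministic evaluation-mode prediction.

    `volume` is a canonical-space intensity grid (values in [0, 1]); the
    network runs at half its resolution and the exported maps are upsampled
    back to the input grid.
    """
    vol = volume.voxels if hasattr(volume, "voxels") else np.asarray(volume)
    _check_input(vol, graph.config)
    out = graph._forward_net(_pool2(vol), train=False)
    z = _upsample2(out["z"].data[1])
    y = _upsample2(out["y"].data[1])
    del out
    gc.collect()   # break leftover graph cycles promptly
    return PredictionPair(z=z, y=y)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 30
    learning_rate: float = 0.01
    loss: LossConfig = field(default_factory=LossConfig)
    val_fraction: float = 0.1
    seed: int = 0
    augment: bool = True
    augment_spec: AugmentSpec = field(default_factory=AugmentSpec)
    early_stop_val_loss: float | None = None


def _net_res_mask(mask: np.ndarray) -> np.ndarray:
    return (_pool2(mask.astype(np.float64)) >= 0.5).astype(np.float64)


def train(graph: ModelGraph, dataset, config: TrainConfig):
    """Train a built graph on (image, mask) pairs.

    10% of the data (at least one sample) is held out for validation.  Each
    epoch applies exactly one randomly chosen augmentation to every training
    image and trains on the augmented images only.  Returns the per-epoch
    history as a list of dicts (epoch, train_loss, val_loss).
    """
    pairs = [(np.asarray(img, dtype=np.float64), np.asarray(msk))
             for img, msk in dataset]
    if not pairs:
        raise ValueError("empty training dataset")
    for img, _ in pairs:
        _check_input(img, graph.config)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(config.val_fraction * len(pairs)))) \
        if len(pairs) > 1 else 0
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = val_idx, train_idx

    opt = Adam(graph.params, lr=config.learning_rate)
    history = []
    for epoch in range(config.epochs):
        losses = []
        for idx in rng.permutation(train_idx):
            img, msk = pairs[idx]
            if config.augment:
                seed = int(rng.integers(2 ** 31))
                img, msk = augment_arrays(img, msk, config.augment_spec, seed)
            y_true = Tensor(_net_res_mask(msk))
            out = graph._forward_net(_pool2(img), train=True, rng=rng)
            loss = composite_loss(out["y"][1], y_true, out["z"][1], config.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, sample {idx}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            del out, loss
            gc.collect()

        val_losses = []
        for idx in val_idx:
            img, msk = pairs[idx]
            out = graph._forward_net(_pool2(img), train=False)
            vl = soft_dice_loss(out["y"][1], Tensor(_net_res_mask(msk)))
            val_losses.append(float(vl.data))
            del out, vl
            gc.collect()
        row = {"epoch": epoch,
               "train_loss": float(np.mean(losses)),
               "val_loss": float(np.mean(val_losses)) if val_losses
               else float("nan")}
        history.append(row)
        if (config.early_stop_val_loss is not None and val_losses
                and row["val_loss"] <= config.early_stop_val_loss):
            break
    return history


def write_history_csv(history, path):
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss"])
        w.writeheader()
        for row in history:
            w.writerow(row)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(graph: ModelGraph, path):
    """Weights as .npz plus a JSON sidecar recording the configuration."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz",
             **{k: p.data for k, p in graph.params.items()})
    cfg = graph.config.__dict__.copy()
    side = path[:-4] if path.endswith(".npz") else path
    with open(side + ".json", "w") as fh:
        json.dump({"variant": graph.variant, "config": cfg}, fh, indent=1,
                  default=lambda o: list(o) if isinstance(o, tuple) else o)


def load_checkpoint(path) -> ModelGraph:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        meta = json.load(fh)
    cfg_d = meta["config"]
    for key in ("channels", "convs_per_level"):
        if cfg_d.get(key) is not None:
            cfg_d[key] = tuple(cfg_d[key])
    cfg = NetworkConfig(**cfg_d)
    graph = build_model(cfg)
    data = np.load(base + ".npz")
    for k, p in graph.params.items():
        if k not in data:
            raise ValueError(f"checkpoint missing weight '{k}'")
        if data[k].shape != p.data.shape:
            raise ValueError(f"checkpoint/config mismatch for '{k}'")
        p.data = data[k].astype(np.float64)
    return graph
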