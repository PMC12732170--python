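"""Hybrid CNN + MLP-Mixer classifier for mediastinal CT patches.

The network has four parts:

1. a VGG16-style convolutional feature extractor (13 conv layers in 5
   stages, each stage closed by 2x2 max pooling) that maps a 224x112x3
   patch to a 7x3x512 feature map;
2. a tokenizer that reshapes the spatial grid to a 21x512 token matrix
   (row-major over spatial positions) and projects each token to 256
   features with one shared linear layer;
3. a stack of MLP-Mixer blocks (default two).  Each block first applies a
   *token mixer* — the token matrix is transposed, an MLP (layernorm,
   linear, GELU, linear; weights shared across feature channels) runs along
   the token axis, the result is transposed back and added to the input —
   and then a *channel mixer*, the same MLP shape applied along the feature
   axis per token, again with a residual sum;
4. a head: global average pooling over tokens, a linear layer to two
   logits, and softmax.

A reduced "small" backbone with the same pooling schedule but far fewer
channels is provided for fast experiments on synthetic phantoms; any other
extractor can be registered through :func:`register_backbone`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .errors import ParameterError

__all__ = [
    "ModelConfig",
    "Backbone",
    "MlpBlock",
    "MixerBlock",
    "MixerNet",
    "register_backbone",
    "extract_features",
    "tokenize",
    "mlp_inner",
    "token_mixer",
    "channel_mixer",
    "mixer_forward",
    "classify",
]

# conv channel plan per stage; every stage ends with a 2x2 max pool
BACKBONE_PLANS: dict[str, tuple[tuple[int, ...], ...]] = {
    "vgg16": ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512)),
    "small": ((8,), (16,), (32,), (32,), (32,)),
}


def register_backbone(name: str, plan: tuple[tuple[int, ...], ...]) -> None:
    """Register an alternative conv channel plan under ``name``."""
    BACKBONE_PLANS[name] = tuple(tuple(s) for s in plan)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``tokens`` (S) and ``channels`` (C) default to 21 and 256, matching the
    tokenization arithmetic for a 224x112 input through five pooling stages
    (7*3 = 21 spatial positions).  Hidden widths default to S and C — a
    parameter-neutral choice, since no value is prescribed.
    """

    backbone: str = "vgg16"
    pretrained: bool = False
    weights_path: str | None = None
    freeze_backbone: bool = False
    n_mixer_blocks: int = 2
    tokens: int = 21
    channels: int = 256
    hidden_tokens: int | None = None
    hidden_channels: int | None = None
    n_classes: int = 2
    final_norm: bool = True
    input_size: tuple[int, int] = (224, 112)
    input_mean: float = 0.5  # subtracted before the conv stack (mean-centering)

    def __post_init__(self):
        if self.n_mixer_blocks < 1:
            raise ParameterError("n_mixer_blocks must be >= 1")
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if self.backbone not in BACKBONE_PLANS:
            raise ParameterError(
                f"unknown backbone {self.backbone!r}; registered: {sorted(BACKBONE_PLANS)}")
        h, w = self.input_size
        for _ in range(5):
            h, w = h // 2, w // 2
        if h * w != self.tokens:
            raise ParameterError(
                f"input_size {self.input_size} yields {h}x{w}={h * w} spatial "
                f"positions, but tokens={self.tokens}")
        self.feature_shape = (h, w)

    @property
    def h_s(self) -> int:
        return self.hidden_tokens or self.tokens

    @property
    def h_c(self) -> int:
        return self.hidden_channels or self.channels


class Backbone:
    """Stack of 3x3 conv + ReLU stages, each followed by 2x2 max pooling."""

    def __init__(self, plan, rng: np.random.Generator, in_channels: int = 3):
        self.layers: list[nn.Layer] = []
        c = in_channels
        for stage in plan:
            for c_out in stage:
                self.layers.append(nn.Conv2D(c, c_out, rng=rng))
                self.layers.append(nn.ReLU())
                c = c_out
            self.layers.append(nn.MaxPool2())
        self.out_channels = c

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class MlpBlock:
    """The mixer's inner MLP: layernorm, linear, GELU, linear.

    Applied row-wise along the last axis of its input, with weights shared
    over all leading axes (i.e. over all tokens, or over all channels,
    depending on orientation).
    """

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.norm = nn.LayerNorm(dim)
        self.fc1 = nn.Dense(dim, hidden, rng=rng, init="glorot")
        self.act = nn.GELU()
        self.fc2 = nn.Dense(hidden, dim, rng=rng, init="glorot")
        self.layers = [self.norm, self.fc1, self.act, self.fc2]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def zero_weights(self) -> None:
        """Zero both linear layers (makes the residual block an identity)."""
        for l in (self.fc1, self.fc2):
            l.params["W"][...] = 0.0
            l.params["b"][...] = 0.0


class MixerBlock:
    """One token-mixing + channel-mixing step with residual sums."""

    def __init__(self, tokens: int, channels: int, h_s: int, h_c: int,
                 rng: np.random.Generator):
        self.token_mlp = MlpBlock(tokens, h_s, rng)
        self.channel_mlp = MlpBlock(channels, h_c, rng)
        self.layers = self.token_mlp.layers + self.channel_mlp.layers

    def token_mix(self, x):
        """x + transpose(MLP(transpose(x))) — mixes information across tokens."""
        y = np.swapaxes(x, -1, -2)
        t = self.token_mlp.forward(y)
        return x + np.swapaxes(t, -1, -2)

    def token_mix_backward(self, dout):
        dt = self.token_mlp.backward(np.swapaxes(dout, -1, -2))
        return dout + np.swapaxes(dt, -1, -2)

    def channel_mix(self, x):
        """x + MLP(x) along the feature axis of each token."""
        return x + self.channel_mlp.forward(x)

    def channel_mix_backward(self, dout):
        return dout + self.channel_mlp.backward(dout)

    def forward(self, x):
        return self.channel_mix(self.token_mix(x))

    def backward(self, dout):
        return self.token_mix_backward(self.channel_mix_backward(dout))


class MixerNet:
    """The full patch classifier; see the module docstring for the layout."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.backbone = Backbone(BACKBONE_PLANS[cfg.backbone], rng)
        self.projection = nn.Dense(self.backbone.out_channels, cfg.channels,
                                   rng=rng, init="glorot")
        self.blocks = [MixerBlock(cfg.tokens, cfg.channels, cfg.h_s, cfg.h_c, rng)
                       for _ in range(cfg.n_mixer_blocks)]
        self.final_norm = nn.LayerNorm(cfg.channels) if cfg.final_norm else None
        self.head = nn.Dense(cfg.channels, cfg.n_classes, rng=rng, init="glorot")
        if cfg.weights_path:
            self.load_weights(cfg.weights_path)
        elif cfg.pretrained:
            raise ParameterError(
                "pretrained=True requires weights_path pointing to an .npz "
                "checkpoint; no weights are bundled with the package")
        self.feature_map = None
        self.d_feature_map = None

    # -- plumbing -----------------------------------------------------------
    @property
    def layers(self) -> list[nn.Layer]:
        out = list(self.backbone.layers) + [self.projection]
        for b in self.blocks:
            out += b.layers
        if self.final_norm is not None:
            out.append(self.final_norm)
        out.append(self.head)
        return out

    @property
    def trainable_layers(self) -> list[nn.Layer]:
        out = [] if self.config.freeze_backbone else list(self.backbone.layers)
        out.append(self.projection)
        for b in self.blocks:
            out += b.layers
        if self.final_norm is not None:
            out.append(self.final_norm)
        out.append(self.head)
        return out

    def train(self, mode: bool = True):
        for l in self.layers:
            l.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batch of patches ``(N, H, W, 3)`` -> logits ``(N, n_classes)``."""
        h, w = self.config.input_size
        if x.ndim != 4 or x.shape[1:] != (h, w, 3):
            raise ParameterError(f"expected input (N, {h}, {w}, 3), got {x.shape}")
        f = self.backbone.forward(x - np.asarray(self.config.input_mean, dtype=x.dtype))
        self.feature_map = f
        n = f.shape[0]
        t = f.reshape(n, self.config.tokens, self.backbone.out_channels)
        t = self.projection.forward(t)
        for b in self.blocks:
            t = b.forward(t)
        if self.final_norm is not None:
            t = self.final_norm.forward(t)
        g = t.mean(axis=1)
        return self.head.forward(g)

    def backward(self, dlogits: np.ndarray, through_backbone: bool = True) -> None:
        """Backpropagate from logits; leaves d(feature map) in
        ``self.d_feature_map`` (used by Grad-CAM) and gradients in the layers."""
        s = self.config.tokens
        dg = self.head.backward(dlogits)
        dt = np.broadcast_to(dg[:, None, :] / s, (dg.shape[0], s, dg.shape[1])).copy()
        if self.final_norm is not None:
            dt = self.final_norm.backward(dt)
        for b in reversed(self.blocks):
            dt = b.backward(dt)
        df = self.projection.backward(dt)
        self.d_feature_map = df.reshape(self.feature_map.shape)
        if through_backbone and not self.config.freeze_backbone:
            self.backbone.backward(self.d_feature_map)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        self.eval()
        out = []
        for i in range(0, len(x), batch_size):
            out.append(nn.softmax(self.forward(x[i:i + batch_size])))
        self.train()
        return np.concatenate(out, axis=0)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights as ``<path>.npz`` plus a JSON config sidecar."""
        path = Path(path)
        arrays = {f"{i}:{k}": l.params[k]
                  for i, l in enumerate(self.layers) for k in l.params}
        np.savez(path.with_suffix(".npz"), **arrays)
        cfg = asdict(self.config)
        cfg.pop("feature_shape", None)
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))

    def load_weights(self, path: str | Path) -> None:
        with np.load(Path(path)) as data:
            for i, l in enumerate(self.layers):
                for k in l.params:
                    key = f"{i}:{k}"
                    if key not in data:
                        raise ParameterError(f"checkpoint missing parameter {key}")
                    if data[key].shape != l.params[k].shape:
                        raise ParameterError(
                            f"shape mismatch for {key}: {data[key].shape} vs "
                            f"{l.params[k].shape}")
                    l.params[k][...] = data[key]

    @classmethod
    def load(cls, path: str | Path) -> "MixerNet":
        path = Path(path)
        cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        cfg.weights_path = None
        net = cls(cfg)
        net.load_weights(path.with_suffix(".npz"))
        return net


# -- functional surface ------------------------------------------------------
def _batched(x: np.ndarray) -> tuple[np.ndarray, bool]:
    if x.ndim == 3 and x.shape[-1] == 3 or x.ndim == 2:
        return x[None], True
    return x, False


def extract_features(patch: np.ndarray, backbone: Backbone) -> np.ndarray:
    """Run a single ``(H, W, 3)`` patch (or a batch) through the conv stack.

    For a 224x112 input and any registered 5-stage plan the output grid is
    ``(7, 3, out_channels)``.
    """
    x, single = _batched(patch)
    f = backbone.forward(x.astype(np.float32, copy=False))
    return f[0] if single else f


def tokenize(feature_map: np.ndarray, projection: nn.Dense) -> np.ndarray:
    """Reshape ``(h, w, C_in)`` row-major to ``(h*w, C_in)`` tokens and apply
    the shared per-token projection, giving ``(S, C)``."""
    single = feature_map.ndim == 3
    f = feature_map[None] if single else feature_map
    n, h, w, c = f.shape
    t = projection.forward(f.reshape(n, h * w, c))
    return t[0] if single else t


def mlp_inner(a: np.ndarray, block: MlpBlock) -> np.ndarray:
    """layernorm -> linear -> GELU -> linear along the last axis of ``a``,
    with weights shared over all leading axes."""
    x, single = _batched(a)
    out = block.forward(x)
    return out[0] if single else out


def token_mixer(x: np.ndarray, block: MixerBlock) -> np.ndarray:
    xb, single = _batched(x)
    out = block.token_mix(xb)
    return out[0] if single else out


def channel_mixer(x: np.ndarray, block: MixerBlock) -> np.ndarray:
    xb, single = _batched(x)
    out = block.channel_mix(xb)
    return out[0] if single else out


def mixer_forward(x: np.ndarray, blocks: list[MixerBlock]) -> np.ndarray:
    xb, single = _batched(x)
    for b in blocks:
        xb = b.forward(xb)
    return xb[0] if single else xb


def classify(x: np.ndarray, head: nn.Dense, final_norm: nn.LayerNorm | None = None
             ) -> np.ndarray:
    """GAP over tokens, linear head, softmax -> class probabilities."""
    xb, single = _batched(x)
    if final_norm is not None:
        xb = final_norm.forward(xb)
    probs = nn.softmax(head.forward(xb.mean(axis=-2)))
    return probs[0] if single else probs
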