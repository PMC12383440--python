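"""Prompt-conditioned multi-modal segmentation network.

Architecture: a shared-weight encoder maps every modality image to a feature
map; the Feature Fusion Block (FFB) concatenates the per-modality maps,
computes squeeze-and-excitation channel-attention weights (global average
pooling followed by a two-layer bottleneck with ReLU then sigmoid), rescales
the concatenated channels, adds the residual identity path, and projects with
a learned 1x1 convolution to the decoder width; the decoder combines the fused
map with a learned embedding of the normalized bounding-box prompt and
upsamples back to input resolution, emitting one logit per pixel.  A pixel is
predicted foreground when its logit is >= 0 (sigmoid 0.5, ties count as
foreground).

Two encoder kinds exist: ``light_trainable`` is the small convolutional
encoder defined here (stride-4, trained from scratch, used by all tests);
``foundation_frozen`` plugs in an external pretrained vision-transformer
encoder whose weights are loaded from a checkpoint path and never updated.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import nn

ENCODER_STRIDE = 4  # two stride-2 convolutions in the light encoder

#: which config part each parameter-name prefix belongs to; the learned
#: box-prompt embedding is grouped with the decoder it feeds.
PART_OF_PREFIX = {"enc": "encoder", "ffb": "ffb", "dec": "decoder", "prompt": "decoder"}


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    encoder_kind: str = "light_trainable"
    n_modalities: int = 4
    encoder_channels: int = 8          # C1, per-modality feature channels
    se_reduction: int = 16             # r, SE bottleneck ratio
    decoder_channels: int = 16
    input_size: int = 64
    trainable_parts: frozenset = frozenset({"encoder", "ffb", "decoder"})
    foundation_checkpoint: str | None = None

    @property
    def fused_channels(self) -> int:
        """C2 = N * C1, channel width after concatenation."""
        return self.n_modalities * self.encoder_channels

    @property
    def bottleneck(self) -> int:
        return max(1, self.fused_channels // self.se_reduction)

    def __post_init__(self):
        if self.encoder_kind not in ("light_trainable", "foundation_frozen"):
            raise ValueError(f"unknown encoder_kind {self.encoder_kind!r}")
        if self.fused_channels // self.se_reduction < 1:
            raise ValueError(
                f"SE bottleneck C2/r = {self.fused_channels}/{self.se_reduction} < 1; "
                "lower se_reduction or raise encoder_channels"
            )
        if self.encoder_kind == "foundation_frozen" and "encoder" in self.trainable_parts:
            raise ValueError("foundation_frozen forbids a trainable encoder")
        if self.input_size % ENCODER_STRIDE != 0:
            raise ValueError(f"input_size must be a multiple of {ENCODER_STRIDE}")


@dataclasses.dataclass
class FeatureMapSet:
    """Per-modality encoder outputs, all (C1, h, w) with a shared spatial size."""

    maps: list  # list of (B, C1, h, w) arrays

    def validate(self):
        shapes = {m.shape for m in self.maps}
        if len(shapes) != 1:
            raise ValueError(f"feature maps disagree in shape: {shapes}")


@dataclasses.dataclass
class FusionState:
    """Intermediate tensors of one FFB pass (for inspection/visualization)."""

    concat: np.ndarray     # (B, C2, h, w)
    squeeze: np.ndarray    # (B, C2) global-average-pooled channel descriptor
    weights: np.ndarray    # (B, C2) attention weights, each in (0, 1)
    modulated: np.ndarray  # (B, C2, h, w) channel-rescaled map
    fused: np.ndarray      # (B, D, h, w) post-residual projected map


# ---------------------------------------------------------------------------
# FFB as standalone functional ops (the algebra under test)


def ffb_squeeze(concat: np.ndarray) -> np.ndarray:
    """Global average pooling over the spatial dims: z_k = mean_{h,w} F_c(k,h,w)."""
    return concat.mean(axis=(-2, -1))


def ffb_excite(z: np.ndarray, W1: np.ndarray, b1: np.ndarray,
               W2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Two-layer bottleneck s = sigmoid(W2 . relu(W1 . z)); outputs in (0, 1)."""
    if W1.shape[1] != z.shape[-1]:
        raise ValueError(f"W1 expects dim {W1.shape[1]}, got z dim {z.shape[-1]}")
    h = np.maximum(z @ W1.T + b1, 0.0)
    return 1.0 / (1.0 + np.exp(-(h @ W2.T + b2)))


def ffb_apply(concat: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Channel-wise rescaling F_fm(k) = s_k * F_c(k)."""
    if concat.shape[-3] != s.shape[-1]:
        raise ValueError("channel count mismatch between map and weights")
    return concat * s[..., :, None, None]


def ffb_fuse(modulated: np.ndarray, concat: np.ndarray,
             proj_W: np.ndarray, proj_b: np.ndarray) -> np.ndarray:
    """Residual combination then learned 1x1 projection to decoder width."""
    out, _ = nn.conv2d_forward(modulated + concat, proj_W, proj_b, stride=1, pad=0)
    return out


# ---------------------------------------------------------------------------
# the full light model


class FusionModel:
    """Light trainable segmentation model over a dict of named parameters."""

    def __init__(self, config: ModelConfig, params: dict | None = None, seed: int = 0):
        self.config = config
        if config.encoder_kind == "foundation_frozen":
            self._load_foundation(config.foundation_checkpoint)
        self.params = params if params is not None else self.init_params(seed)

    @staticmethod
    def _load_foundation(path: str | None):
        import os

        if path is None or not os.path.exists(path or ""):
            raise FileNotFoundError(
                f"foundation encoder weights not found at {path!r}; download a "
                "pretrained checkpoint and set ModelConfig.foundation_checkpoint, "
                "or use encoder_kind='light_trainable'"
            )
        raise NotImplementedError(
            "loading external foundation weights requires a deep-learning runtime; "
            "this build supports the light_trainable encoder"
        )

    def init_params(self, seed: int) -> dict:
        cfg = self.config
        rng = np.random.default_rng(seed)
        c1, c2, d, bn = cfg.encoder_channels, cfg.fused_channels, cfg.decoder_channels, cfg.bottleneck
        p = {
            "enc.conv1.W": nn.he_conv(rng, c1, 3, 3),
            "enc.conv1.b": np.zeros(c1),
            "enc.conv2.W": nn.he_conv(rng, c1, c1, 3),
            "enc.conv2.b": np.zeros(c1),
            "ffb.W1": nn.he_linear(rng, bn, c2),
            "ffb.b1": np.zeros(bn),
            "ffb.W2": nn.he_linear(rng, c2, bn),
            "ffb.b2": np.zeros(c2),
            "ffb.proj.W": nn.he_conv(rng, d, c2, 1),
            "ffb.proj.b": np.zeros(d),
            "prompt.W": nn.he_linear(rng, d, 4),
            "prompt.b": np.zeros(d),
            "dec.conv1.W": nn.he_conv(rng, d, d, 3),
            "dec.conv1.b": np.zeros(d),
            "dec.conv2.W": nn.he_conv(rng, d, d, 3),
            "dec.conv2.b": np.zeros(d),
            "dec.out.W": nn.he_conv(rng, 1, d, 3),
            "dec.out.b": np.zeros(1),
        }
        return p

    # -- parameter bookkeeping ------------------------------------------------

    def trainable_names(self) -> list[str]:
        return [k for k in self.params
                if PART_OF_PREFIX[k.split(".")[0]] in self.config.trainable_parts]

    def no_decay_names(self) -> set:
        return {k for k in self.params if k.endswith(".b") or k.endswith("b1") or k.endswith("b2")}

    # -- forward --------------------------------------------------------------

    def encode_modalities(self, images: np.ndarray):
        """images (B, N, 3, S, S) -> FeatureMapSet of N maps (B, C1, S/4, S/4).

        One shared-weight encoder applied independently per modality.
        """
        b, n_mod = images.shape[:2]
        if n_mod != self.config.n_modalities:
            raise ValueError(f"expected {self.config.n_modalities} modalities, got {n_mod}")
        p = self.params
        maps, caches = [], []
        for n in range(n_mod):
            a1, c1 = nn.conv2d_forward(images[:, n], p["enc.conv1.W"], p["enc.conv1.b"], stride=2, pad=1)
            r1, m1 = nn.relu_forward(a1)
            a2, c2 = nn.conv2d_forward(r1, p["enc.conv2.W"], p["enc.conv2.b"], stride=2, pad=1)
            r2, m2 = nn.relu_forward(a2)
            maps.append(r2)
            caches.append((c1, m1, c2, m2))
        fset = FeatureMapSet(maps)
        fset.validate()
        return fset, caches

    def fuse(self, fset: FeatureMapSet):
        """Run the FFB over a FeatureMapSet; returns FusionState + backprop cache."""
        p = self.params
        concat = np.concatenate(fset.maps, axis=1)
        z = ffb_squeeze(concat)
        h_pre = z @ p["ffb.W1"].T + p["ffb.b1"]
        h = np.maximum(h_pre, 0.0)
        s_pre = h @ p["ffb.W2"].T + p["ffb.b2"]
        s = 1.0 / (1.0 + np.exp(-s_pre))
        modulated = ffb_apply(concat, s)
        residual = modulated + concat
        fused, proj_cache = nn.conv2d_forward(residual, p["ffb.proj.W"], p["ffb.proj.b"], stride=1, pad=0)
        state = FusionState(concat, z, s, modulated, fused)
        cache = (concat, z, h_pre, h, s, proj_cache)
        return state, cache

    def encode_prompt(self, bboxes: np.ndarray):
        """Normalized (x0,y0,x1,y1)/S corners -> (B, D) learned embedding."""
        norm = np.asarray(bboxes, dtype=np.float64) / self.config.input_size
        emb, cache = nn.linear_forward(norm, self.params["prompt.W"], self.params["prompt.b"])
        return emb, (cache, norm)

    def decode(self, fused: np.ndarray, prompt_emb: np.ndarray):
        p = self.params
        x = fused + prompt_emb[:, :, None, None]
        a1, c1 = nn.conv2d_forward(x, p["dec.conv1.W"], p["dec.conv1.b"], stride=1, pad=1)
        r1, m1 = nn.relu_forward(a1)
        u1, s1 = nn.upsample2_forward(r1)
        a2, c2 = nn.conv2d_forward(u1, p["dec.conv2.W"], p["dec.conv2.b"], stride=1, pad=1)
        r2, m2 = nn.relu_forward(a2)
        u2, s2 = nn.upsample2_forward(r2)
        logits, c3 = nn.conv2d_forward(u2, p["dec.out.W"], p["dec.out.b"], stride=1, pad=1)
        return logits[:, 0], (c1, m1, s1, c2, m2, s2, c3)

    def forward(self, images: np.ndarray, bboxes: np.ndarray,
                return_state: bool = False):
        """Full pass: (B, N, 3, S, S) images + (B, 4) boxes -> (B, S, S) logits.

        The logit map is at input resolution (the decoder upsamples the
        stride-4 feature grid back to S x S).
        """
        fset, enc_caches = self.encode_modalities(images)
        state, ffb_cache = self.fuse(fset)
        prompt_emb, prompt_cache = self.encode_prompt(bboxes)
        logits, dec_cache = self.decode(state.fused, prompt_emb)
        cache = (enc_caches, ffb_cache, prompt_cache, dec_cache, images.shape)
        if return_state:
            return logits, cache, state
        return logits, cache

    def predict_mask(self, images: np.ndarray, bboxes: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(images, bboxes)
        return (logits >= 0.0).astype(np.uint8)

    # -- backward -------------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache) -> dict:
        """Gradient of the loss w.r.t. every parameter; input grads discarded."""
        p = self.params
        enc_caches, ffb_cache, prompt_cache, dec_cache, images_shape = cache
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        # decoder
        c1, m1, s1, c2, m2, s2, c3 = dec_cache
        dl = dlogits[:, None]
        du2, dW, db = nn.conv2d_backward(dl, c3, p["dec.out.W"])
        grads["dec.out.W"] += dW
        grads["dec.out.b"] += db
        dr2 = nn.upsample2_backward(du2, s2)
        da2 = nn.relu_backward(dr2, m2)
        du1, dW, db = nn.conv2d_backward(da2, c2, p["dec.conv2.W"])
        grads["dec.conv2.W"] += dW
        grads["dec.conv2.b"] += db
        dr1 = nn.upsample2_backward(du1, s1)
        da1 = nn.relu_backward(dr1, m1)
        dx, dW, db = nn.conv2d_backward(da1, c1, p["dec.conv1.W"])
        grads["dec.conv1.W"] += dW
        grads["dec.conv1.b"] += db
        dfused = dx
        dprompt = dx.sum(axis=(2, 3))

        # prompt embedding
        lin_cache, _ = prompt_cache
        _, dW, db = nn.linear_backward(dprompt, lin_cache, p["prompt.W"])
        grads["prompt.W"] += dW
        grads["prompt.b"] += db

        # FFB
        concat, z, h_pre, h, s, proj_cache = ffb_cache
        dresidual, dW, db = nn.conv2d_backward(dfused, proj_cache, p["ffb.proj.W"])
        grads["ffb.proj.W"] += dW
        grads["ffb.proj.b"] += db
        dmod = dresidual
        dconcat = dresidual.copy()
        ds = (dmod * concat).sum(axis=(2, 3))
        dconcat += dmod * s[:, :, None, None]
        ds_pre = ds * s * (1.0 - s)
        grads["ffb.W2"] += ds_pre.T @ h
        grads["ffb.b2"] += ds_pre.sum(axis=0)
        dh = ds_pre @ p["ffb.W2"]
        dh_pre = dh * (h_pre > 0)
        grads["ffb.W1"] += dh_pre.T @ z
        grads["ffb.b1"] += dh_pre.sum(axis=0)
        dz = dh_pre @ p["ffb.W1"]
        hw = concat.shape[-2] * concat.shape[-1]
        dconcat += dz[:, :, None, None] / hw

        # split back into per-modality feature gradients, shared encoder
        c1ch = self.config.encoder_channels
        for n, (cc1, mm1, cc2, mm2) in enumerate(enc_caches):
            dmap = dconcat[:, n * c1ch:(n + 1) * c1ch]
            da2 = nn.relu_backward(dmap, mm2)
            dr1, dW, db = nn.conv2d_backward(da2, cc2, p["enc.conv2.W"])
            grads["enc.conv2.W"] += dW
            grads["enc.conv2.b"] += db
            da1 = nn.relu_backward(dr1, mm1)
            _, dW, db = nn.conv2d_backward(da1, cc1, p["enc.conv1.W"])
            grads["enc.conv1.W"] += dW
            grads["enc.conv1.b"] += db
        return grads

    # -- persistence ----------------------------------------------------------

    def save(self, path: str) -> None:
        cfg = dataclasses.asdict(self.config)
        cfg["trainable_parts"] = sorted(cfg["trainable_parts"])
        np.savez_compressed(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str) -> "FusionModel":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["trainable_parts"] = frozenset(cfg["trainable_parts"])
        config = ModelConfig(**cfg)
        params = {k: data[k] for k in data.files if k != "__config__"}
        return cls(config, params=params)
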