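"""Promptable ViT segmentation model with serial bottleneck adapters.

Architecture mirrors the segment-anything family: a ViT image encoder (with a
mix of windowed and global attention blocks), a sparse prompt encoder for
points and boxes, and a lightweight two-way cross-attention mask decoder whose
hypernetwork MLP emits a dynamic per-image linear classifier.

Parameter-efficient transfer: each transformer block can carry one bottleneck
adapter after its attention sub-layer and one after its MLP sub-layer
(``Adapter(x) = W_up ReLU(W_down x) + x``).  Adapters are zero-initialised on
the up-projection, so inserting them leaves the network function unchanged
until training moves them.  Freeze policies mark everything but the adapters
(and optionally the decoder head) as non-trainable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Buffer, Parameter, Tensor, concat
from .nn import (Adapter, CrossAttention, LayerNorm, Linear, Mlp, Module,
                 ModuleList, MultiHeadAttention, gelu)

__all__ = [
    "EncoderConfig", "AdapterConfig", "DecoderConfig", "PromptSet",
    "ImageEncoderViT", "PromptEncoder", "MaskDecoder", "SamAdapterNet",
    "adapter_forward", "insert_adapters", "count_trainable_params",
    "freeze_policy", "build_model", "PRESETS", "save_checkpoint",
    "load_checkpoint",
]

FREEZE_POLICIES = ("adapters_only", "adapters_plus_decoder", "full")


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    image_size: int = 64
    patch_size: int = 8
    embed_dim: int = 64
    depth: int = 4
    heads: int = 4
    global_attn_indices: tuple = (0, 1, 2, 3)
    mlp_ratio: float = 2.0
    window_size: int = 0  # 0 => all-global; else local window side in tokens

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if not set(self.global_attn_indices) <= set(range(self.depth)):
            raise ValueError("global_attn_indices outside [0, depth)")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size


@dataclass
class AdapterConfig:
    bottleneck: int = 100
    placement: tuple = ("after-attention", "after-mlp")
    include_bias: bool = True

    def __post_init__(self):
        valid = {"after-attention", "after-mlp"}
        if not set(self.placement) <= valid:
            raise ValueError(f"placement must be a subset of {valid}")
        if self.bottleneck <= 0:
            raise ValueError("bottleneck dimension must be positive")


@dataclass
class DecoderConfig:
    depth: int = 2
    heads: int = 4
    upscale: int = 4
    channels: int = 16
    logit_bias_init: float = -3.0  # start predicting background


@dataclass
class PromptSet:
    """Sparse prompts: labelled points and boxes in pixel coordinates.

    Points are (x, y, label) with label 1 = foreground, 0 = background;
    boxes are (x0, y0, x1, y1) with x0 < x1, y0 < y1.
    """

    points: list = field(default_factory=list)
    boxes: list = field(default_factory=list)

    def validate(self, image_size: int) -> None:
        for x, y, label in self.points:
            if not (0 <= x <= image_size and 0 <= y <= image_size):
                raise ValueError(f"point ({x}, {y}) outside image of size {image_size}")
            if label not in (0, 1):
                raise ValueError(f"point label must be 0 or 1, got {label}")
        for x0, y0, x1, y1 in self.boxes:
            if not (x0 < x1 and y0 < y1):
                raise ValueError(f"degenerate box ({x0}, {y0}, {x1}, {y1})")
            if not (0 <= x0 and x1 <= image_size and 0 <= y0 and y1 <= image_size):
                raise ValueError(f"box ({x0}, {y0}, {x1}, {y1}) outside image")

    @staticmethod
    def full_image(image_size: int) -> "PromptSet":
        return PromptSet(boxes=[(0.0, 0.0, float(image_size), float(image_size))])

    @staticmethod
    def from_mask_bbox(mask: np.ndarray, margin: int = 2) -> "PromptSet":
        """Tight bounding box of a binary mask, dilated by ``margin`` pixels."""
        rows = np.any(mask > 0, axis=1)
        cols = np.any(mask > 0, axis=0)
        if not rows.any():
            return PromptSet.full_image(mask.shape[1])
        r0, r1 = np.where(rows)[0][[0, -1]]
        c0, c1 = np.where(cols)[0][[0, -1]]
        h, w = mask.shape
        return PromptSet(boxes=[(
            float(max(0, c0 - margin)), float(max(0, r0 - margin)),
            float(min(w, c1 + 1 + margin)), float(min(h, r1 + 1 + margin)),
        )])


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

class TransformerBlock(Module):
    def __init__(self, cfg: EncoderConfig, index: int, rng: np.random.Generator):
        d = cfg.embed_dim
        # residual-branch outputs scaled 1/sqrt(2*depth): keeps the residual
        # stream near unit variance when training from scratch
        res_scale = 1.0 / np.sqrt(2.0 * cfg.depth)
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadAttention(d, cfg.heads, rng, out_scale=res_scale)
        self.norm2 = LayerNorm(d)
        self.mlp = Mlp(d, int(d * cfg.mlp_ratio), rng, out_scale=res_scale)
        self.adapter_attn = None
        self.adapter_mlp = None
        self.is_global = index in cfg.global_attn_indices or cfg.window_size == 0
        self.window = cfg.window_size
        self.grid = cfg.grid

    def _attend(self, x: Tensor) -> Tensor:
        if self.is_global:
            return self.attn(x)
        g, w = self.grid, self.window
        if g % w:
            raise ValueError(f"token grid {g} not divisible by window {w}")
        d = x.shape[-1]
        # (1, g*g, d) -> (nw, w*w, d) window partition
        xw = (x.reshape(g // w, w, g // w, w, d)
               .transpose(0, 2, 1, 3, 4)
               .reshape((g // w) ** 2, w * w, d))
        out = self.attn(xw)
        return (out.reshape(g // w, g // w, w, w, d)
                   .transpose(0, 2, 1, 3, 4)
                   .reshape(1, g * g, d))

    def forward(self, x: Tensor) -> Tensor:
        h = self._attend(self.norm1(x))
        if self.adapter_attn is not None:
            h = self.adapter_attn(h)
        x = x + h
        h = self.mlp(self.norm2(x))
        if self.adapter_mlp is not None:
            h = self.adapter_mlp(h)
        return x + h


class ImageEncoderViT(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        p, d = cfg.patch_size, cfg.embed_dim
        self.patch_embed = Linear(p * p, d, rng)
        self.pos_embed = Parameter(rng.normal(0.0, 0.02, size=(cfg.grid**2, d)))
        self.blocks = ModuleList(
            TransformerBlock(cfg, i, rng) for i in range(cfg.depth)
        )
        self.norm = LayerNorm(d)

    def forward(self, image: np.ndarray | Tensor) -> Tensor:
        """Encode a (H, W) image into a (grid, grid, d) embedding grid."""
        data = image.data if isinstance(image, Tensor) else np.asarray(image, float)
        cfg = self.cfg
        if data.shape != (cfg.image_size, cfg.image_size):
            raise ValueError(
                f"image shape {data.shape} does not match configured size "
                f"{cfg.image_size}x{cfg.image_size}")
        p, g = cfg.patch_size, cfg.grid
        patches = (data.reshape(g, p, g, p)
                       .transpose(0, 2, 1, 3)
                       .reshape(g * g, p * p))
        x = self.patch_embed(Tensor(patches)) + self.pos_embed
        x = x.reshape(1, g * g, cfg.embed_dim)
        for block in self.blocks:
            x = block(x)
        x = self.norm(x)
        return x.reshape(g, g, cfg.embed_dim)


# ---------------------------------------------------------------------------
# adapters: functional form, insertion, counting, freezing
# ---------------------------------------------------------------------------

def adapter_forward(x, w_down, b_down, w_up, b_up):
    """Apply one bottleneck adapter to (n, d) token features (numpy arrays).

    Returns ``ReLU(x W_down + b_down) W_up + b_up + x`` — the residual
    bottleneck map with a ReLU between down- and up-projection.
    """
    x = np.asarray(x, dtype=float)
    w_down = np.asarray(w_down, dtype=float)
    w_up = np.asarray(w_up, dtype=float)
    if x.shape[-1] != w_down.shape[0] or w_down.shape[1] != w_up.shape[0] \
            or w_up.shape[1] != x.shape[-1]:
        raise ValueError(
            f"adapter shape mismatch: x {x.shape}, W_down {w_down.shape}, "
            f"W_up {w_up.shape}")
    hidden = np.maximum(x @ w_down + np.asarray(b_down, float), 0.0)
    return hidden @ w_up + np.asarray(b_up, float) + x


def insert_adapters(encoder: ImageEncoderViT, cfg: AdapterConfig,
                    rng: np.random.Generator) -> ImageEncoderViT:
    """Attach one adapter per configured placement to every encoder block."""
    d = encoder.cfg.embed_dim
    if cfg.bottleneck > d:
        raise ValueError(f"adapter bottleneck m={cfg.bottleneck} exceeds d={d}")
    for block in encoder.blocks:
        if "after-attention" in cfg.placement:
            block.adapter_attn = Adapter(d, cfg.bottleneck, rng, cfg.include_bias)
        if "after-mlp" in cfg.placement:
            block.adapter_mlp = Adapter(d, cfg.bottleneck, rng, cfg.include_bias)
    return encoder


def count_trainable_params(model: Module) -> int:
    return sum(p.size for _, p in model.named_parameters() if p.requires_grad)


def _is_adapter(name: str) -> bool:
    return ".adapter_attn." in name or ".adapter_mlp." in name


def freeze_policy(model: Module, policy: str) -> Module:
    """Mark parameters trainable/frozen according to ``policy`` (in place)."""
    if policy not in FREEZE_POLICIES:
        raise ValueError(f"unknown freeze policy {policy!r}; choose from {FREEZE_POLICIES}")
    for name, p in model.named_parameters():
        if policy == "full":
            p.requires_grad = True
        elif policy == "adapters_only":
            p.requires_grad = _is_adapter(name)
        else:  # adapters_plus_decoder: adapters plus the task head
            p.requires_grad = (_is_adapter(name)
                               or name.startswith("decoder.")
                               or name.startswith("prompt_encoder."))
    return model


# ---------------------------------------------------------------------------
# prompt encoder
# ---------------------------------------------------------------------------

class PromptEncoder(Module):
    """Random-Fourier positional encoding plus learned per-type embeddings.

    Token accounting: one token per point, two per box (corner tokens);
    an empty prompt set yields the single learned padding token.
    """

    N_TYPES = 5  # bg point, fg point, box top-left, box bottom-right, padding

    def __init__(self, embed_dim: int, image_size: int, rng: np.random.Generator):
        if embed_dim % 2:
            raise ValueError("embed_dim must be even for Fourier position encoding")
        self.image_size = image_size
        self.pe_matrix = Buffer(rng.normal(0.0, 1.0, size=(2, embed_dim // 2)))
        self.type_embed = Parameter(rng.normal(0.0, 0.02, size=(self.N_TYPES, embed_dim)))

    def _positional(self, xy: np.ndarray) -> np.ndarray:
        coords = 2.0 * (np.asarray(xy, float) / self.image_size) - 1.0
        proj = 2.0 * np.pi * coords @ self.pe_matrix.data
        return np.concatenate([np.sin(proj), np.cos(proj)], axis=-1)

    def forward(self, prompts: PromptSet) -> Tensor:
        prompts.validate(self.image_size)
        tokens = []
        for x, y, label in prompts.points:
            pe = Tensor(self._positional(np.array([[x, y]])))
            tokens.append(pe + self.type_embed[int(label):int(label) + 1])
        for x0, y0, x1, y1 in prompts.boxes:
            pe = Tensor(self._positional(np.array([[x0, y0], [x1, y1]])))
            tokens.append(pe[0:1] + self.type_embed[2:3])
            tokens.append(pe[1:2] + self.type_embed[3:4])
        if not tokens:
            tokens.append(self.type_embed[4:5])
        out = concat(tokens, axis=0) if len(tokens) > 1 else tokens[0]
        return out.reshape(1, out.shape[0], out.shape[-1])


# ---------------------------------------------------------------------------
# mask decoder
# ---------------------------------------------------------------------------

class TwoWayBlock(Module):
    """Token self-attention, token→image and image→token cross-attention."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.cross_t2i = CrossAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, 2 * dim, rng)
        self.norm3 = LayerNorm(dim)
        self.cross_i2t = CrossAttention(dim, heads, rng)
        self.norm4 = LayerNorm(dim)

    def forward(self, tokens: Tensor, image_tokens: Tensor):
        tokens = tokens + self.self_attn(self.norm1(tokens))
        tokens = tokens + self.cross_t2i(self.norm2(tokens), image_tokens)
        tokens = tokens + self.mlp(self.norm3(tokens))
        image_tokens = image_tokens + self.cross_i2t(self.norm4(image_tokens), tokens)
        return tokens, image_tokens


class MaskDecoder(Module):
    def __init__(self, embed_dim: int, grid: int, image_size: int,
                 cfg: DecoderConfig, rng: np.random.Generator):
        self.grid = grid
        self.image_size = image_size
        self.cfg = cfg
        if image_size % (grid * cfg.upscale):
            raise ValueError("grid * upscale must divide image_size")
        self.final_factor = image_size // (grid * cfg.upscale)
        self.mask_token = Parameter(rng.normal(0.0, 0.02, size=(1, embed_dim)))
        self.blocks = ModuleList(
            TwoWayBlock(embed_dim, cfg.heads, rng) for _ in range(cfg.depth)
        )
        self.norm_img = LayerNorm(embed_dim)
        self.norm_tok = LayerNorm(embed_dim)
        self.upscale_fc1 = Linear(embed_dim, cfg.upscale**2 * cfg.channels, rng)
        self.hyper_fc1 = Linear(embed_dim, embed_dim, rng)
        # near-zero final hypernet layer: logits start at the background bias
        self.hyper_fc2 = Linear(embed_dim, cfg.channels, rng, scale=0.01)
        self.logit_bias = Parameter(np.array([cfg.logit_bias_init]))

    def forward(self, image_embedding: Tensor, sparse_tokens: Tensor) -> Tensor:
        g = self.grid
        d = image_embedding.shape[-1]
        if sparse_tokens.shape[-1] != d:
            raise ValueError(
                f"prompt embedding dim {sparse_tokens.shape[-1]} != image dim {d}")
        image_tokens = image_embedding.reshape(1, g * g, d)
        tokens = concat(
            [self.mask_token.reshape(1, 1, d), sparse_tokens], axis=1)
        for block in self.blocks:
            tokens, image_tokens = block(tokens, image_tokens)

        up, c = self.cfg.upscale, self.cfg.channels
        img_normed = self.norm_img(image_tokens.reshape(g * g, d))
        feat = gelu(self.upscale_fc1(img_normed))
        feat = (feat.reshape(g, g, up, up, c)
                    .transpose(0, 2, 1, 3, 4)
                    .reshape(g * up, g * up, c))
        mask_tok = self.norm_tok(tokens[:, 0, :])
        weights = self.hyper_fc2(gelu(self.hyper_fc1(mask_tok)))  # (1, c)
        logits = (feat.reshape(g * up * g * up, c) @ weights.transpose(1, 0)
                  + self.logit_bias)
        logits = logits.reshape(g * up, g * up)
        if self.final_factor > 1:
            logits = logits.upsample2d(self.final_factor)
        return logits


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------

class SamAdapterNet(Module):
    """Encoder + prompt encoder + mask decoder, optionally with adapters."""

    def __init__(self, encoder_cfg: EncoderConfig,
                 decoder_cfg: DecoderConfig | None = None,
                 adapter_cfg: AdapterConfig | None = None,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        decoder_cfg = decoder_cfg or DecoderConfig()
        self.encoder_cfg = encoder_cfg
        self.decoder_cfg = decoder_cfg
        self.adapter_cfg = adapter_cfg
        self.encoder = ImageEncoderViT(encoder_cfg, rng)
        self.prompt_encoder = PromptEncoder(
            encoder_cfg.embed_dim, encoder_cfg.image_size, rng)
        self.decoder = MaskDecoder(
            encoder_cfg.embed_dim, encoder_cfg.grid, encoder_cfg.image_size,
            decoder_cfg, rng)
        if adapter_cfg is not None:
            insert_adapters(self.encoder, adapter_cfg, rng)

    def forward(self, image: np.ndarray, prompts: PromptSet | None = None) -> Tensor:
        """Logits at the preprocessed input resolution for one image."""
        if prompts is None:
            prompts = PromptSet.full_image(self.encoder_cfg.image_size)
        embedding = self.encoder(image)
        sparse = self.prompt_encoder(prompts)
        return self.decoder(embedding, sparse)

    def predict_proba(self, image: np.ndarray,
                      prompts: PromptSet | None = None) -> np.ndarray:
        return self.forward(image, prompts).sigmoid().data

    def predict_mask(self, image: np.ndarray, prompts: PromptSet | None = None,
                     threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(image, prompts) >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# presets and checkpoints
# ---------------------------------------------------------------------------

PRESETS: dict[str, dict] = {
    "tiny": dict(
        encoder=dict(image_size=64, patch_size=8, embed_dim=64, depth=4,
                     heads=4, global_attn_indices=(0, 1, 2, 3), mlp_ratio=2.0,
                     window_size=0),
        decoder=dict(depth=2, heads=4, upscale=4, channels=16),
    ),
    "vit_b": dict(
        encoder=dict(image_size=1024, patch_size=16, embed_dim=768, depth=12,
                     heads=12, global_attn_indices=(2, 5, 8, 11), mlp_ratio=4.0,
                     window_size=16),
        decoder=dict(depth=2, heads=8, upscale=4, channels=32),
    ),
}


def build_model(preset: str = "tiny", adapter_m: int | None = 8,
                include_bias: bool = True, seed: int = 0,
                overrides: dict | None = None) -> SamAdapterNet:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    spec = copy.deepcopy(PRESETS[preset])
    for key, value in (overrides or {}).items():
        spec["encoder" if key in spec["encoder"] else "decoder"][key] = value
    adapter_cfg = None
    if adapter_m is not None:
        adapter_cfg = AdapterConfig(bottleneck=adapter_m, include_bias=include_bias)
    return SamAdapterNet(
        EncoderConfig(**spec["encoder"]),
        DecoderConfig(**spec["decoder"]),
        adapter_cfg,
        seed=seed,
    )


def save_checkpoint(model: Module, path) -> None:
    """Flat name→array archive (.npz)."""
    np.savez(path, **model.state_dict())


def load_checkpoint(model: Module, path) -> Module:
    with np.load(path) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model
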