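"""Two-stage inpainting generator and the local/global Wasserstein critics.

The generator follows the coarse-to-fine contextual-attention design: a
dilated-convolution *coarse* network produces a blurred first prediction of
the removed square; a *refinement* network with parallel dilated and
contextual-attention branches sharpens it by borrowing coherent texture
from the known surroundings.  Two critics score realism: the *local* critic
sees a crop around the completed mask, the *global* critic the whole field
of view (with one extra stride-2 input convolution at 512-px fields of view
so the flattened feature length matches the 256-px case).

Everything runs in the [-1, 1] network domain with a tanh output; module
boundaries convert to/from the [0, 1] storage domain.  Channel widths scale
with a single ``width`` multiplier so desk-scale configurations stay cheap.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .sampler import MASK_FILL, MaskedPatch


class EmptyBackgroundError(ValueError):
    """Contextual attention needs at least one known background patch."""


@dataclasses.dataclass(frozen=True)
class CompletionResult:
    """Coarse, refined and blended predictions in the [-1, 1] network domain.

    ``blended`` equals the original input bit-exactly outside the mask.
    """

    coarse: np.ndarray
    fine: np.ndarray
    blended: np.ndarray

    def blended_unit(self) -> np.ndarray:
        """Blended image mapped back to the [0, 1] storage domain."""
        return (self.blended + 1.0) / 2.0


@dataclasses.dataclass(frozen=True)
class CriticScores:
    local: float
    global_: float


@dataclasses.dataclass
class ModelConfig:
    fov: int = 256
    width: int = 24                  # generator base channel count
    critic_width: int = 24
    dilations: tuple[int, ...] = (2, 4, 8, 16)
    attention_patch: int = 3
    attention_scale: float = 10.0
    local_crop_side: int = 128       # fixed local-critic input side
    seed: int = 0

    @classmethod
    def tiny(cls, seed: int = 0) -> "ModelConfig":
        """Desk-scale configuration: 64-px field of view, reduced widths."""
        return cls(fov=64, width=8, critic_width=8, dilations=(2, 4, 8),
                   local_crop_side=16, seed=seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dilations"] = list(self.dilations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["dilations"] = tuple(d["dilations"])
        return cls(**d)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv:
    def __init__(self, cin, cout, k, rng, stride=1, dilation=1):
        fan_in = cin * k * k
        w = rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)
        self.w = Tensor(w.astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride, self.dilation = stride, dilation
        self.pad = dilation * (k - 1) // 2

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b, stride=self.stride,
                         dilation=self.dilation, pad=self.pad)

    def params(self):
        return [self.w, self.b]


class Linear:
    def __init__(self, nin, nout, rng):
        w = rng.standard_normal((nin, nout)) * np.sqrt(1.0 / nin)
        self.w = Tensor(w.astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(nout, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return ad.add(ad.matmul(x, self.w), self.b)

    def params(self):
        return [self.w, self.b]


def attention_weights(fg_features: np.ndarray, bg_patches: np.ndarray,
                      scale: float = 10.0) -> np.ndarray:
    """Softmax of scaled cosine similarities, one weight row per fg location.

    ``fg_features``: [P, L] patch matrix over the region to fill;
    ``bg_patches``: [P, K] patch matrix from the known region.  Returns
    [L, K] nonnegative rows summing to one.
    """
    fg = np.asarray(fg_features, dtype=np.float64)
    bg = np.asarray(bg_patches, dtype=np.float64)
    if bg.ndim != 2 or bg.shape[1] == 0:
        raise EmptyBackgroundError("need at least one background patch")
    fg_n = fg / np.maximum(np.linalg.norm(fg, axis=0, keepdims=True), 1e-12)
    bg_n = bg / np.maximum(np.linalg.norm(bg, axis=0, keepdims=True), 1e-12)
    scores = scale * (fg_n.T @ bg_n)                     # [L, K]
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


class ContextualAttention:
    """Copy coherent background texture into every location by soft matching.

    Features are compared patch-wise (3x3, stride 1) by cosine similarity;
    a temperature-scaled softmax over *known* (unmasked) patches yields
    per-location weights, and the output is the weight-blended overlap-add
    reconstruction from those background patches.
    """

    def __init__(self, patch: int = 3, scale: float = 10.0):
        self.patch, self.scale = patch, scale

    def __call__(self, f: Tensor, masks_small: np.ndarray) -> Tensor:
        n, c, h, w = f.shape
        k = self.patch
        pad = (k - 1) // 2
        cols = ad.im2col(f, k, stride=1, dilation=1, pad=pad)   # [N, C*k*k, L]
        ones_ctx = (1, 1, h, w, k, 1, 1, pad)
        counts = ad.col2im(Tensor(np.ones((1, k * k, h * w), dtype=np.float32)),
                           ones_ctx).data                        # overlap counts
        outs = []
        for i in range(n):
            known = ~masks_small[i].reshape(-1)
            idx = np.nonzero(known)[0]
            if idx.size == 0:
                raise EmptyBackgroundError("mask covers the whole feature map")
            ci = ad.take(cols, (slice(i, i + 1),))               # [1, P, L]
            bg = ad.take(ci, (slice(None), slice(None), idx))    # [1, P, K]
            norm_all = ad.sqrt(ad.tsum(ci * ci, axis=1, keepdims=True) + Tensor(1e-8))
            norm_bg = ad.sqrt(ad.tsum(bg * bg, axis=1, keepdims=True) + Tensor(1e-8))
            scores = ad.matmul(ad.transpose(bg / norm_bg, (0, 2, 1)),
                               ci / norm_all)                    # [1, K, L]
            weights = ad.softmax(scores * self.scale, axis=1)
            out_cols = ad.matmul(bg, weights)                    # [1, P, L]
            ctx = (1, c, h, w, k, 1, 1, pad)
            outs.append(ad.col2im(out_cols, ctx) * Tensor(1.0 / counts.reshape(1, 1, h, w)))
        return ad.concat(outs, axis=0) if n > 1 else outs[0]


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class Generator:
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        w, rates = cfg.width, cfg.dilations
        mk = lambda *a, **kw: Conv(*a, rng=rng, **kw)
        # coarse stage
        self.c_enc = [mk(2, w, 5), mk(w, 2 * w, 3, stride=2), mk(2 * w, 2 * w, 3),
                      mk(2 * w, 4 * w, 3, stride=2), mk(4 * w, 4 * w, 3)]
        self.c_dil = [mk(4 * w, 4 * w, 3, dilation=r) for r in rates]
        self.c_dec = [mk(4 * w, 4 * w, 3), mk(4 * w, 2 * w, 3), mk(2 * w, w, 3)]
        self.c_out = mk(w, 1, 3)
        # refinement stage: dilated branch
        self.r_conv = [mk(2, w, 5), mk(w, w, 3, stride=2), mk(w, 2 * w, 3),
                       mk(2 * w, 2 * w, 3, stride=2), mk(2 * w, 4 * w, 3)]
        self.r_dil = [mk(4 * w, 4 * w, 3, dilation=r) for r in rates]
        # refinement stage: attention branch
        self.a_conv = [mk(2, w, 5), mk(w, w, 3, stride=2), mk(w, 2 * w, 3),
                       mk(2 * w, 4 * w, 3, stride=2)]
        self.attention = ContextualAttention(cfg.attention_patch, cfg.attention_scale)
        self.a_post = mk(4 * w, 4 * w, 3)
        # merge + decoder
        self.m_conv = [mk(8 * w, 4 * w, 3), mk(4 * w, 2 * w, 3), mk(2 * w, w, 3)]
        self.r_out = mk(w, 1, 3)
        self.use_attention = True    # identity-branch switch used by tests

    def layers(self):
        yield from self.c_enc
        yield from self.c_dil
        yield from self.c_dec
        yield self.c_out
        yield from self.r_conv
        yield from self.r_dil
        yield from self.a_conv
        yield self.a_post
        yield from self.m_conv
        yield self.r_out

    def params(self):
        return [p for layer in self.layers() for p in layer.params()]

    def _coarse(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.c_enc:
            h = ad.elu(conv(h))
        for conv in self.c_dil:
            h = ad.elu(conv(h))
        h = ad.elu(self.c_dec[0](h))
        h = ad.elu(self.c_dec[1](ad.upsample2(h)))
        h = ad.elu(self.c_dec[2](ad.upsample2(h)))
        return ad.tanh(self.c_out(h))

    def _refine(self, x: Tensor, masks: np.ndarray) -> Tensor:
        hb = x
        for conv in self.r_conv:
            hb = ad.elu(conv(hb))
        for conv in self.r_dil:
            hb = ad.elu(conv(hb))
        ha = x
        for conv in self.a_conv:
            ha = ad.elu(conv(ha))
        if self.use_attention:
            masks_small = masks.reshape(masks.shape[0], masks.shape[1] // 4, 4,
                                        masks.shape[2] // 4, 4).any(axis=(2, 4))
            ha = self.attention(ha, masks_small)
        ha = ad.elu(self.a_post(ha))
        h = ad.concat([hb, ha], axis=1)
        h = ad.elu(self.m_conv[0](h))
        h = ad.elu(self.m_conv[1](ad.upsample2(h)))
        h = ad.elu(self.m_conv[2](ad.upsample2(h)))
        return ad.tanh(self.r_out(h))

    def forward(self, truth_net: Tensor, masks: np.ndarray
                ) -> tuple[Tensor, Tensor, Tensor]:
        """truth_net: [N,1,F,F] in [-1,1]; masks: [N,F,F] bool.

        Returns (coarse, fine, blended), each [N,1,F,F].
        """
        m4 = masks[:, None].astype(np.float32)
        masked = ad.where(m4, Tensor(np.float32(MASK_FILL)), truth_net)
        x1 = ad.concat([masked, Tensor(m4)], axis=1)
        coarse = self._coarse(x1)
        pasted = ad.where(m4, coarse, truth_net)
        x2 = ad.concat([pasted, Tensor(m4)], axis=1)
        fine = self._refine(x2, masks)
        blended = ad.where(m4, fine, truth_net)
        return coarse, fine, blended


# ---------------------------------------------------------------------------
# critics
# ---------------------------------------------------------------------------

class Critic:
    """Four stride-2 convolutions (leaky ReLU) followed by a linear score."""

    def __init__(self, input_side: int, width: int, rng: np.random.Generator,
                 extra_input_conv: bool = False):
        mk = lambda *a, **kw: Conv(*a, rng=rng, **kw)
        self.extra = mk(1, 1, 5, stride=2) if extra_input_conv else None
        side = input_side // 2 if extra_input_conv else input_side
        self.convs = [mk(1, width, 5, stride=2),
                      mk(width, 2 * width, 5, stride=2),
                      mk(2 * width, 4 * width, 5, stride=2),
                      mk(4 * width, 4 * width, 5, stride=2)]
        self.feat_side = side // 16
        if self.feat_side < 1:
            raise ValueError(f"critic input side {input_side} too small")
        self.n_features = 4 * width * self.feat_side ** 2
        self.linear = Linear(self.n_features, 1, rng)

    def params(self):
        out = [] if self.extra is None else self.extra.params()
        for c in self.convs:
            out += c.params()
        return out + self.linear.params()

    def features(self, x: Tensor) -> Tensor:
        h = x
        if self.extra is not None:
            h = ad.leaky_relu(self.extra(h))
        for conv in self.convs:
            h = ad.leaky_relu(conv(h))
        return ad.reshape(h, (h.shape[0], self.n_features))

    def __call__(self, x: Tensor) -> Tensor:
        """x: [N,1,S,S] -> scores [N,1]."""
        return self.linear(self.features(x))


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class InpaintModel:
    """Generator plus local and global critics under one configuration."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.generator = Generator(cfg, rng)
        self.local_critic = Critic(cfg.local_crop_side, cfg.critic_width, rng)
        self.global_critic = Critic(cfg.fov, cfg.critic_width, rng,
                                    extra_input_conv=cfg.fov >= 512)

    # -- parameters / checkpoints ------------------------------------------
    def named_params(self) -> dict[str, Tensor]:
        out = {}
        for group, params in (("g", self.generator.params()),
                              ("dl", self.local_critic.params()),
                              ("dg", self.global_critic.params())):
            for i, p in enumerate(params):
                out[f"{group}_{i}"] = p
        return out

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **{k: v.data for k, v in self.named_params().items()})
        path.with_suffix(".config.json").write_text(
            json.dumps(self.cfg.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "InpaintModel":
        path = Path(path)
        cfg = ModelConfig.from_dict(
            json.loads(path.with_suffix(".config.json").read_text()))
        model = cls(cfg)
        with np.load(path) as data:
            for name, p in model.named_params().items():
                if data[name].shape != p.data.shape:
                    raise ValueError(f"checkpoint parameter {name} has shape "
                                     f"{data[name].shape}, expected {p.data.shape}")
                p.data = data[name].copy()
        return model

    # -- inference ----------------------------------------------------------
    def complete_batch(self, truth_net: np.ndarray, masks: np.ndarray
                       ) -> tuple[Tensor, Tensor, Tensor]:
        return self.generator.forward(
            Tensor(truth_net.astype(np.float32)), masks)

    def complete(self, masked: MaskedPatch) -> CompletionResult:
        """Inpaint one masked patch (deterministic given the weights)."""
        if masked.pixels.shape != (self.cfg.fov, self.cfg.fov):
            raise ValueError(f"patch shape {masked.pixels.shape} does not match "
                             f"fov {self.cfg.fov}")
        truth = masked.truth_network()[None, None]
        with ad.no_grad():
            coarse, fine, blended = self.complete_batch(truth, masked.mask[None])
        return CompletionResult(coarse=coarse.data[0, 0], fine=fine.data[0, 0],
                                blended=blended.data[0, 0])

    def local_crop_slices(self, spec) -> tuple[slice, slice]:
        """Fixed-size local-critic window centered on the mask, clipped to the patch."""
        side = self.cfg.local_crop_side
        fov = self.cfg.fov
        oy, ox = spec.mask_offset
        cy = oy + spec.mask_side // 2
        cx = ox + spec.mask_side // 2
        y0 = int(np.clip(cy - side // 2, 0, fov - side))
        x0 = int(np.clip(cx - side // 2, 0, fov - side))
        return slice(y0, y0 + side), slice(x0, x0 + side)

    def criticize(self, patch_net: np.ndarray, crop_net: np.ndarray) -> CriticScores:
        """Score a full patch (global) and its mask-region crop (local)."""
        with ad.no_grad():
            g = self.global_critic(Tensor(patch_net[None, None].astype(np.float32)))
            l = self.local_critic(Tensor(crop_net[None, None].astype(np.float32)))
        return CriticScores(local=l.data.item(), global_=g.data.item())


# ---------------------------------------------------------------------------
# reference inpainters (non-learned)
# ---------------------------------------------------------------------------

class OracleInpainter:
    """Returns the ground truth — the perfect-completion reference."""

    def __init__(self, fov: int):
        self.cfg = ModelConfig(fov=fov)

    def complete(self, masked: MaskedPatch) -> CompletionResult:
        truth = masked.truth_network()
        return CompletionResult(coarse=truth.copy(), fine=truth.copy(),
                                blended=truth.copy())

    def criticize(self, patch_net, crop_net) -> CriticScores:
        return CriticScores(local=0.0, global_=0.0)


class MeanFillInpainter:
    """Deterministic baseline: fill the mask with the mean of the known pixels."""

    def __init__(self, fov: int):
        self.cfg = ModelConfig(fov=fov)

    def complete(self, masked: MaskedPatch) -> CompletionResult:
        truth = masked.truth_network()
        known = truth[~masked.mask]
        fill = float(known.mean()) if known.size else 0.0
        pred = np.where(masked.mask, fill, truth)
        return CompletionResult(coarse=pred.copy(), fine=pred.copy(),
                                blended=pred.copy())

    def criticize(self, patch_net, crop_net) -> CriticScores:
        return CriticScores(local=0.0, global_=0.0)
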