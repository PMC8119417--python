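"""Loss terms for the inpainting GAN.

The total objective combines spatially-discounted L1 reconstruction over
the masked region, plain L1 over the known region, the Wasserstein
generator/critic terms from both critics, and the gradient penalty that
enforces the critics' 1-Lipschitz constraint:

    total = a_mask * L_mask + a_fov * L_fov + a_gan * L_wgan_g
            + L_wgan_d + lambda_gp * L_gp

with default weights (1.2, 1.2, 0.001, 10).  Reconstruction terms are
means over their regions so magnitudes are comparable across mask sizes;
pixels deep inside the mask are down-weighted by gamma^l where l is the
Chebyshev distance to the nearest known pixel outside the mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclasses.dataclass(frozen=True)
class LossWeights:
    alpha_mask: float = 1.2
    alpha_fov: float = 1.2
    alpha_gan: float = 0.001
    lambda_gp: float = 10.0

    def __post_init__(self):
        if min(self.alpha_mask, self.alpha_fov, self.alpha_gan, self.lambda_gp) <= 0:
            raise ValueError("loss weights must be positive")


@dataclasses.dataclass(frozen=True)
class LossBreakdown:
    l_mask: float
    l_fov: float
    l_wgan_g: float
    l_wgan_d: float
    l_gp: float          # raw mean penalty, before the lambda_gp factor
    total: float
    generator_total: float = 0.0
    critic_total: float = 0.0


def spatial_discount(mask_height: int, mask_width: int, gamma: float = 0.99
                     ) -> np.ndarray:
    """Per-pixel weight gamma^l over a solid rectangular mask.

    l is the Chebyshev distance from a mask pixel to the nearest pixel
    outside the mask, so every border pixel of the mask has l = 1.
    """
    if mask_height < 1 or mask_width < 1:
        raise ValueError("mask dimensions must be positive")
    if not (0.0 < gamma <= 1.0):
        raise ValueError("gamma must be in (0, 1]")
    i = np.arange(mask_height)[:, None]
    j = np.arange(mask_width)[None, :]
    l = np.minimum(np.minimum(i + 1, mask_height - i),
                   np.minimum(j + 1, mask_width - j))
    return gamma ** l.astype(np.float64)


def l1_region_loss(coarse, fine, truth, region_mask: np.ndarray,
                   discount: np.ndarray | None = None):
    """Discounted mean L1 of the coarse prediction over the region, plus the
    same for the fine prediction.

    ``region_mask`` is boolean over the patch; ``discount`` (if given) must
    cover the same region (broadcastable over the mask footprint).
    Accepts Tensors (training) or arrays (evaluation); returns the same kind.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    n = int(region_mask.sum())
    if n == 0:
        raise ValueError("empty region for L1 loss")
    if discount is None:
        weights = region_mask.astype(np.float64)
    elif discount.shape == region_mask.shape:
        weights = np.where(region_mask, discount, 0.0)
    else:
        # discount given on the (solid rectangular) region footprint
        if discount.size != n:
            raise ValueError("discount grid does not cover the region")
        weights = np.zeros(region_mask.shape, dtype=np.float64)
        weights[region_mask] = discount.ravel()
    if isinstance(coarse, Tensor) or isinstance(fine, Tensor):
        wt = Tensor(weights.astype(np.float32))
        t = ad.astensor(truth)
        term_c = ad.tsum(wt * ad.absolute(ad.astensor(coarse) - t)) * (1.0 / n)
        term_f = ad.tsum(wt * ad.absolute(ad.astensor(fine) - t)) * (1.0 / n)
        return term_c + term_f
    diff_c = np.abs(np.asarray(coarse) - np.asarray(truth))
    diff_f = np.abs(np.asarray(fine) - np.asarray(truth))
    return float((weights * diff_c).sum() / n + (weights * diff_f).sum() / n)


def wgan_losses(real_scores, fake_scores):
    """Wasserstein losses: critic minimizes mean(fake) - mean(real); the
    generator minimizes -mean(fake).

    Accepts Tensors or sequences; returns (critic_loss, generator_loss) of
    matching kind.
    """
    tensor_mode = isinstance(real_scores, Tensor) or isinstance(fake_scores, Tensor)
    if tensor_mode:
        r, f = ad.astensor(real_scores), ad.astensor(fake_scores)
        if r.data.size == 0 or f.data.size == 0:
            raise ValueError("empty score sequence")
        critic = ad.tmean(f) - ad.tmean(r)
        gen = -ad.tmean(f)
        return critic, gen
    r = np.asarray(real_scores, dtype=np.float64)
    f = np.asarray(fake_scores, dtype=np.float64)
    if r.size == 0 or f.size == 0:
        raise ValueError("empty score sequence")
    return float(f.mean() - r.mean()), float(-f.mean())


def gradient_penalty(critic, real_batch, fake_batch, lambda_gp: float,
                     rng: np.random.Generator) -> Tensor:
    """WGAN-GP term: lambda * E[(||grad_x critic(x_hat)||_2 - 1)^2].

    ``x_hat`` interpolates each real/fake pair at an independent uniform
    position on the connecting segment.  The returned Tensor stays attached
    to the critic parameters (double backprop), so it can be minimized.
    """
    real = np.asarray(real_batch.data if isinstance(real_batch, Tensor) else real_batch)
    fake = np.asarray(fake_batch.data if isinstance(fake_batch, Tensor) else fake_batch)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must have identical shapes")
    n = real.shape[0]
    u = rng.uniform(size=(n,) + (1,) * (real.ndim - 1))
    interp = Tensor((u * real + (1.0 - u) * fake).astype(real.dtype
                     if real.dtype in (np.float32, np.float64) else np.float32),
                    requires_grad=True)
    scores = critic(interp)
    g = ad.grad(ad.tsum(scores), interp, create_graph=True)
    sq = ad.tsum(ad.reshape(g * g, (n, -1)), axis=1)
    norm = ad.sqrt(sq + Tensor(np.full(n, 1e-16, dtype=sq.dtype)))
    return ad.tmean((norm - 1.0) ** 2.0) * float(lambda_gp)


def total_loss(l_mask: float, l_fov: float, l_wgan_g: float, l_wgan_d: float,
               l_gp: float, weights: LossWeights = LossWeights()) -> LossBreakdown:
    """Assemble the scalar breakdown from already-computed components.

    ``l_gp`` is the raw mean penalty; the lambda factor is applied here.
    Also reports the generator-side and critic-side sub-totals used by the
    alternating update.
    """
    components = (l_mask, l_fov, l_wgan_g, l_wgan_d, l_gp)
    if any(not np.isfinite(c) for c in components):
        raise ValueError(f"non-finite loss component in {components}")
    gen = (weights.alpha_mask * l_mask + weights.alpha_fov * l_fov
           + weights.alpha_gan * l_wgan_g)
    critic = l_wgan_d + weights.lambda_gp * l_gp
    return LossBreakdown(l_mask=l_mask, l_fov=l_fov, l_wgan_g=l_wgan_g,
                         l_wgan_d=l_wgan_d, l_gp=l_gp, total=gen + critic,
                         generator_total=gen, critic_total=critic)
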