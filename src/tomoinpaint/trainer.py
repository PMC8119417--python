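"""Alternating WGAN-GP optimization of the inpainting model.

Each iteration draws a fresh batch of tissue-overlapping patches with
random square masks, performs one critic update (Wasserstein loss plus
gradient penalty, for both the local and the global critic) and one
generator update (discounted L1 reconstruction plus the adversarial
term).  Runs are bit-exactly reproducible and resumable: checkpoints
carry weights, Adam moments, the configuration and the sampler RNG state.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .io_core import GrayImage
from .losses import LossBreakdown, LossWeights, gradient_penalty, spatial_discount, wgan_losses
from .model import InpaintModel, ModelConfig
from .sampler import MaskedPatch, place_mask, sample_training_batch


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 9
    iterations: int = 2_000_000
    fov: int = 256
    mask_range: tuple[int, int] = (16, 128)
    min_tissue: float = 0.1
    seed: int = 0
    checkpoint_every: int = 10_000
    critic_steps: int = 1            # critic updates per generator update
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.iterations < 0:
            raise ValueError("invalid batch size or iteration count")

    @classmethod
    def tiny(cls, seed: int = 0, iterations: int = 2000) -> "TrainConfig":
        """Desk-scale schedule matching ModelConfig.tiny()."""
        return cls(fov=64, mask_range=(8, 16), batch_size=4,
                   iterations=iterations, seed=seed, checkpoint_every=max(1, iterations))


@dataclasses.dataclass
class TrainState:
    model: InpaintModel
    opt_g: Adam
    opt_d: Adam
    rng: np.random.Generator
    step: int = 0


def init_state(model_cfg: ModelConfig, cfg: TrainConfig) -> TrainState:
    model = InpaintModel(model_cfg)
    opt_g = Adam(model.generator.params(), lr=cfg.learning_rate,
                 beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    opt_d = Adam(model.local_critic.params() + model.global_critic.params(),
                 lr=cfg.learning_rate, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    return TrainState(model=model, opt_g=opt_g, opt_d=opt_d,
                      rng=np.random.default_rng(cfg.seed))


def _batch_arrays(batch: list[MaskedPatch]) -> tuple[np.ndarray, np.ndarray]:
    truth = np.stack([p.truth_network() for p in batch])[:, None].astype(np.float32)
    masks = np.stack([p.mask for p in batch])
    return truth, masks


def _local_crops(model: InpaintModel, batch: list[MaskedPatch], images: Tensor
                 ) -> Tensor:
    crops = []
    for i, p in enumerate(batch):
        ys, xs = model.local_crop_slices(p.spec)
        crops.append(ad.take(images, (slice(i, i + 1), slice(None), ys, xs)))
    return ad.concat(crops, axis=0) if len(crops) > 1 else crops[0]


def _discount_weights(batch: list[MaskedPatch], gamma: float) -> np.ndarray:
    w = np.zeros((len(batch), 1) + batch[0].mask.shape, dtype=np.float64)
    for i, p in enumerate(batch):
        side = p.spec.mask_side
        w[i, 0][p.spec.mask_slices()] = spatial_discount(side, side, gamma)
    return w


def train_step(state: TrainState, batch: list[MaskedPatch],
               weights: LossWeights = LossWeights(), gamma: float = 0.99
               ) -> LossBreakdown:
    """One critic update followed by one generator update on ``batch``."""
    model = state.model
    truth_np, masks = _batch_arrays(batch)
    n = len(batch)

    # single generator forward reused by both updates
    coarse, fine, blended = model.complete_batch(truth_np, masks)

    # ---- critic update ----------------------------------------------------
    fake = blended.data
    real_t, fake_t = Tensor(truth_np), Tensor(fake)
    real_local = _local_crops(model, batch, real_t)
    fake_local = _local_crops(model, batch, fake_t)

    crit_wgan = Tensor(np.float32(0.0))
    for critic, r, f in ((model.global_critic, real_t, fake_t),
                         (model.local_critic, real_local, fake_local)):
        c_loss, _ = wgan_losses(critic(r), critic(f))
        crit_wgan = crit_wgan + c_loss
    gp = Tensor(np.float32(0.0))
    gp = gp + gradient_penalty(model.global_critic, truth_np, fake, 1.0, state.rng)
    gp = gp + gradient_penalty(model.local_critic, real_local.data, fake_local.data,
                               1.0, state.rng)
    critic_obj = crit_wgan + gp * weights.lambda_gp
    state.opt_d.zero_grad()
    critic_obj.backward()
    state.opt_d.step()

    # ---- generator update -------------------------------------------------
    truth_t = Tensor(truth_np)
    masks4 = masks[:, None]
    disc = Tensor(_discount_weights(batch, gamma).astype(np.float32))
    n_mask = max(int(masks4.sum()), 1)
    n_fov = max(int((~masks4).sum()), 1)
    err_c = ad.absolute(coarse - truth_t)
    err_f = ad.absolute(fine - truth_t)
    l_mask = (ad.tsum(disc * err_c) + ad.tsum(disc * err_f)) * (1.0 / n_mask)
    keep = Tensor((~masks4).astype(np.float32))
    l_fov = (ad.tsum(keep * err_c) + ad.tsum(keep * err_f)) * (1.0 / n_fov)

    gen_scores = []
    for critic, x in ((model.global_critic, blended),
                      (model.local_critic, _local_crops(model, batch, blended))):
        gen_scores.append(critic(x))
    l_wgan_g = -(ad.tmean(gen_scores[0]) + ad.tmean(gen_scores[1]))
    gen_obj = (l_mask * weights.alpha_mask + l_fov * weights.alpha_fov
               + l_wgan_g * weights.alpha_gan)
    state.opt_g.zero_grad()
    for p in model.generator.params():
        p.grad = None
    gen_obj.backward()
    state.opt_g.step()

    state.step += 1
    breakdown = LossBreakdown(
        l_mask=float(l_mask.data), l_fov=float(l_fov.data),
        l_wgan_g=float(l_wgan_g.data), l_wgan_d=float(crit_wgan.data),
        l_gp=float(gp.data),
        total=float(gen_obj.data) + float(critic_obj.data),
        generator_total=float(gen_obj.data), critic_total=float(critic_obj.data))
    if not np.isfinite(breakdown.total):
        raise FloatingPointError(f"non-finite loss at step {state.step}: {breakdown}")
    return breakdown


def validation_l1(model: InpaintModel, images: list[GrayImage], fov: int,
                  mask_side: int, rng: np.random.Generator,
                  min_tissue: float = 0.1, n_patches: int = 8) -> float:
    """Mean masked-region L1 of the fine prediction on center-masked crops."""
    from .sampler import sample_patch

    errs = []
    for _ in range(n_patches):
        img = images[int(rng.integers(len(images)))]
        spec = sample_patch(img, fov, min_tissue, rng)
        patch = place_mask(img, spec.origin, fov, mask_side, position="center")
        result = model.complete(patch)
        truth = patch.truth_network()
        errs.append(float(np.abs(result.fine - truth)[patch.mask].mean()))
    return float(np.mean(errs))


def save_checkpoint(state: TrainState, cfg: TrainConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state.model.save(path / "weights.npz")
    opt_state = {"g": state.opt_g.state_dict(), "d": state.opt_d.state_dict()}
    np.savez(path / "optimizer.npz",
             **{f"g_m_{i}": m for i, m in enumerate(opt_state["g"]["m"])},
             **{f"g_v_{i}": v for i, v in enumerate(opt_state["g"]["v"])},
             **{f"d_m_{i}": m for i, m in enumerate(opt_state["d"]["m"])},
             **{f"d_v_{i}": v for i, v in enumerate(opt_state["d"]["v"])})
    meta = {"step": state.step,
            "opt_t": {"g": state.opt_g.t, "d": state.opt_d.t},
            "train_config": dataclasses.asdict(cfg),
            "rng_state": state.rng.bit_generator.state}
    (path / "state.json").write_text(json.dumps(meta, sort_keys=True))


def load_checkpoint(path) -> tuple[TrainState, TrainConfig]:
    path = Path(path)
    meta = json.loads((path / "state.json").read_text())
    tc = meta["train_config"]
    tc["mask_range"] = tuple(tc["mask_range"])
    cfg = TrainConfig(**tc)
    model = InpaintModel.load(path / "weights.npz")
    state = init_state(model.cfg, cfg)
    state.model = model
    state.opt_g = Adam(model.generator.params(), lr=cfg.learning_rate,
                       beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    state.opt_d = Adam(model.local_critic.params() + model.global_critic.params(),
                       lr=cfg.learning_rate, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    with np.load(path / "optimizer.npz") as data:
        for opt, tag in ((state.opt_g, "g"), (state.opt_d, "d")):
            opt.m = [data[f"{tag}_m_{i}"].copy() for i in range(len(opt.params))]
            opt.v = [data[f"{tag}_v_{i}"].copy() for i in range(len(opt.params))]
    state.opt_g.t = meta["opt_t"]["g"]
    state.opt_d.t = meta["opt_t"]["d"]
    state.step = meta["step"]
    state.rng = np.random.default_rng()
    state.rng.bit_generator.state = meta["rng_state"]
    return state, cfg


def train(images: list[GrayImage], model_cfg: ModelConfig, cfg: TrainConfig,
          checkpoint_dir=None, state: TrainState | None = None,
          log_every: int = 0, validation_images: list[GrayImage] | None = None
          ) -> TrainState:
    """Run ``cfg.iterations`` alternating updates on freshly sampled patches."""
    if not images:
        raise ValueError("empty training set")
    if state is None:
        state = init_state(model_cfg, cfg)
    weights = LossWeights()
    while state.step < cfg.iterations:
        batch = sample_training_batch(images, cfg.fov, cfg.mask_range,
                                      cfg.min_tissue, cfg.batch_size, state.rng)
        breakdown = train_step(state, batch, weights)
        if log_every and state.step % log_every == 0:
            msg = (f"step {state.step}: l_mask={breakdown.l_mask:.4f} "
                   f"l_fov={breakdown.l_fov:.4f} critic={breakdown.critic_total:.4f}")
            if validation_images:
                val = validation_l1(state.model, validation_images, cfg.fov,
                                    max(cfg.mask_range), np.random.default_rng(cfg.seed + 1))
                msg += f" val_l1={val:.4f}"
            print(msg)
        if checkpoint_dir is not None and state.step % cfg.checkpoint_every == 0:
            save_checkpoint(state, cfg, Path(checkpoint_dir) / f"step_{state.step:08d}")
    if checkpoint_dir is not None:
        save_checkpoint(state, cfg, Path(checkpoint_dir) / "final")
    return state
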