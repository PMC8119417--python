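"""The bundled desk-scale end-to-end experiment.

Defines, in one place, the study conditions used by the package's
verification runs (see docs/methods.md): train the tiny model on normal
phantoms, then measure inside/outside error ratios on held-out phantoms
with inserted anomalies, alongside the deterministic mean-fill reference.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .evaluation import inside_outside_ratio, valid_region
from .heatmap import sliding_heatmaps
from .model import MeanFillInpainter, ModelConfig
from .phantom import PhantomParams, generate_phantom, insert_anomaly
from .trainer import TrainConfig, TrainState, train

#: Desk-scale study conditions (chosen once; see docs/methods.md).
N_TRAIN_PHANTOMS = 200
N_EVAL_PHANTOMS = 20
TRAIN_ITERATIONS = 500
TRAIN_PHANTOM = PhantomParams(height=192, width=192)
EVAL_PHANTOM = PhantomParams(height=352, width=352)
EVAL_FOV = 64
EVAL_MASK_SIDE = 16
EVAL_STRIDE = 16


@dataclasses.dataclass
class EndToEndResult:
    mean_ratio: dict[str, float]        # metric -> mean inside/outside ratio
    per_image: dict[str, list[float]]
    baseline_mse_ratio: float           # mean-fill inpainter, MSE metric
    n_train: int
    n_eval: int
    iterations: int


def training_images(seed: int, n: int = N_TRAIN_PHANTOMS):
    rng = np.random.default_rng(seed)
    return [generate_phantom(TRAIN_PHANTOM, rng)[0] for _ in range(n)]


def evaluation_cases(seed: int, n: int = N_EVAL_PHANTOMS):
    """Held-out anomalous phantoms: (image, box) pairs."""
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        img, mask = generate_phantom(EVAL_PHANTOM, rng)
        img, box = insert_anomaly(img, mask, EVAL_PHANTOM, rng)
        cases.append((img, box))
    return cases


def train_tiny(seed: int, iterations: int = TRAIN_ITERATIONS,
               n_train: int = N_TRAIN_PHANTOMS) -> TrainState:
    images = training_images(seed + 1, n_train)
    mc = ModelConfig.tiny(seed=seed)
    tc = TrainConfig.tiny(seed=seed, iterations=iterations)
    return train(images, mc, tc)


def ratio_experiment(seed: int, iterations: int = TRAIN_ITERATIONS,
                     n_train: int = N_TRAIN_PHANTOMS,
                     n_eval: int = N_EVAL_PHANTOMS,
                     include_baseline: bool = True) -> EndToEndResult:
    """Train the tiny model from ``seed`` and evaluate localization ratios."""
    state = train_tiny(seed, iterations, n_train)
    cases = evaluation_cases(seed + 2, n_eval)
    baseline = MeanFillInpainter(EVAL_FOV)
    per_image: dict[str, list[float]] = {"MSE": [], "DISCR": [], "DMSE": []}
    baseline_ratios: list[float] = []
    for img, box in cases:
        maps = sliding_heatmaps(state.model, img, EVAL_FOV, EVAL_MASK_SIDE,
                                stride=EVAL_STRIDE)
        valid = valid_region(img, maps["MSE"])
        for metric, hmap in maps.items():
            _, _, ratio = inside_outside_ratio(hmap, [box], valid)
            if ratio is not None:
                per_image[metric].append(ratio)
        if include_baseline:
            bmap = sliding_heatmaps(baseline, img, EVAL_FOV, EVAL_MASK_SIDE,
                                    stride=EVAL_STRIDE, metrics=("MSE",))["MSE"]
            _, _, bratio = inside_outside_ratio(bmap, [box],
                                                valid_region(img, bmap))
            if bratio is not None:
                baseline_ratios.append(bratio)
    return EndToEndResult(
        mean_ratio={m: float(np.mean(v)) for m, v in per_image.items()},
        per_image=per_image,
        baseline_mse_ratio=float(np.mean(baseline_ratios)) if baseline_ratios
        else float("nan"),
        n_train=n_train, n_eval=n_eval, iterations=iterations)


def baseline_experiment(seed: int, n_eval: int = N_EVAL_PHANTOMS) -> float:
    """Mean-fill-only MSE ratio (no training; deterministic given seed)."""
    cases = evaluation_cases(seed + 2, n_eval)
    baseline = MeanFillInpainter(EVAL_FOV)
    ratios = []
    for img, box in cases:
        bmap = sliding_heatmaps(baseline, img, EVAL_FOV, EVAL_MASK_SIDE,
                                stride=EVAL_STRIDE, metrics=("MSE",))["MSE"]
        _, _, r = inside_outside_ratio(bmap, [box], valid_region(img, bmap))
        if r is not None:
            ratios.append(r)
    return float(np.mean(ratios))
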