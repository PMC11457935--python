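"""Multiscale masked feature loss for adversarial segmentor/critic training.

The objective is a min/max game: the segmentor S minimizes, and the critic C
maximizes,

    L(theta_S, theta_C) = (1/N) sum_n  l_mae( f_C(x_n o S(x_n)),
                                              f_C(x_n o y_n) )

where ``o`` is the elementwise (Hadamard) product that restricts the input
image to the predicted or reference mask, f_C is the critic's ordered set of
per-level feature maps, and

    l_mae(f, f') = (1/L) sum_{i=1..L} || f_i - f'_i ||_1

with L the number of critic scales. ||.||_1 is the entrywise sum of absolute
values; a per-element mean variant is available behind ``per_element_mean``
for callers who want magnitudes independent of image size (off by default,
since summation is the literal reading of the norm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, narrow
from .network import Critic, MultiscaleFeatures, Segmentor

__all__ = ["TrainingBatch", "mask", "multiscale_mae", "adversarial_objective"]


@dataclass
class TrainingBatch:
    """Paired DIC slices and reference masks (labels in [0, 1])."""

    images: list[np.ndarray]
    labels: list[np.ndarray]

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"batch has {len(self.images)} images but {len(self.labels)} labels"
            )
        for x, y in zip(self.images, self.labels):
            if np.shape(x) != np.shape(y):
                raise ValueError(
                    f"image/label shape mismatch: {np.shape(x)} vs {np.shape(y)}"
                )

    def __len__(self):
        return len(self.images)


def mask(image, mask_):
    """Restrict ``image`` to the support of ``mask_`` (elementwise product)."""
    if np.shape(image) != np.shape(mask_):
        raise ValueError(
            f"shape mismatch: image {np.shape(image)} vs mask {np.shape(mask_)}"
        )
    if isinstance(image, Tensor) or isinstance(mask_, Tensor):
        return Tensor._lift(image) * Tensor._lift(mask_)
    return np.asarray(image) * np.asarray(mask_)


def _level_l1(a, b, per_element_mean: bool):
    diff = (Tensor._lift(a) - Tensor._lift(b)).abs()
    if diff.ndim == 4:
        # batched NCHW features: L1 over feature entries, mean over batch
        total = diff.sum(axis=(1, 2, 3))
        if per_element_mean:
            total = total * (1.0 / int(np.prod(diff.shape[1:])))
        return total.mean()
    total = diff.sum()
    if per_element_mean:
        total = total * (1.0 / diff.data.size)
    return total


def multiscale_mae(
    feats_a: MultiscaleFeatures,
    feats_b: MultiscaleFeatures,
    per_element_mean: bool = False,
) -> Tensor:
    """Mean over critic levels of the entrywise L1 feature difference."""
    levels_a = list(feats_a)
    levels_b = list(feats_b)
    if len(levels_a) != len(levels_b):
        raise ValueError(
            f"level-count mismatch: {len(levels_a)} vs {len(levels_b)}"
        )
    if not levels_a:
        raise ValueError("empty feature sets")
    total = None
    for a, b in zip(levels_a, levels_b):
        if np.shape(a.data if isinstance(a, Tensor) else a) != np.shape(
            b.data if isinstance(b, Tensor) else b
        ):
            raise ValueError("per-level feature shapes must match")
        term = _level_l1(a, b, per_element_mean)
        total = term if total is None else total + term
    return total * (1.0 / len(levels_a))


def adversarial_objective(
    batch: TrainingBatch,
    segmentor: Segmentor,
    critic: Critic,
    per_element_mean: bool = False,
) -> Tensor:
    """The min/max objective over one batch, as a differentiable scalar.

    Gradients with respect to segmentor weights descend it; gradients with
    respect to critic weights ascend it. The batch is stacked into one NCHW
    pass so batch normalization sees the whole batch.
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    n = len(batch)
    x = Tensor(np.stack([np.asarray(im, dtype=np.float64) for im in batch.images])[:, None])
    y = Tensor(np.stack([np.asarray(lb, dtype=np.float64) for lb in batch.labels])[:, None])
    pred = segmentor(x)
    # one combined critic pass so both masked branches share normalization
    # statistics inside the critic
    both = concat([mask(x, pred), mask(x, y)], axis=0)
    feats = critic(both)
    feats_pred = MultiscaleFeatures([narrow(level, 0, 0, n) for level in feats])
    feats_true = MultiscaleFeatures([narrow(level, 0, n, 2 * n) for level in feats])
    return multiscale_mae(feats_pred, feats_true, per_element_mean=per_element_mean)
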