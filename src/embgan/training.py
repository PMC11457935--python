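"""Alternating min/max training of the segmentor and critic.

Each optimization step processes one batch twice: first the segmentor is
frozen and the critic takes one full forward/backward pass ascending the
multiscale objective; then the critic is frozen and the segmentor takes one
descending step. Both use Adam. An "epoch" iterates these alternating steps
over every batch of the shuffled dataset. The run is fully reproducible
under its seed: weight initialization, data order, and therefore the whole
loss history. The defaults here are desk-scale (small network, 50 epochs);
the original large-scale recipe (10,000 epochs, batch 36, learning rate
2e-4, Adam) remains expressible through the same config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import Parameter
from .adversarial_loss import TrainingBatch, adversarial_objective
from .imgproc import ContrastParams, autocontrast_8bit, clip_shift, reassemble, split_slices
from .network import Critic, CriticConfig, Segmentor, SegmentorConfig, segmentor_forward
from .volumes import ImageVolume, MaskVolume

__all__ = [
    "TrainConfig",
    "TrainingDivergedError",
    "Adam",
    "train",
    "infer_volume",
    "prepare_training_pairs",
    "save_checkpoint",
    "load_checkpoint",
]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; all positive. Adam runs with library-default
    betas (0.9, 0.999) and eps 1e-8, recorded in checkpoints."""

    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 2e-4
    seed: int = 0
    checkpoint_every: int = 0  # 0 = only final
    per_element_mean: bool = False

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


class Adam:
    """Adam optimizer over a list of parameters; ``maximize`` ascends."""

    def __init__(self, params: list[Parameter], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, maximize: bool = False):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = -p.grad if maximize else p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _set_frozen_stats(module, frozen: bool):
    """Toggle batchnorm running-stat updates across a module tree."""
    stack = [module]
    while stack:
        m = stack.pop()
        if hasattr(m, "frozen_stats"):
            m.frozen_stats = frozen
        stack.extend(child for _, child in m._children())


def train(
    dataset: list[tuple[np.ndarray, np.ndarray]],
    segmentor_config: SegmentorConfig = SegmentorConfig(),
    critic_config: CriticConfig = CriticConfig(),
    train_config: TrainConfig = TrainConfig(),
    callback=None,
) -> tuple[Segmentor, Critic, list[dict]]:
    """Run alternating adversarial training over (image, label) pairs.

    Returns the trained networks and a per-step history with one record per
    phase: ``{"step", "epoch", "phase", "loss"}`` where phase "critic"
    (ascent) always precedes phase "segmentor" (descent) within a step.
    Aborts with :class:`TrainingDivergedError` if the objective goes
    non-finite.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng([train_config.seed, 21])
    segmentor = Segmentor(segmentor_config, seed=int(rng.integers(2 ** 31)))
    critic = Critic(critic_config, seed=int(rng.integers(2 ** 31)))
    opt_s = Adam(segmentor.parameters(), train_config.learning_rate)
    opt_c = Adam(critic.parameters(), train_config.learning_rate)
    history: list[dict] = []
    step = 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(dataset))
        for start in range(0, len(dataset), train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            batch = TrainingBatch(
                images=[dataset[i][0] for i in idx],
                labels=[dataset[i][1] for i in idx],
            )
            # phase 1: freeze S, ascend the objective w.r.t. the critic
            _set_frozen_stats(segmentor, True)
            _set_frozen_stats(critic, False)
            segmentor.zero_grad()
            critic.zero_grad()
            loss_c = adversarial_objective(
                batch, segmentor, critic, per_element_mean=train_config.per_element_mean
            )
            if not np.isfinite(loss_c.data):
                raise TrainingDivergedError(
                    f"non-finite objective in critic phase at step {step}"
                )
            loss_c.backward()
            opt_c.step(maximize=True)
            history.append(
                {"step": step, "epoch": epoch, "phase": "critic", "loss": loss_c.item()}
            )
            # phase 2: freeze C, descend w.r.t. the segmentor
            _set_frozen_stats(segmentor, False)
            _set_frozen_stats(critic, True)
            segmentor.zero_grad()
            critic.zero_grad()
            loss_s = adversarial_objective(
                batch, segmentor, critic, per_element_mean=train_config.per_element_mean
            )
            if not np.isfinite(loss_s.data):
                raise TrainingDivergedError(
                    f"non-finite objective in segmentor phase at step {step}"
                )
            loss_s.backward()
            opt_s.step(maximize=False)
            history.append(
                {"step": step, "epoch": epoch, "phase": "segmentor", "loss": loss_s.item()}
            )
            step += 1
        if callback is not None:
            callback(epoch, segmentor, critic, history)
    return segmentor, critic, history


# ---------------------------------------------------------------------------
# data preparation and inference
# ---------------------------------------------------------------------------

def prepare_training_pairs(
    dic_volumes: list[ImageVolume],
    mask_volumes: list[MaskVolume],
    contrast: ContrastParams = ContrastParams(),
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Slice paired volumes into 2D (image, label) training examples.

    Images go through the standard preprocessing (autocontrast to 8-bit)
    and are scaled to [0, 1]; labels are binarized to {0, 1} floats.
    """
    pairs = []
    for dic, masks in zip(dic_volumes, mask_volumes, strict=True):
        if dic.shape != masks.shape:
            raise ValueError(f"shape mismatch: {dic.shape} vs {masks.shape}")
        img8 = autocontrast_8bit(dic, contrast)
        for img, lab in zip(split_slices(img8), split_slices(masks)):
            pairs.append(
                (
                    img.astype(np.float64) / 255.0,
                    (np.asarray(lab) > 0).astype(np.float64),
                )
            )
    return pairs


def infer_volume(
    segmentor: Segmentor,
    dic_volume: ImageVolume,
    contrast: ContrastParams = ContrastParams(),
    clip_offset: float = 4.0,
) -> ImageVolume:
    """Full inference pipeline for one volume.

    Preprocess (autocontrast to 8-bit, scale to [0, 1]), run the segmentor
    slice-wise (padding and cropping transparently), reassemble the 2D score
    maps into a stack, and clip-shift the result. The output is voxel-aligned
    with the input.
    """
    was_training = segmentor.training
    segmentor.eval()
    try:
        img8 = autocontrast_8bit(dic_volume, contrast)
        outs = [
            segmentor_forward(segmentor, s.astype(np.float64) / 255.0)
            for s in split_slices(img8)
        ]
    finally:
        if was_training:
            segmentor.train()
    prob = reassemble(outs, z_count=dic_volume.n_slices, like=dic_volume)
    return clip_shift(prob, clip_offset)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    path,
    segmentor: Segmentor,
    critic: Critic | None = None,
    train_config: TrainConfig | None = None,
):
    """Single-file .npz archive holding weights plus embedded configs."""
    meta = {
        "segmentor_config": asdict(segmentor.config),
        "critic_config": asdict(critic.config) if critic is not None else None,
        "train_config": asdict(train_config) if train_config is not None else None,
        "adam": {"betas": [0.9, 0.999], "eps": 1e-8},
    }
    arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for k, v in segmentor.named_state("segmentor.").items():
        arrays[k] = v
    if critic is not None:
        for k, v in critic.named_state("critic.").items():
            arrays[k] = v
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[Segmentor, Critic | None]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    segmentor = Segmentor(SegmentorConfig(**meta["segmentor_config"]))
    segmentor.load_state(state, "segmentor.")
    critic = None
    if meta["critic_config"] is not None:
        critic = Critic(CriticConfig(**meta["critic_config"]))
        critic.load_state(state, "critic.")
    return segmentor, critic
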