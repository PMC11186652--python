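"""Four-loss objective, augmentation set, and the training loop.

The CGI loss is the sum of four two-class cross-entropies in log base 2 —
one per section-correlation head (antrum-body, antrum-cardia, all three) and
one for the fusion classifier:

    l = l_AB + l_AC + l_ABC + l_F,      l_H = sum_k -log2 p_H(y_k | x_k).

Each component is the base-2 negative log-likelihood of the *true* class
under a 2-way softmax (for y=0 the term is -log2(1-p)); the positive-only
form has a degenerate all-positive minimiser and cannot express specificity.
Batch reduction defaults to the mean; ``reduction="sum"`` gives the literal
sum over patients.

Optimisation uses Adam.  The reference regime is batch size 68, learning
rate 1e-5 and 1000 epochs; test presets run far smaller (see docs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .model import GSCNet, HeadOutputs
from .synthetic import Cohort

__all__ = [
    "LossBundle",
    "TrainConfig",
    "AugmentConfig",
    "cgi_loss",
    "augment",
    "train",
]


@dataclass
class LossBundle:
    """The four head losses (bits) and their sum."""

    l_ab: Optional[float]
    l_ac: Optional[float]
    l_abc: float
    l_fusion: Optional[float]
    l_total: float

    def as_dict(self) -> dict:
        return {
            "l_ab": self.l_ab,
            "l_ac": self.l_ac,
            "l_abc": self.l_abc,
            "l_fusion": self.l_fusion,
            "l_total": self.l_total,
        }


@dataclass
class AugmentConfig:
    """Stochastic training-time transforms; probabilities in [0, 1].

    The set follows standard endoscopy practice: random cropping (pad-resize
    to ``crop_scale`` x input then crop back), colour jittering, random
    grayscale, horizontal/vertical flips, and right-angle rotations
    (90/180/270 degrees).
    """

    crop_prob: float = 0.5
    crop_scale: float = 1.14
    color_jitter_prob: float = 0.5
    brightness: float = 0.1
    contrast: float = 0.1
    saturation: float = 0.1
    grayscale_prob: float = 0.1
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    rotation_prob: float = 0.5

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(
            crop_prob=0.0,
            color_jitter_prob=0.0,
            grayscale_prob=0.0,
            hflip_prob=0.0,
            vflip_prob=0.0,
            rotation_prob=0.0,
        )


@dataclass
class TrainConfig:
    batch_size: int = 68
    learning_rate: float = 1e-5
    epochs: int = 1000
    seed: int = 0
    reduction: str = "mean"
    augment: bool = True
    augment_cfg: AugmentConfig = field(default_factory=AugmentConfig)
    use_loss_abc: bool = True  # drop for the "-l_ABC" ablation variant
    loss_eps: float = 1e-7

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def cgi_loss(
    outputs: HeadOutputs,
    labels,
    reduction: str = "mean",
    *,
    use_loss_abc: bool = True,
    eps: float = 1e-7,
) -> tuple[LossBundle, nn.Tensor]:
    """Compute the per-head losses and their sum for one batch.

    Returns the float ``LossBundle`` and the total as a differentiable
    scalar tensor.  Probabilities are clamped at ``eps`` so degenerate 0/1
    outputs stay finite.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.shape[0] != outputs.p_abc.data.shape[0]:
        raise ValueError("need exactly one label per patient in the batch")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"labels must be in {{0,1}}, got {np.unique(labels)}")

    components: dict[str, Optional[nn.Tensor]] = {}
    for name, probs in outputs.heads.items():
        if name == "abc" and not use_loss_abc:
            components[name] = None
            continue
        components[name] = nn.nll_base2(probs, labels, reduction=reduction, eps=eps)

    active = [t for t in components.values() if t is not None]
    total = active[0]
    for t in active[1:]:
        total = total + t

    def _val(name):
        t = components.get(name)
        return t.item() if t is not None else None

    bundle = LossBundle(
        l_ab=_val("ab"),
        l_ac=_val("ac"),
        l_abc=_val("abc") if _val("abc") is not None else 0.0,
        l_fusion=_val("fusion"),
        l_total=total.item(),
    )
    return bundle, total


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def augment(image: np.ndarray, cfg: AugmentConfig, seed: int) -> np.ndarray:
    """Apply the stochastic augmentation set to one HxWx3 image in [0, 1]."""
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float64)
    size = img.shape[0]

    if rng.uniform() < cfg.crop_prob:
        big = int(round(size * cfg.crop_scale))
        enlarged = _sk_resize(img, (big, big), order=1, anti_aliasing=False)
        oy = rng.integers(0, big - size + 1)
        ox = rng.integers(0, big - size + 1)
        img = enlarged[oy : oy + size, ox : ox + size]

    if rng.uniform() < cfg.color_jitter_prob:
        img = img + rng.uniform(-cfg.brightness, cfg.brightness)
        mean = img.mean()
        img = (img - mean) * (1.0 + rng.uniform(-cfg.contrast, cfg.contrast)) + mean
        gray = img.mean(axis=2, keepdims=True)
        img = gray + (img - gray) * (1.0 + rng.uniform(-cfg.saturation, cfg.saturation))

    if rng.uniform() < cfg.grayscale_prob:
        img = np.repeat(img.mean(axis=2, keepdims=True), 3, axis=2)

    if rng.uniform() < cfg.hflip_prob:
        img = img[:, ::-1]
    if rng.uniform() < cfg.vflip_prob:
        img = img[::-1, :]

    if rng.uniform() < cfg.rotation_prob:
        k = int(rng.integers(1, 4))  # 90, 180 or 270 degrees
        img = np.rot90(img, k=k, axes=(0, 1))

    return np.clip(np.ascontiguousarray(img), 0.0, 1.0).astype(image.dtype, copy=False)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def _epoch_aug_seed(base_seed: int, epoch: int, index: int, section: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, epoch, index, section]).generate_state(1)[0]
        % (2**31)
    )


def train(
    model: GSCNet,
    cohort: Cohort,
    cfg: TrainConfig,
    val_cohort: Optional[Cohort] = None,
    threshold: float = 0.5,
) -> tuple[GSCNet, list[dict]]:
    """Minimise the CGI loss end-to-end over the cohort.

    Returns the trained model and a history list with one record per epoch
    (loss components, plus validation accuracy/AUC when ``val_cohort`` is
    given).  Fully reproducible from ``cfg.seed`` on a fixed device class.
    """
    from .evaluation import evaluate_model  # deferred: avoids import cycle

    if len(cohort) == 0:
        raise ValueError("cannot train on an empty cohort")
    labels = cohort.labels
    if len(np.unique(labels)) < 2:
        import warnings

        warnings.warn("training cohort contains a single class", stacklevel=2)

    antrum, body, cardia = cohort.image_batches()
    rng = np.random.default_rng(cfg.seed)
    optim = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[dict] = []

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(cohort))
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = []
            for sec_arr, sec_id in ((antrum, 0), (body, 1), (cardia, 2)):
                ims = sec_arr[idx]
                if cfg.augment:
                    ims = np.stack(
                        [
                            augment(
                                im,
                                cfg.augment_cfg,
                                _epoch_aug_seed(cfg.seed, epoch, int(i), sec_id),
                            )
                            for im, i in zip(ims, idx)
                        ]
                    )
                batch.append(ims)
            outputs = model.forward(*batch)
            bundle, total = cgi_loss(
                outputs,
                labels[idx],
                reduction=cfg.reduction,
                use_loss_abc=cfg.use_loss_abc,
                eps=cfg.loss_eps,
            )
            optim.zero_grad()
            total.backward()
            optim.step()
            for key, value in bundle.as_dict().items():
                if value is not None:
                    sums[key] = sums.get(key, 0.0) + value
            n_batches += 1

        record = {"epoch": epoch}
        record.update({k: v / n_batches for k, v in sums.items()})
        if val_cohort is not None:
            report = evaluate_model(model, val_cohort, threshold=threshold)
            record["val_acc"] = report.accuracy
            record["val_auc"] = report.auc
        history.append(record)
    model.eval()
    return model, history
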