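"""GSCNet: scaling feature fusion (SFF) + section correlation (SC) modules.

The network ingests a patient's three gastric-section endoscopy images
(antrum I^A, body I^B, cardia I^C) and diagnoses CGI.  The SFF module runs
each image through three shared-weight "resizing" sub-networks of different
depth — N_L (large field of view: 7x7 stem + 3 residual stages), N_M (one
pooling block + 3 stages) and N_S (two pooling blocks + 2 stages) — each
capped by squeeze-and-excitation channel attention.  All three reach total
stride 16, so their outputs concatenate per section and are projected to the
scaling fusion features f^A, f^B, f^C (14x14 spatial, 256 channels at the
default 224 input).

The SC module encodes the clinical prior that only antrum-vs-corpus
comparisons matter: heads on the concatenations f^AB = {f^A, f^B},
f^AC = {f^A, f^C} and f^ABC = {f^A, f^B, f^C} (two 3x3 convolutions, global
average pooling, two fully connected layers, 2-way softmax), plus a fusion
classifier c^F over the three penultimate activations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "HeadOutputs",
    "GSCNet",
    "build_model",
    "sff_forward",
    "sc_forward",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

SECTIONS = ("antrum", "body", "cardia")


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``branch_channels`` is the width of the last residual stage; earlier
    stages use branch_channels/4 and branch_channels/2 (64 -> 128 -> 256 at
    the default), mirroring a truncated 18-layer residual backbone with its
    final stage removed so the fused maps keep 14x14 resolution at 224 input.
    The ``use_*`` switches exist for ablation variants: ``use_sff=False``
    keeps only the large-scale branch, ``use_ca=False`` replaces channel
    attention with identity, ``use_sc=False`` collapses the SC module to a
    single head on f^ABC.
    """

    input_size: int = 224
    branch_channels: int = 256
    fusion_channels: int = 256
    se_reduction: int = 16
    sc_conv_channels: tuple[int, int] = (256, 128)
    sc_fc_widths: tuple[int, int] = (128, 64)
    n_classes: int = 2
    init_mode: str = "random-seeded"
    backbone_weights: Optional[str] = None
    use_sff: bool = True
    use_ca: bool = True
    use_sc: bool = True
    dtype: str = "float32"

    def __post_init__(self):
        if self.input_size % 16 != 0:
            raise ValueError(
                f"input_size must be divisible by 16, got {self.input_size}"
            )
        if self.branch_channels % 4 != 0 or self.branch_channels <= 0:
            raise ValueError("branch_channels must be a positive multiple of 4")
        for name in ("fusion_channels", "se_reduction", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.init_mode not in ("random-seeded", "pretrained-backbone"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        self.sc_conv_channels = tuple(self.sc_conv_channels)
        self.sc_fc_widths = tuple(self.sc_fc_widths)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    @property
    def feature_size(self) -> int:
        return self.input_size // 16

    @property
    def stage_widths(self) -> tuple[int, int, int]:
        return (self.branch_channels // 4, self.branch_channels // 2, self.branch_channels)


@dataclass
class HeadOutputs:
    """Per-head class probabilities and penultimate activations for a batch."""

    p_ab: Optional[Tensor]
    p_ac: Optional[Tensor]
    p_abc: Tensor
    p_fusion: Optional[Tensor]
    penultimate: dict = field(default_factory=dict)

    @property
    def heads(self) -> dict[str, Tensor]:
        out = {}
        for name, t in (
            ("ab", self.p_ab),
            ("ac", self.p_ac),
            ("abc", self.p_abc),
            ("fusion", self.p_fusion),
        ):
            if t is not None:
                out[name] = t
        return out

    @property
    def final(self) -> Tensor:
        """The head used for prediction: fusion when present, else the ABC head."""
        return self.p_fusion if self.p_fusion is not None else self.p_abc


def _stage(in_ch, out_ch, stride, n_blocks, rng, dtype):
    blocks = [nn.BasicBlock(in_ch, out_ch, stride, rng=rng, dtype=dtype)]
    for _ in range(n_blocks - 1):
        blocks.append(nn.BasicBlock(out_ch, out_ch, 1, rng=rng, dtype=dtype))
    return nn.Sequential(*blocks)


def _pooling_block(in_ch, out_ch, rng, dtype):
    """3x3 convolution followed by stride-2 max pooling."""
    return nn.Sequential(
        nn.Conv2d(in_ch, out_ch, 3, 1, 1, rng=rng, dtype=dtype),
        nn.BatchNorm2d(out_ch, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool2d(2, 2),
    )


def _attention(channels, cfg, rng, dtype):
    if cfg.use_ca:
        return nn.SqueezeExcite(channels, cfg.se_reduction, rng=rng, dtype=dtype)
    return nn.Identity()


class SCHead(nn.Module):
    """One section-correlation head: 2 convs -> GAP -> 2 FCs -> classifier."""

    def __init__(self, in_channels: int, cfg: ModelConfig, rng, dtype):
        super().__init__()
        c1, c2 = cfg.sc_conv_channels
        w1, w2 = cfg.sc_fc_widths
        self.conv = nn.Sequential(
            nn.Conv2d(in_channels, c1, 3, 1, 1, rng=rng, dtype=dtype),
            nn.BatchNorm2d(c1, dtype=dtype),
            nn.ReLU(),
            nn.Conv2d(c1, c2, 3, 1, 1, rng=rng, dtype=dtype),
            nn.BatchNorm2d(c2, dtype=dtype),
            nn.ReLU(),
        )
        self.pool = nn.GlobalAvgPool2d()
        self.fc1 = nn.Linear(c2, w1, rng=rng, dtype=dtype)
        self.fc2 = nn.Linear(w1, w2, rng=rng, dtype=dtype)
        self.classifier = nn.Linear(w2, cfg.n_classes, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.pool(self.conv(x))
        h = nn.relu(self.fc1(h))
        penult = nn.relu(self.fc2(h))
        return self.classifier(penult), penult


class GSCNet(nn.Module):
    def __init__(self, cfg: ModelConfig, seed: int):
        super().__init__()
        self.cfg = cfg
        self.seed = int(seed)
        dtype = cfg.np_dtype
        rng = np.random.default_rng(self.seed)
        w1, w2, w3 = cfg.stage_widths

        # N_L: 7x7 stride-2 stem + stem max-pool + 3 residual stages, strides (1,2,2)
        self.branch_l = nn.Sequential(
            nn.Conv2d(3, w1, 7, 2, 3, rng=rng, dtype=dtype),
            nn.BatchNorm2d(w1, dtype=dtype),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, 1),
            _stage(w1, w1, 1, 2, rng, dtype),
            _stage(w1, w2, 2, 2, rng, dtype),
            _stage(w2, w3, 2, 2, rng, dtype),
            _attention(w3, cfg, rng, dtype),
        )
        if cfg.use_sff:
            # N_M: one pooling block + 3 residual stages, strides (2,2,2)
            self.branch_m = nn.Sequential(
                _pooling_block(3, w1, rng, dtype),
                _stage(w1, w1, 2, 2, rng, dtype),
                _stage(w1, w2, 2, 2, rng, dtype),
                _stage(w2, w3, 2, 2, rng, dtype),
                _attention(w3, cfg, rng, dtype),
            )
            # N_S: two pooling blocks + 2 residual stages, strides (2,2)
            self.branch_s = nn.Sequential(
                _pooling_block(3, w1, rng, dtype),
                _pooling_block(w1, w1, rng, dtype),
                _stage(w1, w2, 2, 2, rng, dtype),
                _stage(w2, w3, 2, 2, rng, dtype),
                _attention(w3, cfg, rng, dtype),
            )
            n_scales = 3
        else:
            self.branch_m = None
            self.branch_s = None
            n_scales = 1

        # shared 1x1 projection: concatenated scales -> fusion_channels
        self.fusion_proj = nn.Sequential(
            nn.Conv2d(n_scales * w3, cfg.fusion_channels, 1, 1, 0, rng=rng, dtype=dtype),
            nn.BatchNorm2d(cfg.fusion_channels, dtype=dtype),
            nn.ReLU(),
        )

        f = cfg.fusion_channels
        if cfg.use_sc:
            self.head_ab = SCHead(2 * f, cfg, rng, dtype)
            self.head_ac = SCHead(2 * f, cfg, rng, dtype)
            self.head_abc = SCHead(3 * f, cfg, rng, dtype)
            self.fusion_classifier = nn.Linear(
                3 * cfg.sc_fc_widths[1], cfg.n_classes, rng=rng, dtype=dtype
            )
        else:
            self.head_ab = None
            self.head_ac = None
            self.head_abc = SCHead(3 * f, cfg, rng, dtype)
            self.fusion_classifier = None

        if cfg.init_mode == "pretrained-backbone":
            if cfg.backbone_weights is None:
                raise ValueError(
                    "init_mode='pretrained-backbone' requires backbone_weights "
                    "(path to an .npz state file)"
                )
            state = dict(np.load(cfg.backbone_weights))
            self.load_state(state)

    # -- forward passes ------------------------------------------------------

    def _branches(self):
        out = [("L", self.branch_l)]
        if self.cfg.use_sff:
            out += [("M", self.branch_m), ("S", self.branch_s)]
        return out

    def _check_images(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.cfg.np_dtype)
        if x.ndim == 3:
            x = x[None]
        s = self.cfg.input_size
        if x.shape[1:] != (s, s, 3):
            raise ValueError(
                f"expected images of shape ({s}, {s}, 3), got {x.shape[1:]}"
            )
        return x.transpose(0, 3, 1, 2)

    def sff_forward(self, antrum, body, cardia) -> tuple[Tensor, Tensor, Tensor]:
        """Scaling fusion features f^A, f^B, f^C for a batch of triplets.

        Inputs are (N, H, W, 3) arrays in [0, 1].  The three section batches
        are stacked so each shared-weight branch runs once; batch-norm
        statistics therefore pool over sections as well as patients, matching
        the shared-backbone design.
        """
        batches = [self._check_images(im) for im in (antrum, body, cardia)]
        n = batches[0].shape[0]
        if any(b.shape[0] != n for b in batches):
            raise ValueError("section batches must have equal length")
        stacked = Tensor(np.concatenate(batches, axis=0))
        scale_feats = [branch(stacked) for _, branch in self._branches()]
        fused = self.fusion_proj(
            nn.concat(scale_feats, axis=1) if len(scale_feats) > 1 else scale_feats[0]
        )
        f_a, f_b, f_c = _split3(fused, n)
        return f_a, f_b, f_c

    def sc_forward(self, f_a: Tensor, f_b: Tensor, f_c: Tensor) -> HeadOutputs:
        """Section-correlation heads on f^AB, f^AC, f^ABC plus the fusion head."""
        for name, t in (("f_b", f_b), ("f_c", f_c)):
            if t.data.shape != f_a.data.shape:
                raise ValueError(
                    f"{name} spatial/channel shape {t.data.shape} does not match "
                    f"f_a {f_a.data.shape}"
                )
        if not self.cfg.use_sc:
            logits, _ = self.head_abc(nn.concat([f_a, f_b, f_c], axis=1))
            return HeadOutputs(None, None, nn.softmax(logits), None)
        logit_ab, pen_ab = self.head_ab(nn.concat([f_a, f_b], axis=1))
        logit_ac, pen_ac = self.head_ac(nn.concat([f_a, f_c], axis=1))
        logit_abc, pen_abc = self.head_abc(nn.concat([f_a, f_b, f_c], axis=1))
        fusion_in = nn.concat([pen_ab, pen_ac, pen_abc], axis=1)
        logit_f = self.fusion_classifier(fusion_in)
        return HeadOutputs(
            nn.softmax(logit_ab),
            nn.softmax(logit_ac),
            nn.softmax(logit_abc),
            nn.softmax(logit_f),
            penultimate={"ab": pen_ab, "ac": pen_ac, "abc": pen_abc},
        )

    def forward(self, antrum, body, cardia) -> HeadOutputs:
        return self.sc_forward(*self.sff_forward(antrum, body, cardia))


def _split3(t: Tensor, n: int) -> tuple[Tensor, Tensor, Tensor]:
    parts = []
    for i in range(3):
        sl = slice(i * n, (i + 1) * n)
        part = nn.Tensor(t.data[sl])
        if t.requires_grad or t._parents:
            part._parents = (t,)

            def bwd(g, sl=sl, t=t):
                full = np.zeros_like(t.data)
                full[sl] = g
                t._accumulate(full)

            part._backward = bwd
        parts.append(part)
    return tuple(parts)


# -- module-level operation wrappers ----------------------------------------


def build_model(cfg: ModelConfig, seed: int) -> GSCNet:
    """Construct GSCNet with parameters drawn deterministically from ``seed``."""
    return GSCNet(cfg, seed)


def _triplet_arrays(triplet):
    return (
        np.asarray(triplet.antrum_image)[None],
        np.asarray(triplet.body_image)[None],
        np.asarray(triplet.cardia_image)[None],
    )


def sff_forward(model: GSCNet, triplet) -> tuple[Tensor, Tensor, Tensor]:
    return model.sff_forward(*_triplet_arrays(triplet))


def sc_forward(model: GSCNet, f_a, f_b, f_c) -> HeadOutputs:
    return model.sc_forward(f_a, f_b, f_c)


def predict(model: GSCNet, triplet, threshold: float = 0.5) -> tuple[float, int]:
    """CGI probability from the fusion head and its thresholded label.

    Ties at the threshold resolve positive.  Inference runs in eval mode with
    no augmentation, so repeated calls are identical.
    """
    was_training = model.training
    model.eval()
    try:
        outputs = model.forward(*_triplet_arrays(triplet))
    finally:
        model.train(was_training)
    p = float(outputs.final.data[0, 1])
    return p, int(p >= threshold)


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(model: GSCNet, path) -> None:
    state = model.named_state()
    cfg = asdict(model.cfg)
    cfg["sc_conv_channels"] = list(cfg["sc_conv_channels"])
    cfg["sc_fc_widths"] = list(cfg["sc_fc_widths"])
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps({"cfg": cfg, "seed": model.seed}).encode(), dtype=np.uint8
        ),
        **{k: v for k, v in state.items() if k not in ("cfg", "seed")},
    )


def load_checkpoint(path) -> GSCNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    cfg_dict = meta["cfg"]
    cfg_dict["sc_conv_channels"] = tuple(cfg_dict["sc_conv_channels"])
    cfg_dict["sc_fc_widths"] = tuple(cfg_dict["sc_fc_widths"])
    # rebuild without re-triggering a pretrained load; weights come from the file
    cfg_dict = dict(cfg_dict, init_mode="random-seeded", backbone_weights=None)
    model = GSCNet(ModelConfig(**cfg_dict), meta["seed"])
    model.cfg.init_mode = meta["cfg"]["init_mode"]
    model.load_state(state)
    return model
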