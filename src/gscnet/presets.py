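"""Named experiment presets.

``cpu_learning_preset`` is the package's reference benchmark for "does the
network learn the CGI task on synthetic data": uniform AIS/CIS grades,
independent sections, severity gain 0.08, full nuisance defaults, 64-pixel
images and a width-reduced model (stages 16/32/64), sized so a full train +
evaluate cycle runs in minutes on one CPU core.

``cpu_ablation_preset`` drives paired variant-comparison runs: same imaging
conditions with a further width-reduced model (stages 8/16/32) and
section-correlated labels (patient_correlation 0.8).  The correlation
matters for the comparison's meaning: with independent sections the pairwise
antrum-body / antrum-cardia heads are supervised toward a label that depends
on a section they cannot see, so their losses carry irreducible error;
coupled sections make the pairwise supervision informative, which is the
regime the section-correlation design targets (clinically, gastric
inflammation is strongly stomach-wide).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ModelConfig
from .synthetic import CohortConfig, RenderConfig
from .training import TrainConfig

__all__ = ["LearningPreset", "cpu_learning_preset", "cpu_ablation_preset"]


@dataclass
class LearningPreset:
    n_train: int
    n_test: int
    render: RenderConfig
    model: ModelConfig
    train: TrainConfig
    patient_correlation: float = 0.0
    seed_offset: int = 101  # cohort seeds: seed+offset (train), seed+2*offset (test)

    def cohorts(self, seed: int):
        from .synthetic import generate_cohort

        train_cfg = CohortConfig(
            n_patients=self.n_train,
            seed=seed + self.seed_offset,
            patient_correlation=self.patient_correlation,
        )
        test_cfg = CohortConfig(
            n_patients=self.n_test,
            seed=seed + 2 * self.seed_offset,
            patient_correlation=self.patient_correlation,
        )
        return (
            generate_cohort(train_cfg, self.render),
            generate_cohort(test_cfg, self.render),
        )


def cpu_learning_preset(seed: int = 0) -> LearningPreset:
    """240 train / 80 test patients, 64px, 20 augmented epochs, batch 32."""
    return LearningPreset(
        n_train=240,
        n_test=80,
        render=RenderConfig(image_size=64),
        model=ModelConfig(
            input_size=64,
            branch_channels=64,
            fusion_channels=64,
            se_reduction=8,
            sc_conv_channels=(64, 32),
            sc_fc_widths=(32, 16),
        ),
        train=TrainConfig(
            batch_size=32, learning_rate=5e-4, epochs=20, seed=seed, augment=True
        ),
    )


def cpu_ablation_preset(seed: int = 0) -> LearningPreset:
    """96 train / 48 test patients, correlated sections, 20 epochs."""
    return LearningPreset(
        n_train=96,
        n_test=48,
        render=RenderConfig(image_size=64),
        model=ModelConfig(
            input_size=64,
            branch_channels=32,
            fusion_channels=32,
            se_reduction=4,
            sc_conv_channels=(32, 16),
            sc_fc_widths=(16, 16),
        ),
        train=TrainConfig(
            batch_size=32, learning_rate=5e-4, epochs=20, seed=seed, augment=False
        ),
        patient_correlation=0.8,
        seed_offset=303,
    )
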