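"""Synthetic endoscopic cohort simulator.

Real CGI cohorts are private clinical data, so this module fabricates labelled
patient triplets whose appearance encodes what the network must learn:

* each gastric section has a distinct base mucosa hue;
* inflammation severity (the per-section IS, 0-6) raises the red channel
  globally (``severity_gain`` per IS unit, with a matching green-channel drop
  so the redness contrast survives global illumination shifts) and sprinkles
  bright-red lesion speckles (``lesion_rate`` expected lesions per IS unit);
* nuisance factors emulate endoscopy acquisition: multiplicative scale jitter
  (camera-to-mucosa distance) via centre zoom-crop-resize, viewing-angle
  rotation jitter, a global illumination offset, and pixel noise.

Labels are never stored independently: the CGI label of every generated
patient is the decision rule applied to its sampled AIS/CIS grades, so the
simulator and the rule cannot disagree by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.special import ndtr

from .cgi_rule import SectionScores, diagnose_cgi

__all__ = [
    "RenderConfig",
    "CohortConfig",
    "PatientTriplet",
    "Cohort",
    "sample_scores",
    "render_section_image",
    "generate_cohort",
    "cgi_positive_probability",
]

SECTIONS = ("antrum", "body", "cardia")

MANIFEST_COLUMNS = [
    "patient_id",
    "antrum_path",
    "body_path",
    "cardia_path",
    "ais_antrum",
    "cis_antrum",
    "ais_body",
    "cis_body",
    "ais_cardia",
    "cis_cardia",
    "is_antrum",
    "is_body",
    "is_cardia",
    "cgi",
]


@dataclass
class RenderConfig:
    """Appearance and nuisance parameters for section-image rendering.

    Channel units are fractions of full scale in [0, 1].  Defaults keep the
    severity signal (0.08 per IS unit, up to 0.48 across the 0-6 range) well
    above the illumination (0.05) and pixel (0.02) noise scales.
    """

    image_size: int = 224
    base_hue: dict = field(
        default_factory=lambda: {"antrum": 0.03, "body": 0.07, "cardia": 0.98}
    )
    base_saturation: float = 0.45
    base_value: float = 0.55
    texture_sigma: float = 0.06  # low-frequency mucosa texture amplitude
    severity_gain: float = 0.08  # red-channel increment per IS unit
    lesion_rate: float = 1.5  # expected lesion count per IS unit
    lesion_radius_range: tuple[float, float] = (0.02, 0.05)  # fraction of image side
    scale_jitter_range: tuple[float, float] = (0.7, 1.3)
    rotation_range: float = 15.0  # degrees, uniform +/-
    illumination_sigma: float = 0.05
    noise_sigma: float = 0.02

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.severity_gain < 0:
            raise ValueError("severity_gain must be >= 0")
        lo, hi = self.scale_jitter_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("scale_jitter_range must be positive and ordered")
        missing = set(SECTIONS) - set(self.base_hue)
        if missing:
            raise ValueError(f"base_hue missing sections: {sorted(missing)}")

    def without_nuisance(self) -> "RenderConfig":
        return dataclasses.replace(
            self,
            scale_jitter_range=(1.0, 1.0),
            rotation_range=0.0,
            illumination_sigma=0.0,
            noise_sigma=0.0,
        )


@dataclass
class CohortConfig:
    """Cohort-level sampling parameters.

    ``grade_distribution`` gives categorical weights over AIS/CIS grades
    {0,1,2,3}, shared by all six grades; ``patient_correlation`` in [0, 1]
    couples a patient's six grades through a shared latent propensity
    (Gaussian copula), 0 meaning independent draws.
    """

    n_patients: int = 100
    grade_distribution: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    patient_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.grade_distribution, dtype=float)
        if w.shape != (4,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError(
                "grade_distribution must be 4 nonnegative weights summing to 1"
            )
        if not 0.0 <= self.patient_correlation <= 1.0:
            raise ValueError("patient_correlation must be in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        self.grade_distribution = tuple(float(x) for x in w)


@dataclass
class PatientTriplet:
    """Three section images with optional histology scores and the CGI label."""

    patient_id: str
    antrum_image: np.ndarray
    body_image: np.ndarray
    cardia_image: np.ndarray
    scores: Optional[SectionScores] = None
    label: Optional[int] = None

    def __post_init__(self):
        shapes = {
            self.antrum_image.shape,
            self.body_image.shape,
            self.cardia_image.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"section images must share dimensions, got {shapes}")
        if self.scores is not None:
            derived = diagnose_cgi(self.scores.profile())
            if self.label is None:
                self.label = derived
            elif self.label != derived:
                raise ValueError(
                    f"label {self.label} inconsistent with scores (rule says {derived})"
                )


class Cohort:
    """In-memory handle over a list of PatientTriplets plus the manifest frame."""

    def __init__(self, patients: list[PatientTriplet], manifest: pd.DataFrame):
        self.patients = patients
        self.manifest = manifest

    def __len__(self) -> int:
        return len(self.patients)

    def __getitem__(self, i) -> PatientTriplet:
        return self.patients[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patients], dtype=int)

    def image_batches(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.stack([p.antrum_image for p in self.patients]),
            np.stack([p.body_image for p in self.patients]),
            np.stack([p.cardia_image for p in self.patients]),
        )


# ---------------------------------------------------------------------------
# Score sampling
# ---------------------------------------------------------------------------

GRADE_FIELDS = (
    "ais_antrum",
    "cis_antrum",
    "ais_body",
    "cis_body",
    "ais_cardia",
    "cis_cardia",
)


def sample_scores(n: int, cfg: CohortConfig) -> list[SectionScores]:
    """Draw ``n`` AIS/CIS score records from the cohort's grade distribution.

    With patient_correlation rho > 0 a patient-level latent z couples the six
    grades: each grade's Gaussian variate is sqrt(rho)*z + sqrt(1-rho)*eps,
    mapped through the distribution's quantile function, so rho=1 makes all
    six grades move together and rho=0 recovers independent sampling.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    w = np.asarray(cfg.grade_distribution)
    cum = np.cumsum(w)
    rho = cfg.patient_correlation
    z = rng.standard_normal(n)
    eps = rng.standard_normal((n, 6))
    v = np.sqrt(rho) * z[:, None] + np.sqrt(1.0 - rho) * eps
    u = ndtr(v)  # Gaussian copula: uniform marginals
    grades = np.searchsorted(cum, u, side="left").clip(0, 3)
    return [
        SectionScores(**{f: int(g) for f, g in zip(GRADE_FIELDS, row)})
        for row in grades
    ]


def cgi_positive_probability(cfg: CohortConfig) -> float:
    """Exact CGI-positive probability induced by the grade distribution.

    Enumerates all 4^6 grade combinations with their product probabilities
    (valid for patient_correlation = 0) and pushes each through the score
    combination and decision rule.
    """
    w = np.asarray(cfg.grade_distribution)
    # P(IS = a + c) for one section
    p_is = np.zeros(7)
    for a in range(4):
        for c in range(4):
            p_is[a + c] += w[a] * w[c]
    total = 0.0
    from .cgi_rule import InflammationProfile

    for ia in range(7):
        for ib in range(7):
            for ic in range(7):
                if diagnose_cgi(InflammationProfile(ia, ib, ic)):
                    total += p_is[ia] * p_is[ib] * p_is[ic]
    return float(total)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    rgb = [
        (v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q),
    ][i]
    return np.array(rgb)


def _zoom_crop_resize(img: np.ndarray, factor: float) -> np.ndarray:
    """Centre zoom by ``factor`` (>1 = closer camera) keeping the output size."""
    if factor == 1.0:
        return img
    size = img.shape[0]
    zoomed = ndimage.zoom(img, (factor, factor, 1.0), order=1, mode="nearest")
    zs = zoomed.shape[0]
    if zs >= size:
        off = (zs - size) // 2
        return zoomed[off : off + size, off : off + size]
    out = np.empty((size, size, 3), dtype=img.dtype)
    pad = (size - zs) // 2
    out[:] = zoomed.mean(axis=(0, 1))
    out[pad : pad + zs, pad : pad + zs] = zoomed
    return out


def render_section_image(
    section: str, is_score: int, cfg: RenderConfig, seed: int
) -> np.ndarray:
    """Render one section image encoding inflammation severity ``is_score``.

    Pipeline: base hue field + smooth texture -> severity (redness shift and
    Poisson lesion speckles) -> nuisance (zoom, rotation, illumination,
    noise) -> clip to [0, 1].  Deterministic in ``seed``.
    """
    if section not in SECTIONS:
        raise ValueError(f"unknown section {section!r}; expected one of {SECTIONS}")
    if not (isinstance(is_score, (int, np.integer)) and 0 <= is_score <= 6):
        raise ValueError(f"is_score must be an integer in 0..6, got {is_score!r}")
    rng = np.random.default_rng(seed)
    size = cfg.image_size
    base = _hsv_to_rgb(cfg.base_hue[section], cfg.base_saturation, cfg.base_value)
    img = np.broadcast_to(base, (size, size, 3)).astype(np.float64).copy()

    # smooth mucosa texture (same draw regardless of severity)
    texture = ndimage.gaussian_filter(
        rng.standard_normal((size, size)), sigma=size / 16.0
    )
    tmax = np.abs(texture).max()
    if tmax > 0:
        texture = texture / tmax * cfg.texture_sigma
    img += texture[:, :, None]

    # severity: global redness shift with opposing green shift, so the
    # red-green contrast survives global illumination offsets
    img[:, :, 0] += cfg.severity_gain * is_score
    img[:, :, 1] -= 0.5 * cfg.severity_gain * is_score

    # lesion speckles: count scales with severity
    lam = cfg.lesion_rate * is_score
    n_lesions = int(rng.poisson(lam)) if lam > 0 else 0
    if n_lesions:
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(n_lesions):
            cy, cx = rng.uniform(0, size, 2)
            r = rng.uniform(*cfg.lesion_radius_range) * size
            blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r * r)))
            img[:, :, 0] += 0.25 * blob
            img[:, :, 1] -= 0.10 * blob

    # nuisance: scale jitter, rotation, illumination offset, pixel noise
    lo, hi = cfg.scale_jitter_range
    factor = float(rng.uniform(lo, hi))
    img = _zoom_crop_resize(img, factor)
    angle = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    if angle != 0.0:
        img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1, mode="reflect")
    if cfg.illumination_sigma > 0:
        img += rng.normal(0.0, cfg.illumination_sigma)
    if cfg.noise_sigma > 0:
        img += rng.normal(0.0, cfg.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def _image_seed(cohort_seed: int, patient_index: int, section: str) -> int:
    """Stable per-image seed independent of generation order."""
    ss = np.random.SeedSequence(
        [int(cohort_seed), int(patient_index), SECTIONS.index(section)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    cfg: CohortConfig,
    render_cfg: RenderConfig,
    out_dir: Optional[str | Path] = None,
) -> Cohort:
    """Generate a labelled cohort; optionally write PNGs and a CSV manifest.

    With ``out_dir=None`` the cohort stays in memory (paths in the manifest
    are empty strings).  The whole cohort is a pure function of the two
    configs.
    """
    scores_list = sample_scores(cfg.n_patients, cfg)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)

    patients = []
    rows = []
    for idx, scores in enumerate(scores_list):
        pid = f"P{idx:05d}"
        profile = scores.profile()
        images = {}
        paths = {}
        for section, is_val in zip(
            SECTIONS, (profile.is_antrum, profile.is_body, profile.is_cardia)
        ):
            img = render_section_image(
                section, is_val, render_cfg, _image_seed(cfg.seed, idx, section)
            )
            images[section] = img.astype(np.float32)
            if out_path is not None:
                rel = f"images/{pid}_{section}.png"
                Image.fromarray(
                    (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
                ).save(out_path / rel)
                paths[section] = rel
            else:
                paths[section] = ""
        triplet = PatientTriplet(
            pid, images["antrum"], images["body"], images["cardia"], scores=scores
        )
        patients.append(triplet)
        rows.append(
            {
                "patient_id": pid,
                "antrum_path": paths["antrum"],
                "body_path": paths["body"],
                "cardia_path": paths["cardia"],
                **{f: getattr(scores, f) for f in GRADE_FIELDS},
                "is_antrum": profile.is_antrum,
                "is_body": profile.is_body,
                "is_cardia": profile.is_cardia,
                "cgi": triplet.label,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return Cohort(patients, manifest)
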