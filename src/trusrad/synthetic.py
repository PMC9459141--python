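"""Synthetic study data with known ground truth.

Every input the pipeline consumes can be generated here: two-class
radiomic feature tables with a small informative subset, paired rater
tables with a known intraclass correlation, textured masked volumes whose
classes differ in heterogeneity, and binary reader verdicts with stated
sensitivity and specificity. All generators are pure functions of their
configuration and seed.

These emulate the statistical structure of a radiomics study — correlated
feature blocks, mean-shifted informative features, rater measurement noise,
imperfect readers — not prostate anatomy, speckle physics, or video
temporal dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import ROIVolume

__all__ = [
    "CohortConfig",
    "RaterNoiseConfig",
    "ReaderProfile",
    "gen_feature_table",
    "gen_rater_pairs",
    "gen_reader_calls",
    "gen_roi_volumes",
]


@dataclass(frozen=True)
class CohortConfig:
    """Two-class feature-table cohort.

    ``effect_size`` is the mean shift of each informative feature in the
    malignant class, in units of the within-class standard deviation.
    Features are arranged in equicorrelated blocks of ``block_size`` with
    within-block correlation ``block_rho``. With ``lognormal=True`` the
    (shifted) Gaussian features are exponentiated, giving skewed marginals
    that exercise the rank-based screen.
    """

    n_benign: int = 113
    n_malignant: int = 118
    p_features: int = 100
    k_informative: int = 10
    effect_size: float = 1.0
    block_rho: float = 0.3
    block_size: int = 10
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("both class counts must be >= 1")
        if not 0 <= self.k_informative <= self.p_features:
            raise ValueError("need 0 <= k_informative <= p_features")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass(frozen=True)
class RaterNoiseConfig:
    """Variance components of a two-rater reproducibility experiment.

    Per feature, each subject has a shared latent effect with SD
    ``sigma_subject``; each rater adds independent measurement noise with
    SD ``sigma_noise``. The implied true intraclass correlation is
    ``sigma_subject**2 / (sigma_subject**2 + sigma_noise**2)``.
    """

    sigma_subject: float = 1.0
    sigma_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_subject < 0 or self.sigma_noise < 0:
            raise ValueError("variance components must be >= 0")

    @property
    def true_icc(self) -> float:
        tot = self.sigma_subject**2 + self.sigma_noise**2
        return 0.0 if tot == 0 else self.sigma_subject**2 / tot


@dataclass(frozen=True)
class ReaderProfile:
    """An imaging reader reduced to fixed sensitivity and specificity.

    Default profiles mirror a junior (< 5 y experience) and a senior
    (> 10 y) radiologist reading MRI.
    """

    sensitivity: float
    specificity: float
    tier: str = "senior"

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity):
            if not 0 <= v <= 1:
                raise ValueError("sensitivity/specificity must be in [0, 1]")
        if self.tier not in ("junior", "senior"):
            raise ValueError("tier must be 'junior' or 'senior'")


#: Test-set operating points of the two reader tiers.
JUNIOR_READER = ReaderProfile(sensitivity=0.71, specificity=0.60, tier="junior")
SENIOR_READER = ReaderProfile(sensitivity=0.63, specificity=0.87, tier="senior")


def gen_feature_table(config: CohortConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a labelled two-class feature table.

    Returns ``(table, informative_idx)``: a DataFrame with columns
    ``feat_0000 ...`` plus a final ``label`` column (0 benign, 1 malignant),
    and the indices of the truly informative features (the first
    ``k_informative`` columns). Within-class marginals have unit SD, so
    ``effect_size`` is directly in SD units.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_benign + config.n_malignant
    p = config.p_features
    labels = np.concatenate([
        np.zeros(config.n_benign, dtype=int),
        np.ones(config.n_malignant, dtype=int),
    ])
    # equicorrelated blocks via a one-factor construction:
    # x = sqrt(rho) * z_block + sqrt(1-rho) * eps  (unit variance)
    n_blocks = -(-p // config.block_size)
    z = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    block_of = np.arange(p) // config.block_size
    x = np.sqrt(config.block_rho) * z[:, block_of] + np.sqrt(1 - config.block_rho) * eps
    informative = np.arange(config.k_informative)
    x[np.ix_(labels == 1, informative)] += config.effect_size
    if config.lognormal:
        x = np.exp(x)
    cols = [f"feat_{j:04d}" for j in range(p)]
    table = pd.DataFrame(x, columns=cols)
    table["label"] = labels
    return table, informative


def gen_rater_pairs(
    config: RaterNoiseConfig, n_subjects: int, n_features: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired rater tables for a reproducibility (ICC) experiment.

    Subject effects are shared across raters; measurement noise is drawn
    independently per rater. With ``sigma_noise == 0`` the two tables are
    identical and the estimated ICC of every feature is 1.
    """
    if n_subjects < 3:
        raise ValueError("need >= 3 subjects for a meaningful ICC estimate")
    rng = np.random.default_rng(config.seed)
    subject = config.sigma_subject * rng.standard_normal((n_subjects, n_features))
    noise_a = config.sigma_noise * rng.standard_normal((n_subjects, n_features))
    noise_b = config.sigma_noise * rng.standard_normal((n_subjects, n_features))
    cols = [f"feat_{j:04d}" for j in range(n_features)]
    return (
        pd.DataFrame(subject + noise_a, columns=cols),
        pd.DataFrame(subject + noise_b, columns=cols),
    )


def gen_reader_calls(
    labels: np.ndarray, profile: ReaderProfile, seed: int
) -> np.ndarray:
    """Binary reader verdicts with the profile's operating point.

    Each case is judged independently:
    P(call=1 | malignant) = sensitivity, P(call=0 | benign) = specificity.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    rng = np.random.default_rng(seed)
    u = rng.random(labels.shape)
    calls = np.where(labels == 1, u < profile.sensitivity, u >= profile.specificity)
    return calls.astype(int)


def gen_roi_volumes(
    n_per_class: int,
    shape: tuple[int, int, int] = (24, 24, 24),
    smooth_sigma: float = 2.0,
    heterogeneity: float = 25.0,
    base_level: float = 120.0,
    base_amplitude: float = 40.0,
    seed: int = 0,
) -> list[tuple[ROIVolume, int]]:
    """Textured masked volumes whose classes differ in heterogeneity.

    Benign volumes are a smooth correlated Gaussian field (white noise
    smoothed with a Gaussian kernel of SD ``smooth_sigma`` voxels, then
    scaled to a grayscale dynamic range around ``base_level``). Malignant
    volumes add an unsmoothed high-frequency component of SD
    ``heterogeneity`` gray levels, so texture features — not the mean —
    separate the classes. Each volume carries a centred ellipsoidal mask
    with semi-axes 0.38 of the extents.
    """
    if any(s < 8 for s in shape):
        raise ValueError(f"every extent must be >= 8, got {shape}")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.indices(shape).astype(float)
    centre = [(s - 1) / 2 for s in shape]
    semi = [0.38 * s for s in shape]
    mask = sum(((grid[a] - centre[a]) / semi[a]) ** 2 for a in range(3)) <= 1.0
    out: list[tuple[ROIVolume, int]] = []
    for label in (0, 1):
        for _ in range(n_per_class):
            field = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_sigma)
            field = field / field.std() * base_amplitude + base_level
            if label == 1:
                field = field + heterogeneity * rng.standard_normal(shape)
            field = np.clip(field, 0.0, 255.0)
            out.append((ROIVolume(field, mask), label))
    return out
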