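"""Simulated study cohorts: covariates, per-layer intensities, rescan pairs.

The generator emulates the covariate structure of a healthy-adult normative
OCT study: ages drawn by decade with the observed group weights (mean ~46.9 y,
SD ~16.9 y), sex-specific height/weight and axial length, a device
image-quality score around 58 +/- 4.4, and optic-disc covariates that are
consumed but carry no true effect. Per-layer mean intensity follows a linear
model

    intensity = mu + beta_age * sd_y * z(age) + beta_q * sd_y * z(imageQ) + eps

with standardized coefficients signed as observed in normal eyes: age effects
negative from RNFL through the photoreceptor layer and positive for RPE;
image-quality effects positive for every layer. Covariates are drawn
independently (except height/weight/axial length vs sex), so the univariate
correlation of each generated layer equals its standardized beta.

Residual SDs are set so the total per-layer variance matches the normative
between-subject SD. An optional equicorrelation of residuals across layers
models shared signal-strength variation.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .layers import LAYER_NAMES

#: normative per-layer mean and between-subject SD (AU, 16-bit scale)
LAYER_MEAN_AU: Dict[str, float] = {
    "RNFL": 31558.68, "GCL": 26653.71, "IPL": 26677.85, "INL": 23538.66,
    "OPL": 24824.14, "ONL": 21381.69, "PR": 31759.63, "RPE": 34677.2,
}
LAYER_SD_AU: Dict[str, float] = {
    "RNFL": 1097.91, "GCL": 896.17, "IPL": 903.37, "INL": 875.85,
    "OPL": 933.38, "ONL": 794.03, "PR": 1444.96, "RPE": 695.81,
}
#: standardized effects of age and image quality per layer
BETA_AGE: Dict[str, float] = {
    "RNFL": -0.517, "GCL": -0.380, "IPL": -0.419, "INL": -0.390,
    "OPL": -0.414, "ONL": -0.248, "PR": -0.242, "RPE": 0.287,
}
BETA_IMAGEQ: Dict[str, float] = {
    "RNFL": 0.673, "GCL": 0.753, "IPL": 0.792, "INL": 0.831,
    "OPL": 0.834, "ONL": 0.851, "PR": 0.553, "RPE": 0.503,
}

AGE_MEAN, AGE_SD = 46.90, 16.87
IMAGEQ_MEAN, IMAGEQ_SD = 58.19, 4.39

COVARIATES = ["age", "height", "weight", "se", "axial_length", "image_q",
              "disc_area", "rd_ratio"]


@dataclasses.dataclass
class CohortModel:
    """Covariate distributions and the per-layer intensity model."""

    # decade bins [lo, hi) and their sampling weights
    age_bins: Tuple[Tuple[float, float], ...] = (
        (20, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 80))
    age_weights: Tuple[float, ...] = (45, 46, 36, 40, 33, 31)
    male_p: float = 102 / 231
    height_by_sex: Dict[str, Tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {"M": (168.99, 5.40), "F": (156.98, 4.88)})
    weight_by_sex: Dict[str, Tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {"M": (66.36, 9.20), "F": (54.84, 9.31)})
    axial_by_sex: Dict[str, Tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {"M": (23.88, 1.03), "F": (23.40, 1.11)})
    se_dist: Tuple[float, float] = (-0.67, 1.91)
    imageq_dist: Tuple[float, float] = (IMAGEQ_MEAN, IMAGEQ_SD)
    disc_area_dist: Tuple[float, float] = (2.27, 0.41)
    rd_ratio_dist: Tuple[float, float] = (0.66, 0.21)
    right_eye_p: float = 113 / 231

    layer_mean: Dict[str, float] = dataclasses.field(default_factory=lambda: dict(LAYER_MEAN_AU))
    layer_sd: Dict[str, float] = dataclasses.field(default_factory=lambda: dict(LAYER_SD_AU))
    beta_age: Dict[str, float] = dataclasses.field(default_factory=lambda: dict(BETA_AGE))
    beta_imageq: Dict[str, float] = dataclasses.field(default_factory=lambda: dict(BETA_IMAGEQ))
    residual_corr: float = 0.0   # equicorrelation of residuals across layers

    def residual_sd(self, layer: str) -> float:
        explained = self.beta_age[layer] ** 2 + self.beta_imageq[layer] ** 2
        rest = max(1.0 - explained, 0.0)
        if rest <= 0:
            raise ValueError(f"layer {layer}: standardized effects leave no residual variance")
        return self.layer_sd[layer] * float(np.sqrt(rest))

    def predicted(self, layer: str, age, image_q):
        """Linear predictor (no residual) for one layer."""
        z_age = (np.asarray(age) - AGE_MEAN) / AGE_SD
        z_q = (np.asarray(image_q) - IMAGEQ_MEAN) / IMAGEQ_SD
        return (self.layer_mean[layer]
                + self.beta_age[layer] * self.layer_sd[layer] * z_age
                + self.beta_imageq[layer] * self.layer_sd[layer] * z_q)


def generate_cohort(model: CohortModel, n: int, seed: int) -> pd.DataFrame:
    """Draw a cohort table of covariates and per-layer intensities.

    Ages come from the decade-weighted bins (uniform within a decade), all in
    [18, 90]; refuses n < 10 (too small for any of the downstream statistics).
    """
    if n < 10:
        raise ValueError("cohort size must be at least 10")
    rng = np.random.default_rng(seed)
    bins = np.asarray(model.age_bins, dtype=float)
    wts = np.asarray(model.age_weights, dtype=float)
    which = rng.choice(len(bins), size=n, p=wts / wts.sum())
    age = rng.uniform(bins[which, 0], bins[which, 1])

    male = rng.random(n) < model.male_p
    sex = np.where(male, "M", "F")

    def by_sex(table):
        mu = np.where(male, table["M"][0], table["F"][0])
        sd = np.where(male, table["M"][1], table["F"][1])
        return rng.normal(mu, sd)

    df = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "sex": sex,
        "age": age,
        "height": by_sex(model.height_by_sex),
        "weight": by_sex(model.weight_by_sex),
        "se": rng.normal(*model.se_dist, n),
        "axial_length": by_sex(model.axial_by_sex),
        "image_q": rng.normal(*model.imageq_dist, n),
        "disc_area": rng.normal(*model.disc_area_dist, n),
        "rd_ratio": np.clip(rng.normal(*model.rd_ratio_dist, n), 0.02, 1.0),
        "laterality": np.where(rng.random(n) < model.right_eye_p, "OD", "OS"),
    })

    shared = rng.normal(0.0, 1.0, n)
    rho = model.residual_corr
    for layer in LAYER_NAMES:
        res_sd = model.residual_sd(layer)
        eps = (np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(0.0, 1.0, n)) * res_sd
        df[layer] = model.predicted(layer, df["age"], df["image_q"]) + eps
    return df


def encoded_layer_means(model: CohortModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """The per-subject layer intensities the cohort table carries (truth)."""
    return cohort[["subject_id"] + LAYER_NAMES].copy()


def simulate_icc_pairs(n_subjects: int, true_icc: float, seed: int,
                       between_sd: float = 1000.0, rater_sd: float = 0.0,
                       grand_mean: float = 30000.0) -> np.ndarray:
    """Two-operator measurement pairs with a known intraclass correlation.

    The generating model is the two-way random-effects decomposition
    x_ij = mu + s_i + r_j + e_ij with true ICC =
    var_s / (var_s + var_r + var_e); the error SD is solved from the target.
    """
    if not 0 < true_icc < 1:
        raise ValueError("true ICC must be in (0, 1)")
    var_s = between_sd**2
    var_r = rater_sd**2
    var_e = var_s / true_icc - var_s - var_r
    if var_e <= 0:
        raise ValueError("rater variance too large for the requested ICC")
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, between_sd, (n_subjects, 1))
    r = rng.normal(0.0, rater_sd, (1, 2))
    e = rng.normal(0.0, np.sqrt(var_e), (n_subjects, 2))
    return grand_mean + s + r + e


def phantom_spec_for_subject(base_spec, row: pd.Series):
    """Phantom spec whose encoded layer means equal one cohort row's values."""
    from .phantom import spec_with_layer_means

    targets = {layer: float(row[layer]) for layer in LAYER_NAMES}
    spec = spec_with_layer_means(base_spec, targets)
    return dataclasses.replace(spec, laterality=str(row.get("laterality", "OD")),
                               image_quality=float(row.get("image_q", 60.0)))
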