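"""Synthetic NSCLC cohorts with known survival structure.

Emulates the covariate marginals of an early stage (IA-IIB) surgical NSCLC
cohort and generates proportional-hazards survival with administrative
censoring, so that the whole graph-survival pipeline can be exercised and
validated without patient data.  The generative model is:

* clinical covariates drawn independently from configurable marginals
  (defaults follow a large published early stage cohort: 59.2% male,
  stage mix 46.4/35.6/7.8/10.2%, mean age 60.6);
* a standard-normal latent image score ``z`` per patient, representing the
  survival-relevant signal a learned image featurizer would extract;
* log hazard = beta_stage * stage_ordinal + beta_image * z;
* overall-survival times Weibull with that log relative hazard; a second
  independent Weibull recurrence channel gives recurrence-free survival as
  the earlier of recurrence and death;
* administrative censoring at a fixed follow-up horizon;
* node features = Gaussian noise in which the first ``n_informative``
  coordinates are mean-shifted by ``z``.

Default Weibull parameters (shape 1.3, OS scale 253 months, recurrence
scale 785.9 months) were calibrated by simulation so the default cohort has
approximately 78.2% 5-year OS and 74.2% 5-year RFS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .preprocess import TumorVolume
from .records import HISTOLOGIES, LOBES, PatientRecord, SEXES, STAGES


class CohortSpecError(ValueError):
    pass


def _check_probs(name: str, p, k: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (k,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise CohortSpecError(f"{name} must be {k} non-negative probabilities summing to 1, got {p}")
    return p


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``effect_sizes`` are log-hazard coefficients (stage ordinal, latent
    image score).  ``image_stage_dependence`` in [-1, 1] optionally couples
    the latent image score to the stage ordinal (0 = independent channels).
    """

    n_patients: int = 400
    p_male: float = 0.592
    age_mean: float = 60.6
    age_sd: float = 8.7
    histology_probs: Tuple[float, ...] = (0.724, 0.229, 0.047)
    lobe_probs: Tuple[float, ...] = (0.257, 0.141, 0.338, 0.098, 0.166)
    stage_probs: Tuple[float, ...] = (0.464, 0.356, 0.078, 0.102)
    feature_dim: int = 32
    n_informative: int = 8
    effect_sizes: Tuple[float, float] = (0.4, 0.5)
    baseline_shape: float = 1.3
    baseline_scale: float = 253.0
    rfs_scale: float = 785.9
    admin_censor_time: float = 84.0
    image_stage_dependence: float = 0.0
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_patients < 1:
            raise CohortSpecError("n_patients must be positive")
        if not 0.0 <= self.p_male <= 1.0:
            raise CohortSpecError("p_male must be a probability")
        _check_probs("histology_probs", self.histology_probs, len(HISTOLOGIES))
        _check_probs("lobe_probs", self.lobe_probs, len(LOBES))
        _check_probs("stage_probs", self.stage_probs, len(STAGES))
        if self.feature_dim < 1 or not 0 <= self.n_informative <= self.feature_dim:
            raise CohortSpecError("need 0 <= n_informative <= feature_dim, feature_dim >= 1")
        if self.admin_censor_time <= 0:
            raise CohortSpecError("admin_censor_time must be > 0")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0 or self.rfs_scale <= 0:
            raise CohortSpecError("Weibull parameters must be positive")
        if not -1.0 <= self.image_stage_dependence <= 1.0:
            raise CohortSpecError("image_stage_dependence must lie in [-1, 1]")
        return self


@dataclass
class SyntheticCohort:
    """A generated cohort: records, node features, and the true log-hazard."""

    records: List[PatientRecord]
    features: np.ndarray
    latent_risk: np.ndarray
    latent_image_score: np.ndarray
    seed: int

    def __post_init__(self):
        n = len(self.records)
        if self.features.shape[0] != n or self.latent_risk.shape != (n,):
            raise CohortSpecError("features/latent_risk do not align with records")
        if not np.all(np.isfinite(self.latent_risk)):
            raise CohortSpecError("latent_risk must be finite")

    @property
    def n(self) -> int:
        return len(self.records)


def _weibull_ph_times(rng: np.random.Generator, shape: float, scale: float,
                      log_hazard: np.ndarray) -> np.ndarray:
    # Inverse-CDF sampling of T with S(t|x) = exp(-(t/scale)^shape * e^lp)
    u = rng.random(log_hazard.size)
    return scale * (-np.log(u) / np.exp(log_hazard)) ** (1.0 / shape)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a reproducible synthetic cohort from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    sex = np.where(rng.random(n) < spec.p_male, "male", "female")
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 95.0)
    histology = rng.choice(HISTOLOGIES, n, p=spec.histology_probs)
    lobe = rng.choice(LOBES, n, p=spec.lobe_probs)
    stage_idx = rng.choice(len(STAGES), n, p=spec.stage_probs)

    rho = spec.image_stage_dependence
    eps = rng.standard_normal(n)
    if rho != 0.0:
        s_std = (stage_idx - stage_idx.mean()) / max(stage_idx.std(), 1e-12)
        z = rho * s_std + math.sqrt(1.0 - rho * rho) * eps
    else:
        z = eps

    beta_stage, beta_image = spec.effect_sizes
    latent_risk = beta_stage * stage_idx + beta_image * z

    t_os = _weibull_ph_times(rng, spec.baseline_shape, spec.baseline_scale, latent_risk)
    t_rec = _weibull_ph_times(rng, spec.baseline_shape, spec.rfs_scale, latent_risk)
    t_rfs = np.minimum(t_os, t_rec)

    c = spec.admin_censor_time
    os_time = np.minimum(t_os, c)
    os_event = (t_os <= c).astype(int)
    rfs_time = np.minimum(t_rfs, c)
    rfs_event = (t_rfs <= c).astype(int)

    features = rng.standard_normal((n, spec.feature_dim))
    if spec.n_informative:
        features[:, : spec.n_informative] += z[:, None]

    width = max(4, len(str(n)))
    records = [
        PatientRecord(
            id=f"P{i:0{width}d}",
            age=float(age[i]),
            sex=str(sex[i]),
            histology=str(histology[i]),
            lobe=str(lobe[i]),
            stage=STAGES[stage_idx[i]],
            os_time=float(os_time[i]),
            os_event=int(os_event[i]),
            rfs_time=float(rfs_time[i]),
            rfs_event=int(rfs_event[i]),
        )
        for i in range(n)
    ]
    return SyntheticCohort(records, features, latent_risk, z, spec.seed)


def generate_volume(
    size_mm: float,
    seed: int,
    field_of_view: Tuple[int, int, int] = (64, 64, 64),
    voxel_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TumorVolume:
    """Phantom tumour: a noisy bright ellipsoid of diameter ``size_mm`` on a
    lung-attenuation background.

    Intensities are CT-like (background around -850 HU, lesion around
    -50 HU).  Ellipsoids larger than the field of view are clipped at the
    borders.  Fully deterministic given ``seed``.
    """
    if size_mm <= 0:
        raise CohortSpecError("size_mm must be > 0")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in field_of_view)
    vol = rng.normal(-850.0, 40.0, shape)

    # mild per-axis radius jitter keeps the phantom near-spherical
    radii_mm = (size_mm / 2.0) * (1.0 + rng.uniform(-0.08, 0.08, 3))
    centers = [(s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(
        ((g - c) * sp / r) ** 2
        for g, c, sp, r in zip(grids, centers, voxel_spacing, radii_mm)
    )
    inside = r2 <= 1.0
    vol[inside] = rng.normal(-50.0, 30.0, int(inside.sum()))
    return TumorVolume(vol, voxel_spacing)
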