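"""Synthetic serum-like FTIR cohorts and multivariate-Gaussian augmentation.

Two distinct generators live here:

* :func:`generate_cohort` builds a fully synthetic case-control cohort with
  known ground truth.  Each spectrum is a sum of Gaussian absorption bands
  (all outside the 1800-2300 cm^-1 silent region, so that region stays
  near-flat), per-sample log-normal band multipliers (biological variation),
  plus instrument drift (baseline offset, slope, sinusoidal fringes) and
  white noise.  Cases carry a stage-graded amplitude shift on designated
  disease bands; covariates (age, sex, BMI) and surrogate blood biomarkers
  with known loadings on disease severity are emitted alongside.

* :func:`fit_mvn` / :func:`sample_mvn` implement the augmentation used to
  train the autoencoder: a multivariate Gaussian fitted to the (preprocessed)
  training spectra, with shrinkage of the covariance toward its diagonal —
  required because the number of grid points typically exceeds the number of
  training spectra — and L2 normalization of the sampled spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .spectra_io import (
    SpectraSet,
    WavenumberGrid,
    default_grid,
    l2_normalize,
)

__all__ = [
    "CohortConfig",
    "MvnModel",
    "generate_cohort",
    "fit_mvn",
    "sample_mvn",
]


def _default_band_centers() -> list[float]:
    # serum fingerprint (carbohydrate/phosphate, amide II/I, lipid ester)
    # and CH-stretch bands; none inside the 1800-2300 silent region
    return [1080.0, 1240.0, 1310.0, 1400.0, 1550.0, 1650.0, 1740.0, 2850.0, 2930.0, 2960.0]


def _default_band_widths() -> list[float]:
    return [35.0, 30.0, 25.0, 28.0, 30.0, 32.0, 20.0, 16.0, 18.0, 14.0]


def _default_band_amplitudes() -> list[float]:
    # amide I (1650) and amide II (1550) dominate serum absorbance
    return [0.45, 0.30, 0.25, 0.40, 0.80, 1.00, 0.20, 0.25, 0.40, 0.20]


def _default_drift() -> dict:
    # small enough that structured drift stays subdominant to biological
    # variation over the whole grid, yet dominates the near-zero silent region
    return {
        "offset_sd": 0.0015,
        "slope_sd": 1.5e-6,
        "fringe_amplitude_sd": 0.0015,
        "fringe_period": 120.0,
    }


def _default_covariate_effects() -> dict:
    # fractional band-amplitude change per standardized covariate unit
    return {
        "age": {5: 0.015, 0: 0.010},
        "sex": {8: 0.030, 3: 0.015},
        "bmi": {6: 0.030, 7: 0.020},
    }


def _default_biomarkers() -> dict:
    # loading on disease severity (stage weight; 0 for controls) + noise sd
    # + missing fraction, mirroring routine blood panels for lung cancer
    return {
        "crp": {"loading": 0.9, "noise_sd": 0.5, "missing": 0.05},
        "cyfra_21_1": {"loading": 0.8, "noise_sd": 0.6, "missing": 0.30},
        "leukocytes": {"loading": 0.5, "noise_sd": 0.8, "missing": 0.05},
        "hemoglobin": {"loading": -0.5, "noise_sd": 0.8, "missing": 0.05},
    }


@dataclass
class CohortConfig:
    """Ground-truth parameters for a synthetic case-control cohort."""

    n_cases: int = 523
    n_controls: int = 523
    seed: int = 0
    n_points: int = 1037
    grid_lo: float = 1000.0
    grid_hi: float = 3000.0
    band_centers: list = field(default_factory=_default_band_centers)
    band_widths: list = field(default_factory=_default_band_widths)
    band_amplitudes: list = field(default_factory=_default_band_amplitudes)
    biological_cv: float = 0.15
    disease_bands: list = field(default_factory=lambda: [4, 5, 6])
    disease_effect: float = 0.05
    stage_weights: dict = field(
        default_factory=lambda: {"I": 0.25, "II": 0.5, "III": 0.75, "IV": 1.0}
    )
    stage_probs: dict = field(
        default_factory=lambda: {"I": 0.07, "II": 0.04, "III": 0.14, "IV": 0.20, "unknown": 0.55}
    )
    drift: dict = field(default_factory=_default_drift)
    noise_sd: float = 0.002
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    biomarker_spec: dict = field(default_factory=_default_biomarkers)

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls <= 0:
            raise ValueError("cohort must contain at least one sample")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("sample counts must be nonnegative")
        if not (len(self.band_centers) == len(self.band_widths) == len(self.band_amplitudes)):
            raise ValueError("band_centers/widths/amplitudes must have equal length")
        if self.biological_cv < 0 or self.noise_sd < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if any(v < 0 for v in self.drift.values()):
            raise ValueError("drift standard deviations must be >= 0")
        weights = [self.stage_weights[s] for s in ("I", "II", "III", "IV")]
        if not all(b > a for a, b in zip(weights, weights[1:])):
            raise ValueError("stage weights must increase strictly I -> IV")

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown CohortConfig keys: {sorted(unknown)}")
        # YAML may stringify integer dict keys in covariate_effects
        if "covariate_effects" in raw:
            raw["covariate_effects"] = {
                cov: {int(k): v for k, v in bands.items()}
                for cov, bands in raw["covariate_effects"].items()
            }
        return cls(**raw)


def _band_profiles(grid: np.ndarray, config: CohortConfig) -> np.ndarray:
    centers = np.asarray(config.band_centers)[:, None]
    widths = np.asarray(config.band_widths)[:, None]
    return np.exp(-0.5 * ((grid[None, :] - centers) / widths) ** 2)


def generate_cohort(config: CohortConfig | None = None) -> SpectraSet:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    grid = default_grid(config.n_points, config.grid_lo, config.grid_hi)
    w = grid.values
    profiles = _band_profiles(w, config)  # (n_bands, n_points)
    base_amp = np.asarray(config.band_amplitudes, dtype=float)
    n_bands = base_amp.size
    n = config.n_cases + config.n_controls
    labels = np.concatenate([np.ones(config.n_cases, int), np.zeros(config.n_controls, int)])

    # covariates: cohorts are matched on age/sex (Table-1-like moments)
    age = np.clip(rng.normal(65.0, 10.0, n), 30, 90)
    sex = (rng.random(n) < 0.46).astype(int)  # 1 = female
    bmi = np.clip(rng.normal(26.0, 5.0, n), 15, 45)

    # disease severity: staged cases get their stage weight, controls 0;
    # stage may be recorded "unknown" although the latent severity is real
    stage_names = list(config.stage_probs)
    stage_p = np.array([config.stage_probs[s] for s in stage_names], dtype=float)
    stage_p = stage_p / stage_p.sum()
    recorded_stage = np.full(n, "unknown", dtype=object)
    severity = np.zeros(n)
    true_stages = ("I", "II", "III", "IV")
    for i in range(config.n_cases):
        drawn = rng.choice(stage_names, p=stage_p)
        if drawn == "unknown":
            hidden = rng.choice(true_stages)
            severity[i] = config.stage_weights[hidden]
        else:
            severity[i] = config.stage_weights[drawn]
        recorded_stage[i] = drawn

    # per-sample band amplitudes
    sigma_log = np.sqrt(np.log1p(config.biological_cv**2))
    multipliers = np.exp(rng.normal(-0.5 * sigma_log**2, sigma_log, (n, n_bands)))
    amps = base_amp[None, :] * multipliers
    z_age = (age - 65.0) / 10.0
    z_bmi = (bmi - 26.0) / 5.0
    z_cov = {"age": z_age, "sex": sex.astype(float), "bmi": z_bmi}
    for cov, per_band in config.covariate_effects.items():
        for band_idx, coef in per_band.items():
            amps[:, band_idx] *= 1.0 + coef * z_cov[cov]
    for band_idx in config.disease_bands:
        amps[:, band_idx] *= 1.0 + config.disease_effect * severity * labels
    amps = np.clip(amps, 0.0, None)  # no negative band amplitudes before noise

    spectra = amps @ profiles
    # instrument drift: additive baseline offset, slope and sinusoidal fringe
    offset = rng.normal(0.0, config.drift["offset_sd"], n)
    slope = rng.normal(0.0, config.drift["slope_sd"], n)
    fringe_amp = rng.normal(0.0, config.drift["fringe_amplitude_sd"], n)
    phase = rng.uniform(0.0, 2.0 * np.pi, n)
    w_centered = w - w.mean()
    spectra = (
        spectra
        + offset[:, None]
        + slope[:, None] * w_centered[None, :]
        + fringe_amp[:, None]
        * np.sin(2.0 * np.pi * w[None, :] / config.drift["fringe_period"] + phase[:, None])
    )
    spectra = spectra + rng.normal(0.0, config.noise_sd, (n, w.size))

    meta = pd.DataFrame(
        {
            "label": labels,
            "age": np.round(age, 1),
            "sex": np.where(sex == 1, "F", "M"),
            "bmi": np.round(bmi, 1),
            "stage": recorded_stage,
        }
    )
    for name, spec in config.biomarker_spec.items():
        values = spec["loading"] * severity + rng.normal(0.0, spec["noise_sd"], n)
        missing = rng.random(n) < spec.get("missing", 0.0)
        meta[name] = np.where(missing, np.nan, values)
    ids = [f"S{i:04d}" for i in range(n)]
    meta.index = pd.Index(ids, name="sample_id")
    return SpectraSet(grid, spectra, ids, meta)


# ---------------------------------------------------------------------------
# Multivariate-Gaussian augmentation
# ---------------------------------------------------------------------------

@dataclass
class MvnModel:
    """Gaussian spectral model: column means + diagonal-shrunk covariance."""

    mean: np.ndarray
    covariance: np.ndarray
    shrinkage: float
    fitted_on: int
    grid: WavenumberGrid

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("MVN mean must be finite")
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape mismatch")


def _auto_shrinkage(centered: np.ndarray) -> float:
    """Ledoit-Wolf-style optimal intensity for shrinking toward the diagonal.

    Minimises expected Frobenius loss of ``(1-s)*S + s*diag(S)``; the optimal
    intensity is ``sum_{i!=j} Var(s_ij) / sum_{i!=j} s_ij^2``, estimated by
    plug-in moments.
    """
    n = centered.shape[0]
    s = centered.T @ centered / (n - 1)
    sq = centered**2
    # Var(s_ij) ~ n/(n-1)^3 * sum_k (x_ki x_kj - mean)^2, plug-in version
    second = sq.T @ sq / n
    var_s = (n / (n - 1.0) ** 2) * (second - (centered.T @ centered / n) ** 2)
    off = ~np.eye(s.shape[0], dtype=bool)
    denom = float((s[off] ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))


def fit_mvn(spectra: SpectraSet, shrinkage: float | str = "auto") -> MvnModel:
    """Fit the augmentation Gaussian on (preprocessed) training spectra."""
    x = np.asarray(spectra.absorbance, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("fitting the MVN requires at least 2 spectra")
    mean = x.mean(axis=0)
    centered = x - mean
    sample_cov = centered.T @ centered / (x.shape[0] - 1)
    if shrinkage == "auto":
        coeff = _auto_shrinkage(centered)
    else:
        coeff = float(shrinkage)
        if not 0.0 <= coeff <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
    cov = (1.0 - coeff) * sample_cov + coeff * np.diag(np.diag(sample_cov))
    return MvnModel(mean=mean, covariance=cov, shrinkage=coeff, fitted_on=x.shape[0], grid=spectra.grid)


def sample_mvn(
    model: MvnModel,
    n: int = 5000,
    seed: int = 0,
    normalize: bool = True,
) -> SpectraSet:
    """Sample ``n`` synthetic spectra (default 5000, the autoencoder's
    training-set size); L2-normalized before return unless ``normalize=False``."""
    if n <= 0:
        raise ValueError("sample count must be positive")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(model.mean, model.covariance, size=n, method="eigh")
    ids = [f"MVN{i:05d}" for i in range(n)]
    out = SpectraSet(model.grid, draws, ids)
    if normalize:
        out = l2_normalize(out)
    return out
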