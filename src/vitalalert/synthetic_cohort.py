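"""Labelled synthetic vital-signs cohorts.

The study cohort — 1,177 adult records drawn from the credential-restricted
MIMIC-III v1.4 database — cannot ship with the package, so this module
generates cohorts whose published marginal statistics (mean, standard
deviation, minimum, maximum per variable) it reproduces. Every downstream
component is testable against these synthetic cohorts.

Each variable is drawn from a truncated normal on the published [min, max]
support. Because truncation shifts the moments of the parent normal, the
parent location and scale are *moment-matched* numerically so that the
truncated distribution itself has the published mean and standard deviation
(a naive ``loc=mean`` parent would, e.g., miss the age mean by about one
year due to the hard ceiling at 99). Variables are independent by default —
no covariance structure is published — but a correlation matrix can be
supplied, in which case a Gaussian copula couples the same marginals.

Ground-truth labels: the binary normal/abnormal label of the original
extract is not defined anywhere public, so the label-generating rule is
explicit and configurable:

``latent_news2``
    p(abnormal) = logistic(a · (NEWS2 aggregate − b)), defaults a=1.5, b=4,
    reusing the production NEWS2 scorer on the scored subset of features.
    Labels are then a noisy monotone function of true deterioration.
``logistic_linear``
    p(abnormal) = logistic(β₀ + Σ βᵢ · standardized featureᵢ) with
    configurable coefficients — the generating model is known exactly, which
    supports parameter-recovery checks of the logistic classifier.

Missing data can be injected cell-wise and is then repaired by group-mean
imputation (mean of the observed values within the same label class),
mirroring the preprocessing of the original extract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .news2 import SCORED_PARAMETERS, score_parameter
from .risk_model import LABEL_COLUMN


@dataclass(frozen=True)
class VariableStats:
    """Target marginal summary of one variable: mean, std and support."""

    mean: float
    std: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError(f"min must be below max: {self.min} >= {self.max}")
        if self.std < 0:
            raise ValueError(f"std must be non-negative: {self.std}")
        if not self.min <= self.mean <= self.max:
            raise ValueError(
                f"mean {self.mean} outside support [{self.min}, {self.max}]"
            )


#: Published summary statistics of the 1,177-record MIMIC-III vital-signs
#: extract the generator emulates (per-variable mean, std, min, max).
MIMIC_SUMMARY: dict[str, VariableStats] = {
    "age": VariableStats(74.05, 13.43, 19.0, 99.0),
    "bmi": VariableStats(30.188, 8.4305, 13.3468, 104.97),
    "heart_rate": VariableStats(84.57, 15.929, 36.0, 135.7083),
    "systolic_bp": VariableStats(117.99, 17.24, 75.0, 203.0),
    "resp_rate": VariableStats(20.8, 3.98, 11.14, 40.9),
    "temperature": VariableStats(36.68, 0.602, 33.25, 39.13),
    "spo2": VariableStats(96.27, 2.285, 75.91, 100.0),
    "blood_sugar": VariableStats(148.79, 51.098, 66.67, 414.1),
}

LABEL_RULES = ("latent_news2", "logistic_linear")

#: Default coefficients of the logistic_linear rule, on standardized
#: features: clinically signed (worse vitals → higher abnormality odds).
DEFAULT_LOGISTIC_PARAMS: dict = {
    "beta0": -0.8,
    "beta": {
        "age": 0.3,
        "bmi": 0.2,
        "heart_rate": 0.6,
        "systolic_bp": -0.4,
        "resp_rate": 0.8,
        "temperature": 0.5,
        "spo2": -0.9,
        "blood_sugar": 0.4,
    },
}

#: Defaults of the latent_news2 rule: slope a, centre b on the NEWS2
#: aggregate scale.
DEFAULT_LATENT_NEWS2_PARAMS: dict = {"a": 1.5, "b": 4.0}


@dataclass
class CohortConfig:
    """Distributional parameters of a synthetic cohort.

    Defaults are the study conditions: 1,177 records with the published
    per-variable summaries, NEWS2-latent labels, no label noise and no
    missingness.
    """

    n: int = 1177
    variables: dict[str, VariableStats] = field(
        default_factory=lambda: dict(MIMIC_SUMMARY)
    )
    label_rule: str = "latent_news2"
    label_params: Optional[dict] = None
    label_noise: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    correlation: Optional[np.ndarray] = None  # hook; identity if omitted

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be at least 2, got {self.n}")
        if self.label_rule not in LABEL_RULES:
            raise ValueError(
                f"unknown label_rule {self.label_rule!r}; expected one of {LABEL_RULES}"
            )
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError(f"label_noise out of [0, 0.5): {self.label_noise}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate out of [0, 1): {self.missing_rate}")
        for name, stats in self.variables.items():
            if not isinstance(stats, VariableStats):
                self.variables[name] = VariableStats(*stats)
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            m = len(self.variables)
            if corr.shape != (m, m) or not np.allclose(corr, corr.T):
                raise ValueError("correlation must be a symmetric m x m matrix")
            self.correlation = corr


@lru_cache(maxsize=256)
def _matched_parent(mean: float, std: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncated normal has the target
    mean and std (solved numerically; exact to ~1e-8)."""

    def residual(p: np.ndarray) -> list[float]:
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        with np.errstate(invalid="ignore"):  # extreme iterates degenerate benignly
            m = truncnorm.mean(a, b, loc=mu, scale=sigma) - mean
            s = truncnorm.std(a, b, loc=mu, scale=sigma) - std
        return [m if math.isfinite(m) else 1e6, s if math.isfinite(s) else 1e6]

    sol = optimize.root(residual, x0=[mean, math.log(std)], method="hybr")
    res = residual(sol.x)
    if not sol.success or max(abs(r) for r in res) > 1e-6 * max(std, 1.0):
        raise ValueError(
            f"no truncated normal on [{lo}, {hi}] attains mean={mean}, std={std}"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _truncnorm_frozen(stats: VariableStats):
    mu, sigma = _matched_parent(stats.mean, stats.std, stats.min, stats.max)
    a, b = (stats.min - mu) / sigma, (stats.max - mu) / sigma
    return truncnorm(a, b, loc=mu, scale=sigma)


def sample_variable(
    stats: VariableStats, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n values from the moment-matched truncated normal."""
    if stats.std == 0.0:
        return np.full(n, stats.mean)
    return _truncnorm_frozen(stats).rvs(size=n, random_state=rng)


def _sample_features(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    names = list(config.variables)
    if config.correlation is None:
        data = {
            name: sample_variable(config.variables[name], config.n, rng)
            for name in names
        }
        return pd.DataFrame(data)
    # Gaussian copula: correlated standard normals -> uniform -> marginal ppf
    chol = np.linalg.cholesky(config.correlation)
    z = rng.standard_normal((config.n, len(names))) @ chol.T
    u = norm.cdf(z)
    data = {}
    for j, name in enumerate(names):
        stats = config.variables[name]
        if stats.std == 0.0:
            data[name] = np.full(config.n, stats.mean)
        else:
            data[name] = _truncnorm_frozen(stats).ppf(u[:, j])
    return pd.DataFrame(data)


#: Scored-parameter -> cohort-column mapping used by the latent_news2 rule.
_NEWS2_FEATURE_MAP: dict[str, str] = {
    "respiration_rate": "resp_rate",
    "spo2": "spo2",
    "systolic_bp": "systolic_bp",
    "pulse_rate": "heart_rate",
    "temperature": "temperature",
}


def news2_aggregates(features: pd.DataFrame) -> np.ndarray:
    """NEWS2 aggregate per row, scored on the five chart parameters
    (pulse rate is the recorded heart rate; SpO2 on scale 1)."""
    missing = [c for c in _NEWS2_FEATURE_MAP.values() if c not in features.columns]
    if missing:
        raise ValueError(f"features lack NEWS2 columns: {missing}")
    columns = {
        p: features[c].to_numpy(dtype=float) for p, c in _NEWS2_FEATURE_MAP.items()
    }
    agg = np.zeros(len(features), dtype=int)
    for p in SCORED_PARAMETERS:
        scale = "scale1" if p == "spo2" else None
        agg += np.array(
            [score_parameter(p, v, spo2_scale=scale) for v in columns[p]], dtype=int
        )
    return agg


def assign_labels(
    features: pd.DataFrame,
    rule: str,
    params: Optional[dict] = None,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw binary abnormality labels from the chosen generating rule.

    Use a seed independent of the one that generated the features:
    truncated-normal sampling inverts uniforms, so reusing the same integer
    seed here makes the label thresholds identical to the uniforms behind
    the features and induces spurious feature-label dependence.
    (:func:`generate_cohort` avoids this by advancing one shared stream.)
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if features.isna().any().any():
        raise ValueError("features must be complete before label assignment")
    if rule == "latent_news2":
        p = {**DEFAULT_LATENT_NEWS2_PARAMS, **(params or {})}
        z = p["a"] * (news2_aggregates(features).astype(float) - p["b"])
        prob = expit(z)
    elif rule == "logistic_linear":
        p = params if params is not None else DEFAULT_LOGISTIC_PARAMS
        beta = p["beta"]
        standardize = p.get("standardize")
        z = np.full(len(features), float(p.get("beta0", 0.0)))
        for col, coef in beta.items():
            x = features[col].to_numpy(dtype=float)
            if standardize is not None:
                m, s = standardize[col]
            else:
                m, s = float(np.mean(x)), float(np.std(x, ddof=0))
            z += coef * ((x - m) / s if s > 0 else 0.0)
        prob = expit(z)
    else:
        raise ValueError(f"unknown label rule {rule!r}")
    return (rng.random(len(features)) < prob).astype(int)


def impute_missing(
    features: pd.DataFrame, groups: Optional[Sequence] = None
) -> pd.DataFrame:
    """Replace each missing cell by the group mean of the observed values.

    Groups are the label classes when supplied, otherwise the whole cohort
    is one group. Observed cells are never touched. A variable with no
    observed value in some group cannot be imputed and raises.
    """
    out = features.copy()
    if groups is None:
        key = pd.Series(0, index=out.index)
    else:
        key = pd.Series(np.asarray(groups), index=out.index)
        if len(key) != len(out):
            raise ValueError("groups length must match the number of rows")
    for col in out.columns:
        if not out[col].isna().any():
            continue
        means = out[col].groupby(key).transform("mean")
        if means[out[col].isna()].isna().any():
            bad = sorted(key[out[col].isna() & means.isna()].unique().tolist())
            raise ValueError(
                f"variable {col!r} entirely missing within group(s) {bad}; "
                "no fallback available"
            )
        out[col] = out[col].fillna(means)
    return out


def generate_cohort(
    config: Optional[CohortConfig] = None, seed: Optional[int] = None
) -> pd.DataFrame:
    """Generate a complete labelled cohort.

    Features are sampled from the configured marginals, labels assigned by
    the configured rule and flipped with probability ``label_noise``, then
    (if ``missing_rate`` > 0) cells are blanked at random and repaired by
    label-group mean imputation, reproducing the preprocessing path of the
    original extract. Deterministic given the seed; the seed used is
    recorded in ``DataFrame.attrs['seed']``.
    """
    if config is None:
        config = CohortConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    features = _sample_features(config, rng)
    labels = assign_labels(
        features, config.label_rule, config.label_params, rng=rng
    )
    if config.label_noise > 0:
        flip = rng.random(config.n) < config.label_noise
        labels = np.where(flip, 1 - labels, labels)
    if config.missing_rate > 0:
        mask = rng.random(features.shape) < config.missing_rate
        blanked = features.mask(mask)
        features = impute_missing(blanked, groups=labels)
    cohort = features.copy()
    cohort[LABEL_COLUMN] = labels.astype(int)
    cohort.attrs["seed"] = int(seed)
    return cohort
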