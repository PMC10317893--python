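"""Synthetic cohort generator with a planted piecewise outcome model.

The generator emulates the pooled structure of the multicenter study
cohort (n = 1314): categorical marginals for sex, histology, T stage,
N stage and ATA risk class; log-normal laws for thyroglobulin (Tg),
TSH and 24-h radioiodine uptake with the published medians; and a
planted piecewise-constant risk model on (N stage, Tg) whose terminal
probabilities are the published tree risks.  The one terminal the study
does not report (node-positive patients with low Tg) is calibrated in
closed form so the pooled event rate matches the published 15.2%.

Tg is sampled conditionally on N stage: node-positive patients have a
higher median Tg (``tg_n1_median_ratio``, default 3x), while the
*marginal* median is held at the published value by solving the mixture
median equation.  Setting the ratio to 1 recovers full independence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import (ATA_LEVELS, HISTOLOGY_LEVELS, SEX_LEVELS, Cohort)

__all__ = [
    "PlantedRiskModel", "GeneratorConfig", "CalibrationError",
    "planted_risk", "tg_class_medians", "calibrate_baseline_risk",
    "default_config", "generate",
]

_Z75 = float(stats.norm.ppf(0.75))          # 0.6745; quartile z-score
_Z90 = float(stats.norm.ppf(0.90))          # calibrates P(TSH > 30) = 0.90


class CalibrationError(ValueError):
    """The requested pooled event rate is unattainable."""


@dataclass(frozen=True)
class PlantedRiskModel:
    """Piecewise-constant risk of a positive PT-WBS on (N stage, Tg).

    Bands are right-closed (``tg <= cutoff`` falls in the lower band),
    matching the tree's "<= / >" split convention.  ``risk_n1_lo`` is the
    unreported node-positive low-Tg terminal; it is left unset here and
    filled in by :func:`calibrate_baseline_risk`.
    """

    cut_n1: float = 23.3
    cut_hi: float = 35.0
    cut_lo: float = 7.1
    risk_n1_hi: float = 0.83
    risk_n0_hi: float = 0.563
    risk_n0_mid: float = 0.152
    risk_n0_lo: float = 0.058
    risk_n1_lo: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.cut_lo < self.cut_hi:
            raise ValueError("need 0 < cut_lo < cut_hi")
        if self.cut_n1 <= 0:
            raise ValueError("cut_n1 must be positive")
        risks = [self.risk_n1_hi, self.risk_n0_hi, self.risk_n0_mid, self.risk_n0_lo]
        if self.risk_n1_lo is not None:
            risks.append(self.risk_n1_lo)
        if any(not 0 <= r <= 1 for r in risks):
            raise ValueError("risks must lie in [0, 1]")
        if not self.risk_n0_lo <= self.risk_n0_mid <= self.risk_n0_hi:
            raise ValueError("node-negative risks must be non-decreasing in Tg")


def planted_risk(n_stage, tg, model: PlantedRiskModel):
    """Evaluate the planted risk surface (vectorized over records)."""
    n_stage = np.asarray(n_stage)
    tg = np.asarray(tg, dtype=float)
    if np.any(tg < 0):
        raise ValueError("tg must be non-negative")
    if not np.all(np.isin(n_stage, (0, 1))):
        raise ValueError("n_stage must be 0 or 1")
    if model.risk_n1_lo is None and np.any((n_stage == 1) & (tg <= model.cut_n1)):
        raise ValueError("risk_n1_lo is unset; calibrate the model first")
    q = 0.0 if model.risk_n1_lo is None else model.risk_n1_lo
    out = np.where(
        n_stage == 1,
        np.where(tg > model.cut_n1, model.risk_n1_hi, q),
        np.where(tg > model.cut_hi, model.risk_n0_hi,
                 np.where(tg > model.cut_lo, model.risk_n0_mid, model.risk_n0_lo)),
    )
    return float(out) if out.ndim == 0 else out


def _default_tg_sigma() -> float:
    # dispersion matched to the published quartile ratio 10 / 0.7
    return float(np.log(10.0 / 0.7) / (2.0 * _Z75))


@dataclass(frozen=True)
class GeneratorConfig:
    """Marginal distributions plus the planted outcome model.

    All location parameters are natural-scale medians of log-normal laws;
    sigma values are log-scale standard deviations.  Probability vectors
    are renormalized on use.
    """

    n: int = 1314
    p_n1: float = 0.16
    tg_median: float = 3.0
    tg_log_sigma: float = field(default_factory=_default_tg_sigma)
    tg_n1_median_ratio: float = 3.0
    tsh_median: float = 64.5
    tsh_log_sigma: float = field(default_factory=lambda: float(np.log(64.5 / 30.0) / _Z90))
    raiu_median: float = 4.4
    raiu_log_sigma: float = field(default_factory=lambda: float(np.log(7.8 / 2.2) / (2.0 * _Z75)))
    histology_probs: tuple = (0.63, 0.18, 0.18, 0.01)
    t_stage_probs: tuple = (0.53, 0.22, 0.24, 0.01)
    ata_probs: tuple = (0.54, 0.26, 0.21)
    sex_p_female: float = 0.76
    age_center: float = 49.0
    age_scale: float = field(default_factory=lambda: float((59.0 - 40.0) / (2.0 * _Z75)))
    age_range: tuple = (18, 95)
    target_event_rate: float = 0.152
    remnant_fraction: float = 0.0
    planted_model: PlantedRiskModel = field(default_factory=PlantedRiskModel)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("p_n1", "sex_p_female", "target_event_rate", "remnant_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("tg_log_sigma", "tsh_log_sigma", "raiu_log_sigma", "age_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tg_n1_median_ratio <= 0:
            raise ValueError("tg_n1_median_ratio must be positive")
        for name, k in (("histology_probs", 4), ("t_stage_probs", 4), ("ata_probs", 3)):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (k,) or np.any(p < 0) or p.sum() <= 0:
                raise ValueError(f"{name} must be {k} non-negative weights")

    def _norm(self, name: str) -> np.ndarray:
        p = np.asarray(getattr(self, name), dtype=float)
        return p / p.sum()


def tg_class_medians(config: GeneratorConfig) -> tuple[float, float]:
    """N-conditional Tg medians (m0, m1) with m1 = ratio * m0.

    m0 solves the mixture-median equation so that the marginal median of
    Tg equals ``config.tg_median`` exactly in the population.
    """
    r, s, med, p1 = (config.tg_n1_median_ratio, config.tg_log_sigma,
                     config.tg_median, config.p_n1)
    if r == 1.0:
        return med, med
    if p1 == 0.0:
        return med, med * r
    if p1 == 1.0:
        return med / r, med

    def gap(log_m0: float) -> float:
        m0 = np.exp(log_m0)
        return ((1 - p1) * stats.norm.cdf(np.log(med / m0) / s)
                + p1 * stats.norm.cdf(np.log(med / (r * m0)) / s) - 0.5)

    a, b = sorted((np.log(med / r), np.log(med)))
    m0 = float(np.exp(optimize.brentq(gap, a - 1e-9, b + 1e-9)))
    return m0, r * m0


def _tg_band_probs(config: GeneratorConfig) -> dict:
    """Closed-form probabilities of the planted Tg bands, per N class."""
    m0, m1 = tg_class_medians(config)
    s = config.tg_log_sigma
    pm = config.planted_model

    def cdf(x: float, m: float) -> float:
        return float(stats.norm.cdf(np.log(x / m) / s))

    p1_hi = 1.0 - cdf(pm.cut_n1, m1)
    p0_lo = cdf(pm.cut_lo, m0)
    p0_hi = 1.0 - cdf(pm.cut_hi, m0)
    return {"p1_hi": p1_hi, "p1_lo": 1.0 - p1_hi,
            "p0_lo": p0_lo, "p0_hi": p0_hi, "p0_mid": 1.0 - p0_lo - p0_hi}


def calibrate_baseline_risk(config: GeneratorConfig) -> float:
    """Solve the node-positive low-Tg terminal risk in closed form.

    Returns the q for which the pooled event rate of the planted mixture
    equals ``config.target_event_rate``, using the exact band
    probabilities of the configured log-normal Tg laws.  Raises
    :class:`CalibrationError` (reporting the attainable range) when no
    q in [0, 1] solves the identity.
    """
    b = _tg_band_probs(config)
    pm = config.planted_model
    p1 = config.p_n1
    fixed = (p1 * b["p1_hi"] * pm.risk_n1_hi
             + (1 - p1) * (b["p0_hi"] * pm.risk_n0_hi
                           + b["p0_mid"] * pm.risk_n0_mid
                           + b["p0_lo"] * pm.risk_n0_lo))
    weight = p1 * b["p1_lo"]
    lo_rate, hi_rate = fixed, fixed + weight
    if weight == 0.0:
        if abs(fixed - config.target_event_rate) < 1e-12:
            return 0.0
        raise CalibrationError(
            f"event rate fixed at {fixed:.4f}; target {config.target_event_rate} unattainable")
    q = (config.target_event_rate - fixed) / weight
    if not 0.0 <= q <= 1.0:
        raise CalibrationError(
            f"target event rate {config.target_event_rate} outside attainable "
            f"range [{lo_rate:.4f}, {hi_rate:.4f}]")
    return float(q)


def default_config() -> GeneratorConfig:
    """Study-condition defaults with the calibrated baseline risk filled in."""
    config = GeneratorConfig()
    q = calibrate_baseline_risk(config)
    model = dataclasses.replace(config.planted_model, risk_n1_lo=q)
    return dataclasses.replace(config, planted_model=model)


def generate(config: GeneratorConfig, seed: Optional[int] = None) -> Cohort:
    """Draw a synthetic cohort; a pure function of (config, seed).

    Predictors are drawn from the configured marginals (Tg conditionally
    on N stage), the PT-WBS label as Bernoulli(planted risk) mapped to
    ``positive`` / ``negative``, with an optional ``remnant`` fraction
    among non-events.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (config.seed or the seed argument)")
    model = config.planted_model
    if model.risk_n1_lo is None:
        model = dataclasses.replace(model, risk_n1_lo=calibrate_baseline_risk(config))

    rng = np.random.default_rng(seed)
    n = config.n
    n_stage = (rng.random(n) < config.p_n1).astype(np.int64)
    sex = np.where(rng.random(n) < config.sex_p_female, "F", "M")
    histology = rng.choice(np.asarray(HISTOLOGY_LEVELS, dtype=object), size=n,
                           p=config._norm("histology_probs"))
    t_stage = rng.choice(np.arange(1, 5), size=n, p=config._norm("t_stage_probs"))
    ata = rng.choice(np.asarray(ATA_LEVELS, dtype=object), size=n,
                     p=config._norm("ata_probs"))
    age = np.rint(np.clip(rng.normal(config.age_center, config.age_scale, n),
                          *config.age_range)).astype(np.int64)
    tsh = np.exp(np.log(config.tsh_median) + config.tsh_log_sigma * rng.standard_normal(n))
    raiu = np.minimum(np.exp(np.log(config.raiu_median)
                             + config.raiu_log_sigma * rng.standard_normal(n)), 100.0)
    m0, m1 = tg_class_medians(config)
    tg = np.exp(np.where(n_stage == 1, np.log(m1), np.log(m0))
                + config.tg_log_sigma * rng.standard_normal(n))

    risk = planted_risk(n_stage, tg, model)
    event = rng.random(n) < risk
    remnant = (~event) & (rng.random(n) < config.remnant_fraction)
    ptwbs = np.where(event, "positive", np.where(remnant, "remnant", "negative"))

    df = pd.DataFrame({
        "age": age, "sex": sex, "histology": histology, "t_stage": t_stage,
        "n_stage": n_stage, "ata_risk": ata, "tsh": tsh, "tg": tg,
        "raiu": raiu, "ptwbs": ptwbs, "center": None,
    })
    return Cohort(df, provenance=f"synthetic(seed={seed})", seed=int(seed))
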