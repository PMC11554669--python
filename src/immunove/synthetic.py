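"""Synthetic vaccine-trial generator with analytic vaccine-efficacy oracles.

Emulates the structure the analyses assume: a randomized two-arm trial with
one binary baseline covariate, an arm- and covariate-dependent normal
biomarker on the log2 scale, proportional-hazards event times whose hazard
depends on the biomarker through an exponential-baseline Cox link,
administrative plus exponential-dropout censoring, and optional independent
competing causes. Every draw is reproducible from the config seed, and a
closed-form ``true_ve`` oracle gives the efficacy the generator implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import integrate

from .data_model import StudyTable

__all__ = ["TrialConfig", "CompetingCause", "simulate_trial", "true_ve"]


@dataclass
class CompetingCause:
    """An independent competing cause with its own exponential-baseline PH hazard."""

    rate: float  # baseline hazard per day
    beta_t: float = 0.0
    beta_covariate: float = 0.0
    beta_vaccine: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("competing-cause rate must be > 0")


@dataclass
class TrialConfig:
    """Parameters of a simulated immunogenicity sub-study.

    Biomarker T is normal per arm on the log2 scale: vaccine arm
    N(mu_vaccine + covariate_shift * x, sd_vaccine), control arm
    N(mu_control + covariate_shift * x, sd_control) or degenerate at 0 when
    ``control_degenerate`` (the fold-rise convention: controls are assigned
    log2 fold rise 0). The cause-1 hazard is
    rate * exp(beta_t*T + beta_t2*T^2 + beta_covariate*x + beta_vaccine*v);
    ``beta_vaccine`` != 0 breaks full mediation (a direct vaccine effect).
    Censoring is the administrative ``horizon`` plus exponential dropout.
    """

    n_vaccine: int = 600
    n_control: int = 600
    covariate_name: str = "subgroup"
    covariate_prevalence: float = 0.5
    biomarker_name: str = "titer"
    mu_vaccine: float = 2.0
    mu_control: float = 0.0
    sd_vaccine: float = 1.0
    sd_control: float = 1.0
    covariate_shift: float = 0.0
    control_degenerate: bool = False
    beta_t: float = float(np.log(0.5))
    beta_t2: float = 0.0
    beta_covariate: float = 0.0
    beta_vaccine: float = 0.0
    baseline_rate: float = 1e-4  # events per day at T = 0
    horizon: float = 1095.0  # days (~3-year follow-up)
    dropout_rate: float = 0.0  # per day
    competing: list[CompetingCause] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vaccine < 1 or self.n_control < 1:
            raise ValueError("need at least one subject per arm")
        if not (0.0 <= self.covariate_prevalence <= 1.0):
            raise ValueError("covariate prevalence must be in [0, 1]")
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be > 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.dropout_rate < 0:
            raise ValueError("dropout rate must be >= 0")
        if self.sd_vaccine <= 0 or (self.sd_control <= 0 and not self.control_degenerate):
            raise ValueError("biomarker standard deviations must be > 0")
        self.competing = [
            c if isinstance(c, CompetingCause) else CompetingCause(**c)
            for c in self.competing
        ]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        return cls(**d)


def _linear_predictor(cfg: TrialConfig, T, x, v):
    return (cfg.beta_t * T + cfg.beta_t2 * T**2
            + cfg.beta_covariate * x + cfg.beta_vaccine * v)


def simulate_trial(config: TrialConfig, seed: int | None = None) -> StudyTable:
    """Draw one trial; ``seed`` overrides ``config.seed`` when given.

    Per subject: covariate ~ Bernoulli(prevalence); biomarker from the
    arm/covariate normal law; each cause's latent time by inverse transform
    from its exponential-baseline PH hazard; the observed time is the
    minimum of cause times, dropout and the administrative horizon, with
    cause 0 recorded when censoring comes first.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_vaccine + cfg.n_control
    v = np.concatenate([np.ones(cfg.n_vaccine), np.zeros(cfg.n_control)])
    x = (rng.random(n) < cfg.covariate_prevalence).astype(float)
    mu = np.where(v == 1, cfg.mu_vaccine, cfg.mu_control) + cfg.covariate_shift * x
    sd = np.where(v == 1, cfg.sd_vaccine,
                  0.0 if cfg.control_degenerate else cfg.sd_control)
    T = mu + sd * rng.standard_normal(n)
    if cfg.control_degenerate:
        T = np.where(v == 1, T, 0.0)

    hazards = [(cfg.baseline_rate, _linear_predictor(cfg, T, x, v))]
    for cc in cfg.competing:
        lp = cc.beta_t * T + cc.beta_covariate * x + cc.beta_vaccine * v
        hazards.append((cc.rate, lp))
    times = np.empty((len(hazards), n))
    for k, (rate, lp) in enumerate(hazards):
        u = rng.random(n)
        times[k] = -np.log(u) / (rate * np.exp(np.clip(lp, -500, 500)))
    dropout = (
        -np.log(rng.random(n)) / cfg.dropout_rate
        if cfg.dropout_rate > 0
        else np.full(n, np.inf)
    )
    first_cause_time = times.min(axis=0)
    which = times.argmin(axis=0) + 1
    censor_time = np.minimum(dropout, cfg.horizon)
    observed = np.minimum(first_cause_time, censor_time)
    cause = np.where(first_cause_time <= censor_time, which, 0)
    observed = np.maximum(observed, 1e-9)  # StudyTable requires time > 0

    df = pd.DataFrame(
        {
            "subject_id": [f"s{i:06d}" for i in range(n)],
            "arm": np.where(v == 1, "vaccine", "control"),
            "time": observed,
            "cause": cause.astype(int),
            cfg.covariate_name: x.astype(int),
            cfg.biomarker_name: T,
        }
    )
    # cause codes must be contiguous: drop unused competing codes if none occurred
    present = sorted(set(df["cause"]) - {0})
    recode = {0: 0, **{c: i + 1 for i, c in enumerate(present)}}
    df["cause"] = df["cause"].map(recode)
    return StudyTable(df, covariates=[cfg.covariate_name],
                      biomarkers=[cfg.biomarker_name])


def _mgf_normal(beta: float, mu: float, sigma: float) -> float:
    """E[exp(beta*T)] for T ~ N(mu, sigma^2)."""
    return float(np.exp(beta * mu + 0.5 * beta**2 * sigma**2))


def _mean_rho_quadratic(b1, b2, mu, sigma, tol=1e-8):
    """E[exp(b1*T + b2*T^2)] under N(mu, sigma^2) by adaptive quadrature."""
    if sigma == 0:
        return float(np.exp(b1 * mu + b2 * mu**2))
    if 2.0 * b2 * sigma**2 >= 1.0:
        raise ValueError("quadratic hazard link diverges under this biomarker law")

    def integrand(z):
        t = mu + sigma * z
        return np.exp(b1 * t + b2 * t**2 - 0.5 * z**2) / np.sqrt(2 * np.pi)

    val, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=tol, epsrel=tol)
    return float(val)


def true_ve(config: TrialConfig, subgroup_level: int | None = None) -> float:
    """Analytic VE (percent) implied by the generator's biomarker laws.

    With a linear hazard link, the ratio of expected hazard ratios between
    arms has the closed form exp(beta*(mu_v - mu_c) + beta^2*(sd_v^2 - sd_c^2)/2)
    (normal moment-generating function); the quadratic link falls back to
    adaptive quadrature over the two normal laws. The covariate shift moves
    both arms' means equally, so subgroup VE is level-independent unless a
    direct vaccine effect is configured (which the oracle excludes).
    """
    cfg = config
    if cfg.beta_vaccine != 0.0:
        raise ValueError("true_ve assumes full mediation (no direct vaccine effect)")
    shift = cfg.covariate_shift * (subgroup_level or 0)
    mu_v = cfg.mu_vaccine + shift
    mu_c = (0.0 if cfg.control_degenerate else cfg.mu_control + shift)
    sd_v = cfg.sd_vaccine
    sd_c = 0.0 if cfg.control_degenerate else cfg.sd_control
    if cfg.beta_t2 == 0.0:
        ratio = _mgf_normal(cfg.beta_t, mu_v, sd_v) / _mgf_normal(cfg.beta_t, mu_c, sd_c)
    else:
        ratio = (
            _mean_rho_quadratic(cfg.beta_t, cfg.beta_t2, mu_v, sd_v)
            / _mean_rho_quadratic(cfg.beta_t, cfg.beta_t2, mu_c, sd_c)
        )
    return float((1.0 - ratio) * 100.0)
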