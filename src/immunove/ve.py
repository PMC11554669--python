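"""Risk curves and immunogenicity-based vaccine efficacy estimation.

The risk curve rho(T | X) is the hazard ratio at biomarker value T relative
to a reference value T_ref, holding the baseline covariate profile X fixed.
Subgroup vaccine efficacy integrates the fitted risk curve over the observed
immunogenicity distributions of the two arms:

    VE = (1 - mean_i rho(T_i^vaccinated) / mean_m rho(T_m^control)) * 100

where each subject contributes their own biomarker value and covariate
vector. The confidence interval combines a stratified bootstrap of subjects
with one multivariate-normal draw of the model coefficients per replicate
(percentile CI). A case-count comparator (incidence-rate ratio with an
exact conditional-binomial CI) is provided for the classical estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import StudyTable
from .survival import CoxPH, CoxPHResults, DesignSpec, _t_columns

__all__ = [
    "RiskCurve",
    "VEEstimate",
    "risk_curve",
    "case_count_ve",
    "immunogenicity_ve",
    "ve_confidence_interval",
    "ve_from_vaccination_status",
]


@dataclass
class VEEstimate:
    """Point estimate and 95% CI of subgroup vaccine efficacy, in percent."""

    point: float
    ci_low: float
    ci_high: float
    method: str  # case_count | model_vaccination_status | model_immunogenicity
    subgroup: str = ""
    n_bootstrap: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.point) and self.point > 100.0 + 1e-9:
            raise ValueError("VE cannot exceed 100%")

    def __str__(self) -> str:
        def fmt(v):
            return "-Inf" if v == -np.inf else ("NA" if np.isnan(v) else f"{v:.0f}")

        label = f" [{self.subgroup}]" if self.subgroup else ""
        return (
            f"VE{label} = {fmt(self.point)}% "
            f"(95% CI, {fmt(self.ci_low)} to {fmt(self.ci_high)}) [{self.method}]"
        )


# ---------------------------------------------------------------------------
# design-row construction for arbitrary biomarker values
# ---------------------------------------------------------------------------


def _design_rows(spec: DesignSpec, names: list[str], T, profile: dict) -> np.ndarray:
    """Design rows at biomarker values ``T`` under a fixed covariate profile.

    ``profile`` maps covariate names (and optionally ``"vaccination"``) to
    numeric values; every non-biomarker term of the model must be covered.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    t_cols = _t_columns(T, spec.immunogenicity_term)
    by_name: dict[str, np.ndarray] = dict(zip(spec.t_term_names(), t_cols))
    base: dict[str, np.ndarray] = {spec.biomarker: t_cols[0]}
    for cov in spec.covariates:
        if cov not in profile:
            raise KeyError(f"covariate profile is missing term {cov!r}")
        base[cov] = np.full(len(T), float(profile[cov]))
        by_name[cov] = base[cov]
    if spec.include_vaccination or any("vaccination" in pair for pair in spec.interactions):
        base["vaccination"] = np.full(len(T), float(profile.get("vaccination", 0.0)))
        by_name["vaccination"] = base["vaccination"]
    for a, b in spec.interactions:
        by_name[f"{a}:{b}"] = base[a] * base[b]
    try:
        return np.column_stack([by_name[name] for name in names])
    except KeyError as err:
        raise KeyError(f"profile cannot supply design column {err}") from err


def _results_spec(results) -> DesignSpec:
    spec = getattr(results, "spec", None)
    if spec is None:
        raise ValueError("fit does not carry a design spec; build it with "
                         "from_study_table so risk curves can be evaluated")
    return spec


@dataclass
class RiskCurve:
    """Hazard ratio rho(T | X) = exp(lp(T, X) - lp(T_ref, X)).

    rho(T_ref) = 1 exactly, rho > 0 everywhere, and rho is unchanged by any
    additive shift of the linear predictor (the baseline hazard and any
    profile-constant terms cancel).
    """

    results: CoxPHResults
    profile: dict
    t_ref: float

    def __post_init__(self) -> None:
        self.spec = _results_spec(self.results)
        self.names = list(self.results.params.index)
        self._ref_row = _design_rows(self.spec, self.names, [self.t_ref], self.profile)

    def __call__(self, T) -> np.ndarray:
        rows = _design_rows(self.spec, self.names, T, self.profile)
        beta = self.results.params.to_numpy()
        diff = (rows - self._ref_row) @ beta
        return np.exp(diff)

    def confidence_band(self, T, alpha: float = 0.05) -> pd.DataFrame:
        """Pointwise delta-method CI on the log hazard-ratio scale."""
        T = np.atleast_1d(np.asarray(T, dtype=float))
        rows = _design_rows(self.spec, self.names, T, self.profile) - self._ref_row
        beta = self.results.params.to_numpy()
        cov = self.results.cov_params.to_numpy()
        diff = rows @ beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", rows, cov, rows), 0.0))
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"T": T, "hr": np.exp(diff),
             "lower": np.exp(diff - z * se), "upper": np.exp(diff + z * se)}
        )

    def plot(self, T_grid=None, ax=None):
        """Basic risk-curve plot with the pointwise 95% band."""
        import matplotlib.pyplot as plt

        if T_grid is None:
            T_grid = np.linspace(self.t_ref - 2.0, self.t_ref + 2.0, 101)
        band = self.confidence_band(T_grid)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(band["T"], band["hr"], color="C0")
        ax.fill_between(band["T"], band["lower"], band["upper"], alpha=0.25, color="C0")
        ax.axhline(1.0, color="0.5", lw=0.8)
        ax.axvline(self.t_ref, color="k", lw=0.8)
        ax.set_xlabel("immunogenicity T")
        ax.set_ylabel(r"hazard ratio $\rho(T)$")
        return ax


def risk_curve(results: CoxPHResults, profile: dict | None = None,
               t_ref: float | None = None,
               table: StudyTable | None = None) -> RiskCurve:
    """Build the risk curve of a fitted model at a covariate profile.

    ``t_ref`` defaults to the median of all observed biomarker values in
    ``table`` (the reference only shifts the curve; it cancels in VE).
    """
    if not results.converged:
        raise ValueError("risk curve requires a converged fit")
    spec = _results_spec(results)
    if t_ref is None:
        if table is None:
            raise ValueError("supply t_ref or a table to take the median from")
        t_ref = float(np.median(table.data[spec.biomarker].to_numpy(dtype=float)))
    return RiskCurve(results, dict(profile or {}), float(t_ref))


# ---------------------------------------------------------------------------
# case-count comparator
# ---------------------------------------------------------------------------


def case_count_ve(cases_v: int, py_v: float, cases_c: int, py_c: float,
                  subgroup: str = "") -> VEEstimate:
    """Classical VE from incidence rates, with an exact conditional CI.

    VE = (1 - (cases_v/py_v)/(cases_c/py_c)) * 100. Conditional on the total
    case count, the vaccine-arm count is binomial with success probability
    p = IRR*py_v / (IRR*py_v + py_c); a Clopper-Pearson interval for p maps
    monotonically to an exact CI for the incidence-rate ratio.
    """
    if py_v <= 0 or py_c <= 0:
        raise ValueError("person-years must be positive")
    cases_v, cases_c = int(cases_v), int(cases_c)
    if cases_v < 0 or cases_c < 0:
        raise ValueError("case counts must be non-negative")
    n = cases_v + cases_c
    if n == 0:
        raise ValueError("VE undefined: zero cases in both arms")
    if cases_c == 0:
        point = -np.inf
    else:
        point = (1.0 - (cases_v / py_v) / (cases_c / py_c)) * 100.0
    # Clopper-Pearson bounds for the conditional binomial proportion
    x = cases_v
    p_lo = 0.0 if x == 0 else float(stats.beta.ppf(0.025, x, n - x + 1))
    p_hi = 1.0 if x == n else float(stats.beta.ppf(0.975, x + 1, n - x))

    def _ve(p):
        if p >= 1.0:
            return -np.inf
        irr = (p / (1.0 - p)) * (py_c / py_v)
        return (1.0 - irr) * 100.0

    return VEEstimate(point=float(point), ci_low=_ve(p_hi), ci_high=_ve(p_lo),
                      method="case_count", subgroup=subgroup)


# ---------------------------------------------------------------------------
# immunogenicity-based estimation
# ---------------------------------------------------------------------------


def _subgroup_mask(table: StudyTable, subgroup) -> np.ndarray:
    if subgroup is None:
        return np.ones(len(table), dtype=bool)
    if callable(subgroup):
        return np.asarray(subgroup(table.data), dtype=bool)
    if isinstance(subgroup, tuple) and len(subgroup) == 2:
        col, val = subgroup
        return (table.data[col] == val).to_numpy()
    return np.asarray(subgroup, dtype=bool)


def _rho_design(results, table: StudyTable, mask) -> np.ndarray:
    """Design matrix for rho at each subject's own biomarker and covariates.

    The vaccination-status column (present in Prentice-augmented fits) is
    zeroed: the risk curve is a function of the biomarker and baseline
    covariates only, so both arms are evaluated on the same curve.
    """
    from .survival import build_design

    spec = _results_spec(results)
    sub = table.data[mask]
    X, names = build_design(sub, spec)
    if list(results.params.index) != names:
        raise ValueError("fit design columns do not match the table")
    if "vaccination" in names:
        X = X.copy()
        X[:, names.index("vaccination")] = 0.0
    return X


def immunogenicity_ve(results, table: StudyTable, subgroup=None,
                      beta: np.ndarray | None = None) -> float:
    """Point estimate (percent) of subgroup VE from the fitted risk model.

    Averages rho over the vaccinated subjects' observed biomarker values
    (each with their own covariate vector) and divides by the same average
    over control subjects. The reference value and baseline hazard cancel.
    """
    mask = _subgroup_mask(table, subgroup)
    X = _rho_design(results, table, mask)
    b = results.params.to_numpy() if beta is None else np.asarray(beta, dtype=float)
    is_vax = table.is_vaccine[mask]
    if is_vax.sum() == 0 or (~is_vax).sum() == 0:
        raise ValueError("subgroup must contain subjects from both arms")
    rho = np.exp(np.clip(X @ b, -500, 500))
    return float((1.0 - rho[is_vax].mean() / rho[~is_vax].mean()) * 100.0)


def _coef_sampler(results):
    """Cholesky factor of the coefficient covariance (point mass if singular)."""
    cov = results.cov_params.to_numpy()
    if not np.all(np.isfinite(cov)):
        raise ValueError("fit covariance is not finite")
    if np.allclose(cov, 0.0):
        return np.zeros_like(cov)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eigval, eigvec = np.linalg.eigh(cov)
        if np.any(eigval < -1e-8):
            warnings.warn("singular coefficient covariance; parameter resampling "
                          "collapses to the point estimate", stacklevel=3)
            return np.zeros_like(cov)
        return eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))


def ve_confidence_interval(results, table: StudyTable, subgroup=None,
                           n_bootstrap: int = 1000, seed: int = 0,
                           subgroup_label: str = "") -> VEEstimate:
    """Hybrid bootstrap / parametric-resampling percentile CI for subgroup VE.

    Each replicate (i) resamples subjects with replacement within each arm
    of the subgroup, carrying every subject's full biomarker/covariate
    record, and (ii) draws one coefficient vector from the multivariate
    normal with the fit's point estimate and covariance; the VE of the
    replicate is computed from those. The CI is the empirical 2.5th/97.5th
    percentile (inverse-ECDF convention) of the replicate VEs; the point
    estimate uses the original data and point coefficients. Fully
    reproducible given ``seed``.
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    if not results.converged:
        raise ValueError("confidence interval requires a converged fit")
    mask = _subgroup_mask(table, subgroup)
    X = _rho_design(results, table, mask)
    is_vax = table.is_vaccine[mask]
    Xv, Xc = X[is_vax], X[~is_vax]
    if len(Xv) == 0 or len(Xc) == 0:
        raise ValueError("subgroup must contain subjects from both arms")
    beta_hat = results.params.to_numpy()
    L = _coef_sampler(results)
    point = immunogenicity_ve(results, table, subgroup)

    rng = np.random.default_rng(seed)
    p = len(beta_hat)
    ves = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        iv = rng.integers(0, len(Xv), size=len(Xv))
        ic = rng.integers(0, len(Xc), size=len(Xc))
        beta_b = beta_hat + L @ rng.standard_normal(p)
        rv = np.exp(np.clip(Xv[iv] @ beta_b, -500, 500)).mean()
        rc = np.exp(np.clip(Xc[ic] @ beta_b, -500, 500)).mean()
        ves[b] = (1.0 - rv / rc) * 100.0
    lo, hi = np.percentile(ves, [2.5, 97.5], method="inverted_cdf")
    return VEEstimate(point=point, ci_low=float(lo), ci_high=float(hi),
                      method="model_immunogenicity", subgroup=subgroup_label,
                      n_bootstrap=n_bootstrap, seed=seed)


def ve_from_vaccination_status(table: StudyTable, covariate: str | None = None,
                               level=None, subgroup_label: str = "") -> VEEstimate:
    """Classical model-based VE: 1 - HR of vaccination within a subgroup.

    Fits a composite-endpoint Cox model with vaccination status, the
    subgroup covariate and their interaction; the subgroup hazard ratio is
    exp(beta_vacc + level * beta_interaction) with a Wald CI on the log-HR
    scale. Without ``covariate`` the overall vaccination HR is used.
    """
    df = table.data
    table.arm_split()
    vacc = table.is_vaccine.astype(float)
    cols, names = [vacc], ["vaccination"]
    if covariate is not None:
        x = df[covariate].to_numpy(dtype=float)
        cols += [x, vacc * x]
        names += [covariate, f"vaccination:{covariate}"]
    X = np.column_stack(cols)
    res = CoxPH(df["time"].to_numpy(), (df["cause"] >= 1).astype(float),
                X, names=names).fit()
    if not res.converged:
        raise ValueError("vaccination-status model did not converge")
    c = np.zeros(len(names))
    c[0] = 1.0
    if covariate is not None:
        if level is None:
            raise ValueError("level is required when a covariate is given")
        c[2] = float(level)
    log_hr = float(c @ res.params.to_numpy())
    se = float(np.sqrt(c @ res.cov_params.to_numpy() @ c))
    z = stats.norm.ppf(0.975)
    return VEEstimate(
        point=(1.0 - np.exp(log_hr)) * 100.0,
        ci_low=(1.0 - np.exp(log_hr + z * se)) * 100.0,
        ci_high=(1.0 - np.exp(log_hr - z * se)) * 100.0,
        method="model_vaccination_status",
        subgroup=subgroup_label,
    )
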