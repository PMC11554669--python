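"""Proportional-hazards engine: Cox, cause-specific and Fine-Gray fits.

Model objects are built from arrays (or a :class:`~immunove.data_model.StudyTable`
via a design spec) and their ``fit()`` returns a results object carrying the
coefficient vector, its covariance, the log partial likelihood, AIC and a
``summary()`` table, in the style of statsmodels.

The partial likelihood is maximized by Newton-Raphson with step-halving.
Ties are handled by the Efron approximation by default (Breslow available).
Case weights are supported throughout, which is what the Fine-Gray
subdistribution fit builds on: subjects failing from a competing cause stay
in the risk set past their event with inverse-probability-of-censoring
weights G(t)/G(s) from a Kaplan-Meier estimate of the censoring
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import StudyTable

__all__ = [
    "DesignSpec",
    "build_design",
    "CoxPH",
    "CoxPHResults",
    "FineGray",
    "FineGrayResults",
    "CIFEstimate",
    "PHDiagnostic",
    "estimate_cif",
    "ph_test",
    "model_tests",
    "ConvergenceWarning",
]

#: Newton-Raphson stopping rules (fixed so fits are bit-reproducible)
SCORE_TOL = 1e-8
LL_RTOL = 1e-10
MAX_ITER = 50
#: |beta| * sd(x) beyond this is treated as monotone-likelihood divergence
DIVERGENCE_SCALE = 10.0


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

_T_FORMS = ("linear", "quadratic", "log", "sqrt")


@dataclass
class DesignSpec:
    """Describes how a model design matrix is built from a study table.

    ``immunogenicity_term`` selects the functional form of the biomarker T:
    linear (T), quadratic (T and T^2), log(T) or sqrt(T). ``interactions``
    are pairs of term names (biomarker, covariate or ``"vaccination"``);
    the biomarker name refers to its first (linear-order) transformed
    column. Column order is deterministic: T terms, covariates,
    interactions, vaccination status.
    """

    biomarker: str
    immunogenicity_term: str = "linear"
    covariates: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    include_vaccination: bool = False

    def __post_init__(self) -> None:
        if self.immunogenicity_term not in _T_FORMS:
            raise ValueError(
                f"immunogenicity_term must be one of {_T_FORMS},"
                f" got {self.immunogenicity_term!r}"
            )
        declared = {self.biomarker, *self.covariates, "vaccination"}
        for a, b in self.interactions:
            if a not in declared or b not in declared:
                raise ValueError(f"interaction ({a}, {b}) references undeclared terms")

    @property
    def n_t_terms(self) -> int:
        return 2 if self.immunogenicity_term == "quadratic" else 1

    def t_term_names(self) -> list[str]:
        t = self.biomarker
        return {
            "linear": [t],
            "quadratic": [t, f"{t}^2"],
            "log": [f"log({t})"],
            "sqrt": [f"sqrt({t})"],
        }[self.immunogenicity_term]


def _t_columns(values: np.ndarray, form: str) -> list[np.ndarray]:
    if form == "linear":
        return [values]
    if form == "quadratic":
        return [values, values**2]
    if np.any(values <= 0):
        raise ValueError(f"{form} transform requires positive biomarker values")
    return [np.log(values) if form == "log" else np.sqrt(values)]


def build_design(
    table: StudyTable | pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, list[str]]:
    """Build the (subjects x terms) design matrix for ``spec``.

    Categorical covariates are expanded to reference-coded indicators.
    Returns the matrix and its deterministic column names.
    """
    df = table.data if isinstance(table, StudyTable) else table
    if spec.biomarker not in df.columns:
        raise KeyError(f"biomarker column {spec.biomarker!r} not in table")
    cols: list[np.ndarray] = []
    names: list[str] = []
    t_raw = df[spec.biomarker].to_numpy(dtype=float)
    t_cols = _t_columns(t_raw, spec.immunogenicity_term)
    cols += t_cols
    names += spec.t_term_names()

    base: dict[str, np.ndarray] = {spec.biomarker: t_cols[0]}
    for cov in spec.covariates:
        series = df[cov]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True)
            for dcol in dummies.columns:
                arr = dummies[dcol].to_numpy(dtype=float)
                cols.append(arr)
                names.append(str(dcol))
            base[cov] = dummies.to_numpy(dtype=float)[:, 0] if dummies.shape[1] else None
        else:
            arr = series.to_numpy(dtype=float)
            cols.append(arr)
            names.append(cov)
            base[cov] = arr
    if spec.interactions or spec.include_vaccination:
        vacc = (df["arm"] == "vaccine").to_numpy(dtype=float) if "arm" in df else None
        base["vaccination"] = vacc
    for a, b in spec.interactions:
        xa, xb = base.get(a), base.get(b)
        if xa is None or xb is None:
            raise ValueError(f"interaction ({a}, {b}) references an unusable term")
        cols.append(xa * xb)
        names.append(f"{a}:{b}")
    if spec.include_vaccination:
        cols.append(base["vaccination"])
        names.append("vaccination")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# weighted partial likelihood (Efron / Breslow)
# ---------------------------------------------------------------------------


def _partial_loglik(beta, X, time, event, weights, ties):
    """(log partial likelihood, score vector, observed information matrix).

    Vectorized over event-time groups; Efron handles tied deaths by the
    fractional removal of the tied subjects' weighted risk contributions.
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    Xs, ts, es, ws = X[order], time[order], event[order].astype(bool), weights[order]
    lp = np.clip(Xs @ beta, -500, 500)
    r = ws * np.exp(lp)
    rx = Xs * r[:, None]
    rxx = Xs[:, :, None] * Xs[:, None, :] * r[:, None, None]

    # suffix sums: risk set of an event time = all rows at or after its group start
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rx[::-1], axis=0)[::-1]
    S2 = np.cumsum(rxx[::-1], axis=0)[::-1]

    _, starts = np.unique(ts, return_index=True)
    n_groups = len(starts)
    group_of = np.searchsorted(starts, np.arange(n), side="right") - 1

    didx = np.flatnonzero(es)
    if len(didx) == 0:
        raise ValueError("no events in the data")
    dgroup = group_of[didx]
    d_g = np.bincount(dgroup, minlength=n_groups).astype(float)
    W_g = np.bincount(dgroup, weights=ws[didx], minlength=n_groups)
    sum_wlp = np.bincount(dgroup, weights=ws[didx] * lp[didx], minlength=n_groups)
    sum_wx = np.zeros((n_groups, p))
    SD1 = np.zeros((n_groups, p))
    SD2 = np.zeros((n_groups, p, p))
    np.add.at(sum_wx, dgroup, ws[didx, None] * Xs[didx])
    SD0 = np.bincount(dgroup, weights=r[didx], minlength=n_groups)
    np.add.at(SD1, dgroup, rx[didx])
    np.add.at(SD2, dgroup, rxx[didx])

    gsel = np.flatnonzero(d_g > 0)
    d_sel = d_g[gsel].astype(int)
    rep = np.repeat(gsel, d_sel)
    l = np.concatenate([np.arange(d) for d in d_sel]) if len(d_sel) else np.array([])
    frac = (l / d_g[rep]) if ties == "efron" else np.zeros(len(rep))

    sidx = starts[rep]
    denom = S0[sidx] - frac * SD0[rep]
    num1 = S1[sidx] - frac[:, None] * SD1[rep]
    num2 = S2[sidx] - frac[:, None, None] * SD2[rep]
    wl = W_g[rep] / d_g[rep]  # per-(group, l) weight

    ll = sum_wlp.sum() - np.sum(wl * np.log(denom))
    xbar = num1 / denom[:, None]
    score = sum_wx.sum(axis=0) - np.sum(wl[:, None] * xbar, axis=0)
    info = np.einsum("m,mij->ij", wl, num2 / denom[:, None, None]) - np.einsum(
        "m,mi,mj->ij", wl, xbar, xbar
    )
    return ll, score, info


def _newton(loglik, p):
    """Maximize a concave log-likelihood; returns (beta, ll, score, info, converged, n_iter)."""
    beta = np.zeros(p)
    ll, score, info = loglik(beta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_score, new_info = loglik(new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 25:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = loglik(new_beta)
            halvings += 1
        delta_ll = abs(new_ll - ll)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score)) < SCORE_TOL or delta_ll < LL_RTOL * (abs(ll) + LL_RTOL):
            converged = True
            break
    return beta, ll, score, info, converged, it


def _safe_cov(info: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return (cov + cov.T) / 2.0


# ---------------------------------------------------------------------------
# results objects
# ---------------------------------------------------------------------------


class CoxPHResults:
    """Fitted Cox proportional-hazards model.

    Attributes
    ----------
    params : pandas.Series
        Estimated log hazard-ratio coefficients.
    cov_params : pandas.DataFrame
        Inverse observed information at the maximum.
    llf : float
        Maximized log partial likelihood.
    aic : float
        ``2*k - 2*llf``.
    converged, diverged : bool
        ``diverged`` marks monotone-likelihood/separation fits whose last
        iterate is reported but must not be interpreted as an estimate.
    cause : int
        0 for a composite/any-event fit, k for a cause-specific fit.
    """

    _kind = "Cox PH"

    def __init__(self, model, beta, ll, score, info, converged, n_iter):
        self.model = model
        names = model.names
        self.params = pd.Series(beta, index=names)
        self.cov_params = pd.DataFrame(_safe_cov(info), index=names, columns=names)
        self.llf = float(ll)
        self.score_vector = score
        self.information = info
        self.n_iter = n_iter
        self.cause = model.cause
        self.ties_method = model.ties
        self.n = len(model.time)
        self.n_events = int(model.event.sum())
        sds = model.design.std(axis=0)
        sds[sds == 0] = 1.0
        self.diverged = bool(np.max(np.abs(beta) * sds) > DIVERGENCE_SCALE)
        self.converged = bool(converged and not self.diverged)
        if not self.converged:
            warnings.warn(
                "partial-likelihood maximization did not converge"
                + (" (monotone likelihood / separation suspected)" if self.diverged else ""),
                ConvergenceWarning,
                stacklevel=3,
            )

    @property
    def df_model(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.df_model - 2.0 * self.llf

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided Wald p-values per coefficient."""
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues.to_numpy())), index=self.params.index
        )

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def linear_predictor(self, design: np.ndarray) -> np.ndarray:
        return np.asarray(design, dtype=float) @ self.params.to_numpy()

    def baseline_cumulative_hazard(self) -> pd.Series:
        """Breslow estimator of the baseline cumulative hazard.

        Provided for simulation checks only: every efficacy quantity in this
        package depends on hazard ratios, which cancel the baseline.
        """
        m = self.model
        lp = np.clip(m.design @ self.params.to_numpy(), -500, 500)
        r = m.weights * np.exp(lp)
        order = np.argsort(m.time, kind="stable")
        ts, es, rs = m.time[order], m.event[order].astype(bool), r[order]
        S0 = np.cumsum(rs[::-1])[::-1]
        times, starts = np.unique(ts, return_index=True)
        d = np.zeros(len(times))
        np.add.at(d, np.searchsorted(times, ts[es]), m.weights[order][es])
        h0 = d / S0[starts]
        keep = d > 0
        return pd.Series(np.cumsum(h0[keep]), index=times[keep])

    def summary(self) -> str:
        hr_ci = np.exp(self.conf_int().to_numpy())
        rows = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "HR": self.hazard_ratios(),
                "HR 2.5%": hr_ci[:, 0],
                "HR 97.5%": hr_ci[:, 1],
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )
        head = (
            f"{self._kind} fit  (cause={self.cause}, ties={self.ties_method})\n"
            f"n = {self.n}, events = {self.n_events}, "
            f"log PL = {self.llf:.4f}, AIC = {self.aic:.4f}\n"
            f"converged = {self.converged}"
            + (", DIVERGED (monotone likelihood)" if self.diverged else "")
            + f", iterations = {self.n_iter}\n"
        )
        return head + rows.to_string(float_format=lambda v: f"{v:.4f}")

    def to_dict(self) -> dict:
        return {
            "kind": self._kind,
            "cause": self.cause,
            "n": self.n,
            "n_events": self.n_events,
            "coefficients": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "wald_p": self.pvalues.to_dict(),
            "log_partial_likelihood": self.llf,
            "aic": self.aic,
            "converged": self.converged,
            "diverged": self.diverged,
            "ties": self.ties_method,
        }


class FineGrayResults(CoxPHResults):
    """Fitted Fine-Gray subdistribution-hazards model.

    ``llf`` is a log *pseudo*-partial likelihood (IPCW-weighted); the
    covariance is the inverse weighted information matrix. ``aic`` uses the
    pseudo-likelihood and is comparable only across Fine-Gray fits for the
    same cause on the same data.
    """

    _kind = "Fine-Gray"


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------


class CoxPH:
    """Cox proportional-hazards model lambda0(t) * exp(beta' x).

    Parameters
    ----------
    time, event : array-like
        Follow-up times (> 0) and 0/1 event indicators.
    design : array-like (n x p)
        Predictor matrix (no intercept; the baseline hazard absorbs it).
    names : list of str, optional
    weights : array-like, optional
        Case weights (used by the Fine-Gray machinery).
    ties : {"efron", "breslow"}
    cause : int
        Tag recorded on the results (0 = composite endpoint).
    """

    def __init__(self, time, event, design, names=None, weights=None,
                 ties="efron", cause=0):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=float)
        design = np.asarray(design, dtype=float)
        if design.ndim == 1:
            design = design[:, None]
        self.design = design
        n, p = design.shape
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("time/event/design lengths differ")
        if np.any(self.time <= 0):
            raise ValueError("times must be positive")
        if self.event.sum() < 1:
            raise ValueError("at least one event is required")
        self.names = list(names) if names is not None else [f"x{j}" for j in range(p)]
        self.weights = (
            np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        )
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties
        self.cause = cause

    @classmethod
    def from_study_table(cls, table: StudyTable, spec: DesignSpec,
                         target_cause: int | None = None, ties="efron") -> "CoxPH":
        """Build the model from a study table and design spec.

        With ``target_cause`` k, fits the cause-specific hazard for cause k:
        events are rows with that cause and competing events are censored at
        their times. Without it, any cause >= 1 counts as the event
        (composite endpoint).
        """
        X, names = build_design(table, spec)
        cause = table.data["cause"].to_numpy()
        if target_cause is None:
            event = (cause >= 1).astype(float)
            tag = 0
        else:
            if target_cause < 1 or not np.any(cause == target_cause):
                raise ValueError(f"target cause {target_cause} absent from the data")
            event = (cause == target_cause).astype(float)
            tag = int(target_cause)
        model = cls(table.data["time"].to_numpy(), event, X, names=names,
                    ties=ties, cause=tag)
        model.spec = spec
        return model

    def loglik(self, beta) -> float:
        """Log partial likelihood at ``beta`` (Efron/Breslow per ``self.ties``)."""
        ll, _, _ = _partial_loglik(
            np.atleast_1d(np.asarray(beta, dtype=float)),
            self.design, self.time, self.event, self.weights, self.ties,
        )
        return float(ll)

    def _objective(self, beta):
        return _partial_loglik(beta, self.design, self.time, self.event,
                               self.weights, self.ties)

    def fit(self) -> CoxPHResults:
        res = _newton(self._objective, self.design.shape[1])
        results = CoxPHResults(self, *res)
        results.spec = getattr(self, "spec", None)
        return results


class FineGray:
    """Fine-Gray model for the subdistribution hazard of one cause.

    Subjects who fail from a competing cause at time s remain in the risk
    set at every later event time t of the target cause, down-weighted by
    G(t-)/G(s-) where G is the Kaplan-Meier estimate of the censoring
    distribution (pooled across arms). The weighted pseudo-partial
    likelihood is maximized by the same Newton machinery as :class:`CoxPH`.
    """

    def __init__(self, time, cause, design, target_cause, names=None, ties="efron"):
        self.time = np.asarray(time, dtype=float)
        self.cause = np.asarray(cause, dtype=int)
        design = np.asarray(design, dtype=float)
        if design.ndim == 1:
            design = design[:, None]
        self.design = design
        self.target_cause = int(target_cause)
        if self.target_cause < 1:
            raise ValueError("target cause must be >= 1")
        if not np.any(self.cause == self.target_cause):
            raise ValueError(f"target cause {target_cause} absent from the data")
        if np.all(self.cause == 0):
            raise ValueError("all observations censored")
        self.names = (
            list(names) if names is not None else [f"x{j}" for j in range(design.shape[1])]
        )
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties
        self._prepare()

    @classmethod
    def from_study_table(cls, table: StudyTable, spec: DesignSpec,
                         target_cause: int, ties="efron") -> "FineGray":
        X, names = build_design(table, spec)
        model = cls(table.data["time"].to_numpy(), table.data["cause"].to_numpy(),
                    X, target_cause, names=names, ties=ties)
        model.spec = spec
        return model

    def _prepare(self) -> None:
        t, c = self.time, self.cause
        # censoring-distribution Kaplan-Meier G(t-) (censoring as the event)
        self._G_times, self._G_surv = _km_censoring(t, c)
        self._event_times = np.unique(t[c == self.target_cause])
        competing = (c >= 1) & (c != self.target_cause)
        self._competing = competing
        # IPCW weight of each competing-event subject at each target event time
        G_at_event = _km_left(self._G_times, self._G_surv, self._event_times)
        G_at_own = _km_left(self._G_times, self._G_surv, t)
        n_ev = len(self._event_times)
        n = len(t)
        W = np.zeros((n_ev, n))
        natural = t[None, :] >= self._event_times[:, None]
        W[natural] = 1.0
        comp_rows = np.flatnonzero(competing)
        for i in comp_rows:
            past = self._event_times > t[i]
            if G_at_own[i] > 0:
                W[past, i] = G_at_event[past] / G_at_own[i]
        self._W = W

    def loglik(self, beta) -> float:
        ll, _, _ = self._objective(np.atleast_1d(np.asarray(beta, dtype=float)))
        return float(ll)

    def _objective(self, beta):
        X, t, c = self.design, self.time, self.cause
        lp = np.clip(X @ beta, -500, 500)
        e = np.exp(lp)
        p = X.shape[1]
        ll = 0.0
        score = np.zeros(p)
        info = np.zeros((p, p))
        for j, tj in enumerate(self._event_times):
            w = self._W[j]
            active = w > 0
            wa = w[active]
            Xa = X[active]
            ra = wa * e[active]
            S0 = ra.sum()
            S1 = ra @ Xa
            S2 = (Xa * ra[:, None]).T @ Xa
            deaths = np.flatnonzero((c == self.target_cause) & (t == tj))
            d = len(deaths)
            SD0 = e[deaths].sum()
            SD1 = e[deaths] @ X[deaths]
            SD2 = (X[deaths] * e[deaths][:, None]).T @ X[deaths]
            ll += lp[deaths].sum()
            score += X[deaths].sum(axis=0)
            for l in range(d):
                frac = (l / d) if self.ties == "efron" else 0.0
                denom = S0 - frac * SD0
                num1 = S1 - frac * SD1
                num2 = S2 - frac * SD2
                ll -= np.log(denom)
                xbar = num1 / denom
                score -= xbar
                info += num2 / denom - np.outer(xbar, xbar)
        return ll, score, info

    def fit(self) -> FineGrayResults:
        beta, ll, score, info, converged, it = _newton(self._objective, self.design.shape[1])
        shim = _FGModelShim(self)
        results = FineGrayResults(shim, beta, ll, score, info, converged, it)
        results.cause = self.target_cause
        results.censoring_survival = pd.Series(self._G_surv, index=self._G_times)
        results.spec = getattr(self, "spec", None)
        return results


class _FGModelShim:
    """Adapts a FineGray model to the attribute surface CoxPHResults expects."""

    def __init__(self, fg: FineGray):
        self.names = fg.names
        self.time = fg.time
        self.event = (fg.cause == fg.target_cause).astype(float)
        self.design = fg.design
        self.weights = np.ones(len(fg.time))
        self.ties = fg.ties
        self.cause = fg.target_cause
        self.finegray = fg


def _km_censoring(time, cause):
    """Kaplan-Meier of the censoring distribution (cause 0 as the event)."""
    order = np.argsort(time, kind="stable")
    t, cens = time[order], (cause[order] == 0)
    times, starts = np.unique(t, return_index=True)
    at_risk = len(t) - starts
    d = np.zeros(len(times))
    np.add.at(d, np.searchsorted(times, t[cens]), 1)
    surv = np.cumprod(1.0 - d / at_risk)
    return times, surv


def _km_left(times, surv, query):
    """Left-continuous evaluation G(t-) of a KM step function."""
    idx = np.searchsorted(times, query, side="left") - 1
    out = np.ones(len(query))
    pos = idx >= 0
    out[pos] = surv[idx[pos]]
    return out


def fit_cause_specific(table: StudyTable, spec: DesignSpec, target_cause: int,
                       ties="efron") -> CoxPHResults:
    """Cause-specific Cox fit: competing events censored at their times."""
    return CoxPH.from_study_table(table, spec, target_cause=target_cause, ties=ties).fit()


# ---------------------------------------------------------------------------
# cumulative incidence
# ---------------------------------------------------------------------------


@dataclass
class CIFEstimate:
    """Nonparametric (Aalen-Johansen form) cumulative incidence functions.

    ``survival[j]`` is the overall (any-cause) survival just after
    ``times[j]``; ``cif[c][j]`` the cumulative incidence of cause c.
    S(t) + sum_c CIF_c(t) = 1 at every step.
    """

    times: np.ndarray
    survival: np.ndarray
    cif: dict[int, np.ndarray]

    def at(self, cause: int, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cif[cause][idx])


def estimate_cif(time, cause, mask=None) -> CIFEstimate:
    """Estimate per-cause CIFs and overall survival for one group.

    Each cause's incidence increment at an event time t_j is
    S(t_{j-1}) * d_cj / n_j, the overall survival times the cause-specific
    hazard increment; overall survival is the Kaplan-Meier of any event.
    """
    time = np.asarray(time, dtype=float)
    cause = np.asarray(cause, dtype=int)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        time, cause = time[mask], cause[mask]
    if len(time) == 0:
        raise ValueError("empty group")
    if not np.any(cause >= 1):
        raise ValueError("no events of any cause")
    order = np.argsort(time, kind="stable")
    t, c = time[order], cause[order]
    times, starts = np.unique(t, return_index=True)
    at_risk = len(t) - starts
    causes = sorted(set(c) - {0})
    d_c = {k: np.zeros(len(times)) for k in causes}
    for k in causes:
        np.add.at(d_c[k], np.searchsorted(times, t[c == k]), 1)
    d_any = np.sum([d_c[k] for k in causes], axis=0)
    surv = np.empty(len(times))
    cif = {k: np.empty(len(times)) for k in causes}
    s_prev = 1.0
    acc = {k: 0.0 for k in causes}
    for j in range(len(times)):
        haz = d_any[j] / at_risk[j]
        for k in causes:
            acc[k] += s_prev * (d_c[k][j] / at_risk[j])
            cif[k][j] = acc[k]
        s_prev *= 1.0 - haz
        surv[j] = s_prev
    return CIFEstimate(times=times, survival=surv, cif=cif)


# ---------------------------------------------------------------------------
# diagnostics and tests
# ---------------------------------------------------------------------------


@dataclass
class PHDiagnostic:
    """Proportional-hazards diagnostic from scaled Schoenfeld residuals.

    Per-term p-values of the score test for zero slope of the scaled
    residuals on time (identity time transform); ``violated`` is the global
    flag: any term significant at ``alpha``.
    """

    p_values: pd.Series
    statistics: pd.Series
    alpha: float
    transform: str = "identity"
    variant: str = "score"

    @property
    def violated(self) -> bool:
        return bool((self.p_values < self.alpha).any())


def ph_test(results: CoxPHResults, alpha: float = 0.05) -> PHDiagnostic:
    """Test the PH assumption of a fitted Cox model.

    Uses the score test for a linear association of each term's scaled
    Schoenfeld residuals with event time; a small p-value indicates a
    time-varying effect for that term.
    """
    m = results.model
    if not results.converged:
        raise ValueError("PH diagnostic requires a converged fit")
    beta = results.params.to_numpy()
    X, time, event, w = m.design, m.time, m.event.astype(bool), m.weights
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    lp = np.clip(X @ beta, -500, 500)
    r = w * np.exp(lp)
    order = np.argsort(time, kind="stable")
    Xs, ts, es, rs = X[order], time[order], event[order], r[order]
    p = X.shape[1]
    S0 = np.cumsum(rs[::-1])[::-1]
    S1 = np.cumsum((Xs * rs[:, None])[::-1], axis=0)[::-1]
    S2 = np.cumsum((Xs[:, :, None] * Xs[:, None, :] * rs[:, None, None])[::-1],
                   axis=0)[::-1]
    _, starts = np.unique(ts, return_index=True)
    group_of = np.searchsorted(starts, np.arange(len(ts)), side="right") - 1
    didx = np.flatnonzero(es)
    g = starts[group_of[didx]]
    xbar = S1[g] / S0[g, None]
    resid = Xs[didx] - xbar  # Schoenfeld residuals, one per death
    Vk = S2[g] / S0[g, None, None] - xbar[:, :, None] * xbar[:, None, :]
    g_times = ts[didx]
    gc = g_times - g_times.mean()
    # score for a coefficient on x * g(t), with beta profiled out:
    # U = sum gc_k s_k, Var = sum gc^2 V_k - (sum gc V_k) I^{-1} (sum gc V_k)
    u = resid.T @ gc
    A = np.einsum("k,kij->ij", gc**2, Vk)
    B = np.einsum("k,kij->ij", gc, Vk)
    I = np.einsum("kij->ij", Vk)
    try:
        V = A - B @ np.linalg.solve(I, B)
    except np.linalg.LinAlgError:
        V = A - B @ np.linalg.pinv(I) @ B
    var_diag = np.clip(np.diag(V), 1e-300, None)
    stat = u**2 / var_diag
    pvals = stats.chi2.sf(stat, df=1)
    return PHDiagnostic(
        p_values=pd.Series(pvals, index=results.params.index),
        statistics=pd.Series(stat, index=results.params.index),
        alpha=alpha,
    )


def model_tests(fit_reduced: CoxPHResults, fit_full: CoxPHResults):
    """Likelihood-ratio test of nested fits plus per-term Wald p-values.

    Returns ``(lrt_p, wald_p)``: the LRT compares twice the log
    partial-likelihood gain to a chi-square with df = coefficient-count
    difference; ``wald_p`` are the full model's per-term Wald p-values.
    """
    red_names = set(fit_reduced.params.index)
    full_names = set(fit_full.params.index)
    if not red_names <= full_names:
        raise ValueError("models are not nested (reduced terms not a subset)")
    if fit_reduced.n != fit_full.n or fit_reduced.n_events != fit_full.n_events:
        raise ValueError("fits are not on the same data")
    df = fit_full.df_model - fit_reduced.df_model
    stat = max(0.0, 2.0 * (fit_full.llf - fit_reduced.llf))
    lrt_p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df=df))
    if df == 0 and stat < 1e-10:
        lrt_p = 1.0
    return lrt_p, fit_full.pvalues
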