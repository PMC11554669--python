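"""Correlate-of-risk model selection and the Prentice correlate-of-protection test.

A biomarker is a *correlate of risk* (CoR) if it is significantly associated
with the clinical endpoint in the selected risk model, and a *correlate of
protection* (CoP, by the Prentice conditional-independence criterion) if it
remains significant while adding vaccination status to the model does not
significantly improve the fit.

Model selection follows a two-stage AIC procedure with a parsimony guard:
biomarker-only candidates (linear vs quadratic) first, then the winning form
unadjusted vs adjusted for covariates and their biomarker interactions. A
model with more parameters is only preferred when it beats the smaller one
by at least 2 AIC points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import StudyTable
from .survival import (
    CoxPH,
    CoxPHResults,
    DesignSpec,
    FineGray,
    model_tests,
)

__all__ = ["CoRResult", "CoPResult", "assess_cor", "prentice_test"]

#: AIC improvement required to accept one extra-parameter model
AIC_PARSIMONY_MARGIN = 2.0

MODEL_FAMILIES = ("cox", "cause_specific", "fine_gray")


@dataclass
class Candidate:
    label: str
    spec: DesignSpec
    results: object | None
    converged: bool

    @property
    def aic(self) -> float:
        return np.inf if self.results is None else self.results.aic

    @property
    def k(self) -> int:
        return 0 if self.results is None else self.results.df_model


@dataclass
class CoRResult:
    """Outcome of the correlate-of-risk assessment."""

    selected: object
    selected_label: str
    candidates: list[Candidate]
    immunogenicity_p: float
    is_cor: bool
    alpha: float
    biomarker: str
    model_family: str
    target_cause: int | None
    subgroup_tests: dict = field(default_factory=dict)

    def ledger(self) -> pd.DataFrame:
        """Candidate table: label, form, parameter count, log PL, AIC."""
        return pd.DataFrame(
            {
                "candidate": [c.label for c in self.candidates],
                "form": [c.spec.immunogenicity_term for c in self.candidates],
                "k": [c.k for c in self.candidates],
                "logPL": [None if c.results is None else c.results.llf
                          for c in self.candidates],
                "AIC": [c.aic for c in self.candidates],
                "converged": [c.converged for c in self.candidates],
                "selected": [c.label == self.selected_label for c in self.candidates],
            }
        )

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker,
            "model_family": self.model_family,
            "target_cause": self.target_cause,
            "selected": self.selected_label,
            "candidates": self.ledger().to_dict(orient="records"),
            "immunogenicity_p": self.immunogenicity_p,
            "is_cor": self.is_cor,
            "alpha": self.alpha,
            "subgroup_tests": self.subgroup_tests,
        }


@dataclass
class CoPResult:
    """Outcome of the Prentice correlate-of-protection test."""

    base: object
    augmented: object
    vaccination_p: float
    biomarker_p: float
    biomarker_still_significant: bool
    is_cop: bool
    alpha: float

    def to_dict(self) -> dict:
        return {
            "vaccination_p": self.vaccination_p,
            "biomarker_p_augmented": self.biomarker_p,
            "biomarker_still_significant": self.biomarker_still_significant,
            "is_cop": self.is_cop,
            "alpha": self.alpha,
        }


def _fit_family(table: StudyTable, spec: DesignSpec, model_family: str,
                target_cause: int | None):
    if model_family == "cox":
        return CoxPH.from_study_table(table, spec).fit()
    if model_family == "cause_specific":
        if target_cause is None:
            raise ValueError("cause_specific family requires target_cause")
        return CoxPH.from_study_table(table, spec, target_cause=target_cause).fit()
    if model_family == "fine_gray":
        if target_cause is None:
            raise ValueError("fine_gray family requires target_cause")
        return FineGray.from_study_table(table, spec, target_cause=target_cause).fit()
    raise ValueError(f"model_family must be one of {MODEL_FAMILIES}")


def _select(candidates: list[Candidate]) -> Candidate:
    """AIC selection with the parsimony guard.

    The minimum-AIC candidate wins unless a candidate with fewer parameters
    is within AIC_PARSIMONY_MARGIN of it (an extra parameter must buy more
    than 2 AIC points), in which case the smallest such candidate wins.
    Deterministic and invariant to input order.
    """
    usable = [c for c in candidates if c.converged and np.isfinite(c.aic)]
    if not usable:
        raise RuntimeError("no correlate-of-risk candidate converged")
    best_aic = min(c.aic for c in usable)
    near = [c for c in usable if c.aic - best_aic <= AIC_PARSIMONY_MARGIN]
    return min(near, key=lambda c: (c.k, c.aic, c.label))


def _t_term_names(spec: DesignSpec, names) -> list[str]:
    """All design columns involving the biomarker (main terms + interactions)."""
    t_main = set(spec.t_term_names())
    out = []
    for name in names:
        if name in t_main:
            out.append(name)
        elif ":" in name and spec.biomarker in name.split(":"):
            out.append(name)
    return out


def _joint_t_lrt(results, t_names: list[str]) -> float:
    """Joint LRT p-value for dropping every biomarker-involving term."""
    model = results.model
    names = list(results.params.index)
    keep = [j for j, nm in enumerate(names) if nm not in t_names]
    df = len(names) - len(keep)
    if df == 0:
        raise ValueError("model has no biomarker terms")
    if hasattr(model, "finegray"):
        fg = model.finegray
        if keep:
            reduced = FineGray(fg.time, fg.cause, fg.design[:, keep],
                               fg.target_cause,
                               names=[names[j] for j in keep], ties=fg.ties).fit()
            llf_reduced = reduced.llf
        else:
            llf_reduced = fg.loglik(np.zeros(fg.design.shape[1]))
    else:
        if keep:
            reduced = CoxPH(model.time, model.event, model.design[:, keep],
                            names=[names[j] for j in keep],
                            weights=model.weights, ties=model.ties,
                            cause=model.cause).fit()
            llf_reduced = reduced.llf
        else:
            llf_reduced = CoxPH(model.time, model.event, model.design,
                                names=names, weights=model.weights,
                                ties=model.ties).loglik(np.zeros(len(names)))
    stat = max(0.0, 2.0 * (results.llf - llf_reduced))
    return float(stats.chi2.sf(stat, df=df))


def _subgroup_t_tests(results, spec: DesignSpec, table: StudyTable,
                      alpha: float) -> dict:
    """Joint Wald test of the biomarker terms at each covariate level.

    For models with biomarker-by-covariate interactions, the effect of T in
    the subgroup at covariate level x is the contrast (beta_T + x * beta_{T:cov})
    per T term; the joint Wald chi-square of those contrasts gives a
    subgroup-specific CoR verdict.
    """
    out: dict = {}
    names = list(results.params.index)
    beta = results.params.to_numpy()
    cov = results.cov_params.to_numpy()
    t_main = spec.t_term_names()
    for covname in spec.covariates:
        inter = f"{spec.biomarker}:{covname}"
        alt = f"{covname}:{spec.biomarker}"
        inter = inter if inter in names else (alt if alt in names else None)
        if inter is None:
            continue
        levels = sorted(pd.unique(table.data[covname]))
        for level in levels:
            C = np.zeros((len(t_main), len(names)))
            for r, tname in enumerate(t_main):
                C[r, names.index(tname)] = 1.0
                if r == 0:  # interaction acts on the linear-order T column
                    C[r, names.index(inter)] = float(level)
            cb = C @ beta
            vb = C @ cov @ C.T
            try:
                stat = float(cb @ np.linalg.solve(vb, cb))
            except np.linalg.LinAlgError:
                stat = float(cb @ np.linalg.pinv(vb) @ cb)
            p = float(stats.chi2.sf(stat, df=len(t_main)))
            out[f"{covname}={level}"] = {"p": p, "is_cor": p < alpha}
    return out


def assess_cor(
    table: StudyTable,
    biomarker: str,
    covariates: list[str] | None = None,
    model_family: str = "cox",
    target_cause: int | None = None,
    alpha: float = 0.05,
) -> CoRResult:
    """Two-stage AIC selection of the immunogenicity risk model, then a CoR verdict.

    Stage 1 fits biomarker-only candidates with a linear and a quadratic
    term and keeps the lower-AIC form unless the improvement is under 2 AIC
    points (parsimony). Stage 2 fits the winning form unadjusted and
    adjusted for the supplied covariates plus their interactions with the
    biomarker, selected by the same rule. The biomarker is a CoR if the
    joint likelihood-ratio test over all its terms in the final model is
    significant at ``alpha``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if biomarker not in table.data.columns:
        raise KeyError(f"biomarker column {biomarker!r} not in table")
    covariates = list(covariates or [])

    candidates: list[Candidate] = []

    def _try(label: str, spec: DesignSpec) -> Candidate:
        try:
            res = _fit_family(table, spec, model_family, target_cause)
            cand = Candidate(label, spec, res, bool(res.converged))
        except (ValueError, np.linalg.LinAlgError):
            cand = Candidate(label, spec, None, False)
        candidates.append(cand)
        return cand

    stage1 = [
        _try("linear", DesignSpec(biomarker, "linear")),
        _try("quadratic", DesignSpec(biomarker, "quadratic")),
    ]
    form = _select(stage1).spec.immunogenicity_term

    stage2 = [c for c in stage1 if c.spec.immunogenicity_term == form]
    if covariates:
        adj_spec = DesignSpec(
            biomarker,
            form,
            covariates=covariates,
            interactions=[(biomarker, c) for c in covariates],
        )
        stage2 = stage2 + [_try(f"{form}+adjusted", adj_spec)]
    final = _select(stage2)

    t_names = _t_term_names(final.spec, list(final.results.params.index))
    p_joint = _joint_t_lrt(final.results, t_names)
    subgroup = (
        _subgroup_t_tests(final.results, final.spec, table, alpha)
        if final.spec.interactions
        else {}
    )
    return CoRResult(
        selected=final.results,
        selected_label=final.label,
        candidates=candidates,
        immunogenicity_p=p_joint,
        is_cor=bool(p_joint < alpha),
        alpha=alpha,
        biomarker=biomarker,
        model_family=model_family,
        target_cause=target_cause,
        subgroup_tests=subgroup,
    )


def prentice_test(table: StudyTable, cor: CoRResult, alpha: float | None = None) -> CoPResult:
    """Prentice conditional-independence test of the selected CoR model.

    Vaccination status is added to the final CoR model; the biomarker is a
    CoP if (i) adding vaccination does not significantly improve the fit
    (LRT p >= alpha) and (ii) the biomarker terms remain jointly significant
    in the augmented model.
    """
    alpha = cor.alpha if alpha is None else alpha
    table.arm_split()  # raises on single-arm data
    if not cor.selected.converged:
        raise ValueError("selected CoR model did not converge")
    spec = next(c.spec for c in cor.candidates if c.label == cor.selected_label)
    aug_spec = DesignSpec(
        spec.biomarker,
        spec.immunogenicity_term,
        covariates=list(spec.covariates),
        interactions=list(spec.interactions),
        include_vaccination=True,
    )
    augmented = _fit_family(table, aug_spec, cor.model_family, cor.target_cause)
    vaccination_p, _ = model_tests(cor.selected, augmented)
    t_names = _t_term_names(aug_spec, list(augmented.params.index))
    biomarker_p = _joint_t_lrt(augmented, t_names)
    still = bool(biomarker_p < alpha)
    return CoPResult(
        base=cor.selected,
        augmented=augmented,
        vaccination_p=float(vaccination_p),
        biomarker_p=float(biomarker_p),
        biomarker_still_significant=still,
        is_cop=bool(still and vaccination_p >= alpha),
        alpha=alpha,
    )
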