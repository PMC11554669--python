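"""Subject-level trial tables and biomarker derivation rules.

The universal input to every analysis in this package is a *study table*:
one row per subject with a treatment arm, a follow-up time from the
post-vaccination landmark visit, an event cause code (0 = censored,
k >= 1 = event of cause k), baseline covariates, and one or more
immunogenicity biomarkers (log2 scale where applicable).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyTable",
    "BiomarkerMatrix",
    "SchemaError",
    "read_study_table",
    "write_study_table",
    "derive_log2_fold_rise",
    "center_scale",
    "average_titer",
    "vif",
    "principal_components",
    "compare_groups",
]

ARM_VACCINE = "vaccine"
ARM_CONTROL = "control"

#: accepted spellings for each normalized arm label (case-insensitive)
_ARM_ALIASES = {
    "vaccine": ARM_VACCINE,
    "vaccinated": ARM_VACCINE,
    "control": ARM_CONTROL,
    "placebo": ARM_CONTROL,
}


class SchemaError(ValueError):
    """Raised when an input table violates the study-table schema."""


def _normalize_arm(label) -> str:
    key = str(label).strip().lower()
    if key not in _ARM_ALIASES:
        raise SchemaError(
            f"unknown arm label {label!r}; expected one of {sorted(_ARM_ALIASES)}"
        )
    return _ARM_ALIASES[key]


@dataclass
class StudyTable:
    """Validated subject-level trial data.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain columns ``subject_id``, ``arm`` (normalized to
        ``vaccine``/``control``), ``time`` (positive, days from the
        landmark visit) and ``cause`` (integer, 0 = censored).
    covariates : list of str
        Columns holding baseline covariates.
    biomarkers : list of str
        Columns holding immunogenicity biomarker values.
    n_dropped : int
        Rows removed by complete-case filtering on required columns.
    """

    data: pd.DataFrame
    covariates: list[str] = field(default_factory=list)
    biomarkers: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = self.data
        required = ["subject_id", "arm", "time", "cause"]
        for col in required + self.covariates + self.biomarkers:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        df = df.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["arm"] = df["arm"].map(_normalize_arm)
        df["time"] = df["time"].astype(float)
        df["cause"] = df["cause"].astype(int)
        dup = df["subject_id"][df["subject_id"].duplicated()]
        if len(dup):
            raise SchemaError(f"duplicate subject_id values: {sorted(set(dup))[:5]}")
        bad = df.loc[df["time"] <= 0, "subject_id"]
        if len(bad):
            raise SchemaError(
                f"non-positive time for subject_id {bad.iloc[0]!r}"
                + (f" (+{len(bad) - 1} more)" if len(bad) > 1 else "")
            )
        if (df["cause"] < 0).any():
            raise SchemaError("cause codes must be >= 0")
        causes = sorted(set(df["cause"]) - {0})
        if causes and causes != list(range(1, len(causes) + 1)):
            raise SchemaError(
                f"cause codes must form a contiguous set 1..K, got {causes}"
            )
        self.data = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_causes(self) -> int:
        return int(self.data["cause"].max())

    @property
    def is_vaccine(self) -> np.ndarray:
        return (self.data["arm"] == ARM_VACCINE).to_numpy()

    def arm_split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(vaccine rows, control rows); raises if either arm is empty."""
        v = self.data[self.data["arm"] == ARM_VACCINE]
        c = self.data[self.data["arm"] == ARM_CONTROL]
        if len(v) == 0 or len(c) == 0:
            raise SchemaError("both arms must be represented")
        return v, c

    def subset(self, mask) -> "StudyTable":
        return StudyTable(
            self.data[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            covariates=list(self.covariates),
            biomarkers=list(self.biomarkers),
        )


def read_study_table(
    path,
    covariates: list[str] | None = None,
    biomarkers: list[str] | None = None,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> StudyTable:
    """Read a delimited text file (comma default, tab accepted) into a StudyTable.

    ``column_map`` renames file columns to the schema roles, e.g.
    ``{"ptid": "subject_id", "trt": "arm"}``. Rows with missing values in
    any required, covariate or biomarker column are dropped (complete-case)
    and counted in ``StudyTable.n_dropped``.
    """
    covariates = list(covariates or [])
    biomarkers = list(biomarkers or [])
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if column_map:
        df = df.rename(columns=column_map)
    required = ["subject_id", "arm", "time", "cause"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    used = required + covariates + biomarkers
    complete = df.dropna(subset=[c for c in used if c in df.columns])
    n_dropped = len(df) - len(complete)
    return StudyTable(
        complete.reset_index(drop=True),
        covariates=covariates,
        biomarkers=biomarkers,
        n_dropped=n_dropped,
    )


def write_study_table(table: StudyTable, path) -> None:
    """Write a StudyTable back to CSV (round-trips with read_study_table)."""
    table.data.to_csv(path, index=False)


def derive_log2_fold_rise(baseline_titer, post_titer, arm) -> float:
    """Log2 fold rise in antibody titer, with the control/clamp convention.

    Control-arm subjects are assigned fold rise 1 (log2 fold rise 0): the
    control group has by definition no assay change, so any measured change
    is attributed to assay variability. Vaccine-arm fold rises below 1 are
    clamped to 1 for the same reason.
    """
    baseline_titer = float(baseline_titer)
    post_titer = float(post_titer)
    if baseline_titer <= 0 or post_titer <= 0:
        raise ValueError("titers must be positive")
    if _normalize_arm(arm) == ARM_CONTROL:
        return 0.0
    return max(0.0, float(np.log2(post_titer / baseline_titer)))


def center_scale(values) -> np.ndarray:
    """Center to mean 0 and scale to sample standard deviation 1 (n-1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input vector cannot be scaled")
    return (x - x.mean()) / sd


@dataclass
class BiomarkerMatrix:
    """Subjects x biomarkers matrix with centering/scaling metadata.

    ``means``/``sds`` record the per-column centering constants; they are
    present iff the stored ``values`` are centered and scaled, which lets
    downstream operations refuse unscaled input.
    """

    values: np.ndarray
    columns: list[str]
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be a 2-d matrix with >= 1 column")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column names do not match matrix width")

    @property
    def is_scaled(self) -> bool:
        return self.means is not None and self.sds is not None

    @classmethod
    def from_frame(cls, df: pd.DataFrame, columns: list[str]) -> "BiomarkerMatrix":
        return cls(df[columns].to_numpy(dtype=float), list(columns))

    def scaled(self) -> "BiomarkerMatrix":
        """Center and scale every column; retains the scaling metadata."""
        means = self.values.mean(axis=0)
        sds = self.values.std(axis=0, ddof=1)
        if np.any(sds == 0):
            raise ValueError("constant biomarker column cannot be scaled")
        return BiomarkerMatrix(
            (self.values - means) / sds, list(self.columns), means=means, sds=sds
        )


def average_titer(scaled: BiomarkerMatrix) -> np.ndarray:
    """Per-subject arithmetic mean across centered-and-scaled biomarker columns.

    A single summary biomarker for correlated serotype-specific titers; the
    input must carry scaling metadata (see :meth:`BiomarkerMatrix.scaled`).
    """
    if not scaled.is_scaled:
        raise ValueError("average_titer requires a centered/scaled BiomarkerMatrix")
    return scaled.values.mean(axis=1)


def vif(predictors: BiomarkerMatrix | np.ndarray) -> np.ndarray:
    """Variance inflation factor 1/(1-R^2) of each column on the others.

    Perfectly collinear columns yield ``inf`` rather than an error.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    x = predictors.values if isinstance(predictors, BiomarkerMatrix) else predictors
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 predictor columns")
    if x.shape[0] < x.shape[1] + 1:
        raise ValueError("need at least columns+1 rows")
    # constant column for the auxiliary regressions' intercept
    design = np.column_stack([np.ones(len(x)), x])
    out = np.empty(x.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(x.shape[1]):
            v = variance_inflation_factor(design, j + 1)
            out[j] = np.inf if (not np.isfinite(v)) else max(v, 1.0)
    return out


def principal_components(
    scaled: BiomarkerMatrix, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-``k`` principal component scores of the sample correlation structure.

    Returns ``(scores, cumulative_variance)`` where ``scores`` is the
    subjects x k projection matrix and ``cumulative_variance`` the
    cumulative proportion of variance explained by components 1..k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = scaled.values if isinstance(scaled, BiomarkerMatrix) else np.asarray(scaled)
    if k > x.shape[1]:
        raise ValueError("k exceeds the number of biomarker columns")
    xc = x - x.mean(axis=0)
    # eigendecomposition of the sample covariance (= correlation on scaled input)
    cov = xc.T @ xc / (len(xc) - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    scores = xc @ eigvec[:, :k]
    total = eigval.sum()
    cumvar = np.cumsum(eigval[:k]) / total if total > 0 else np.zeros(k)
    return scores, cumvar


def compare_groups(values_a, values_b, alpha: float = 0.05):
    """Two-group location comparison with the standard routing decision tree.

    Each group is screened for normality with a Kolmogorov-Smirnov test
    against a normal with estimated moments (significance ``alpha``). If both
    pass, Bartlett's test decides between the pooled-variance t-test and
    Welch's t-test; if either fails, the two-sided Mann-Whitney U test is
    used. Returns ``(test_name, p_value)`` with ``test_name`` in
    ``{"t-test", "welch", "mann-whitney"}``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 observations")

    def _normal(x):
        return stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue >= alpha

    if _normal(a) and _normal(b):
        if stats.bartlett(a, b).pvalue >= alpha:
            return "t-test", float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        return "welch", float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return "mann-whitney", float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
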