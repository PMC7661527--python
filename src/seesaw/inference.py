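"""Brain-behavior statistics: scale scoring, correlations, groups, ANOVA.

Implements the cohort-level inference layer: Zung SAS/SDS sum scoring with
reverse-keyed items, head-motion exclusion, Pearson and partial correlations
with exact degree-of-freedom bookkeeping (df = n - 2 - k), Bonferroni
adjustment for the two-test family, rank-based extreme-group construction,
between-subjects 2x2 ANOVA, pooled-variance t-tests, and Cronbach's alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "SubjectRecord",
    "CohortTable",
    "score_scale",
    "apply_exclusions",
    "pearson",
    "partial_correlation",
    "bonferroni",
    "assign_extreme_groups",
    "anova_2x2",
    "two_sample_t",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation with its t statistic, exact df and two-sided p."""

    r: float
    t: float
    df: int
    p: float
    n: int
    n_covariates: int = 0

    def __str__(self) -> str:
        return f"r({self.df}) = {self.r:.3f}, p = {self.p:.4g}"


@dataclass
class SubjectRecord:
    """One cohort row: behavioral scores, demographics, exclusion state."""

    id: str
    sas_score: float
    sds_score: float
    age: float
    gender: str
    dominance: object | None = None
    excluded: bool = False
    exclusion_reason: str | None = None


@dataclass
class CohortTable:
    """Ordered subject collection with unique ids."""

    subjects: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    @property
    def n_included(self) -> int:
        return sum(not s.excluded for s in self.subjects)

    def included(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if not s.excluded]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "id": s.id,
                "sas_score": s.sas_score,
                "sds_score": s.sds_score,
                "age": s.age,
                "gender": s.gender,
                "excluded": s.excluded,
                "exclusion_reason": s.exclusion_reason,
            }
            if s.dominance is not None:
                row.update(s.dominance.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def score_scale(items, reverse_keys=()) -> int:
    """Sum a 20-item 4-point scale; reverse-keyed items score 5 - response.

    ``reverse_keys`` holds 0-based item indices.  Result lies in [20, 80].
    """
    items = np.asarray(items)
    if items.shape != (20,):
        raise ValueError("exactly 20 item responses required")
    for i, v in enumerate(items):
        if v not in (1, 2, 3, 4):
            raise ValueError(f"item {i}: response {v!r} outside 1..4")
    reverse = np.zeros(20, dtype=bool)
    reverse[list(reverse_keys)] = True
    vals = np.where(reverse, 5 - items, items)
    return int(vals.sum())


def apply_exclusions(
    cohort: CohortTable,
    motion_summaries: dict | None = None,
    motion_limits: tuple[float, float] = (2.0, 2.0),
    quality_flags: dict | None = None,
) -> CohortTable:
    """Flag subjects exceeding motion limits or carrying a quality flag.

    ``motion_summaries`` maps subject id -> (max |translation| mm,
    max |rotation| degrees).  Exclusion is strict: "above" the limit, so a
    subject exactly at the boundary is retained.
    """
    mm_lim, deg_lim = motion_limits
    for s in cohort.subjects:
        if quality_flags and quality_flags.get(s.id):
            s.excluded = True
            s.exclusion_reason = "image quality"
            continue
        if motion_summaries and s.id in motion_summaries:
            t_max, r_max = motion_summaries[s.id]
            if t_max > mm_lim or r_max > deg_lim:
                s.excluded = True
                s.exclusion_reason = (
                    f"head motion (|t|max={t_max:.2f} mm, |r|max={r_max:.2f} deg)"
                )
    return cohort


def pearson(x, y) -> CorrelationResult:
    """Two-tailed Pearson correlation with df = n - 2."""
    return partial_correlation(x, y, None)


def partial_correlation(x, y, covariates=None) -> CorrelationResult:
    """Partial Pearson correlation controlling for k covariates.

    Both variables are residualised on [intercept, covariates] by least
    squares; the Pearson r of the residuals is tested on df = n - 2 - k.
    With no covariates this is the plain bivariate correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y lengths differ")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate rows do not match n")
    k = cov.shape[1]
    if n < k + 3:
        raise ValueError(f"need n >= k + 3 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ beta
    rx, ry = resid[:, 0], resid[:, 1]
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx < 1e-12 or sy < 1e-12:
        raise ValueError("constant input after residualisation")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r=r, t=float(t), df=df, p=float(p), n=n, n_covariates=k)


def bonferroni(p_values, m: int = 2) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p) for a family of m tests."""
    p_values = list(np.atleast_1d(p_values))
    if m < len(p_values):
        raise ValueError("family size m smaller than number of p-values")
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, float(p) * m))
    return out


def assign_extreme_groups(
    df: pd.DataFrame,
    group_size: int = 33,
    sas_col: str = "sas_score",
    sds_col: str = "sds_score",
    id_col: str = "id",
) -> dict[str, list]:
    """Rank-based extreme groups on the anxiety and depression scales.

    Subjects are ranked ascending on each scale (average ranks for ties,
    boundary ties broken by id).  Groups of ``group_size`` are drawn without
    replacement in order: HH (highest rank sum), LL (lowest rank sum), LH
    (max SAS-rank minus SDS-rank: high anxious / low depressed), HL (max
    SDS-rank minus SAS-rank).  Returns id lists keyed "HH", "LL", "LH", "HL".
    """
    if 4 * group_size > len(df):
        raise ValueError(
            f"need at least {4 * group_size} subjects, have {len(df)}"
        )
    work = df[[id_col, sas_col, sds_col]].copy()
    work["rank_sas"] = work[sas_col].rank(method="average")
    work["rank_sds"] = work[sds_col].rank(method="average")
    remaining = work.copy()

    def take(score: pd.Series, largest: bool) -> list:
        ordered = remaining.assign(_score=score).sort_values(
            ["_score", id_col], ascending=[not largest, True]
        )
        return list(ordered[id_col].iloc[:group_size])

    groups: dict[str, list] = {}
    specs = [
        ("HH", lambda r: r["rank_sds"] + r["rank_sas"], True),
        ("LL", lambda r: r["rank_sds"] + r["rank_sas"], False),
        ("LH", lambda r: r["rank_sas"] - r["rank_sds"], True),
        ("HL", lambda r: r["rank_sds"] - r["rank_sas"], True),
    ]
    for name, scorer, largest in specs:
        ids = take(scorer(remaining), largest)
        groups[name] = ids
        remaining = remaining[~remaining[id_col].isin(ids)]
    return groups


def anova_2x2(
    y, factor_a, factor_b, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Between-subjects 2x2 ANOVA (type III, sum-to-zero contrasts).

    Returns a frame indexed by effect ("A", "B", "A:B") with F, df_num,
    df_error and p.  Without covariates error df = N - 4; each covariate
    column costs one further df.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    y = np.asarray(y, dtype=float).ravel()
    a = pd.Categorical(factor_a)
    b = pd.Categorical(factor_b)
    if len(a.categories) != 2 or len(b.categories) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    tab = pd.crosstab(np.asarray(a), np.asarray(b))
    if (tab.values == 0).any():
        raise ValueError("every factor cell must be non-empty")
    data = pd.DataFrame({"y": y, "A": a, "B": b})
    formula = "y ~ C(A, Sum) * C(B, Sum)"
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True)
        for c in cov.columns:
            data[c] = pd.to_numeric(cov[c])
        formula += " + " + " + ".join(cov.columns)
    fit = ols(formula, data=data).fit()
    table = sm.stats.anova_lm(fit, typ=3)
    rename = {
        "C(A, Sum)": "A",
        "C(B, Sum)": "B",
        "C(A, Sum):C(B, Sum)": "A:B",
    }
    rows = []
    for raw, name in rename.items():
        rows.append(
            {
                "effect": name,
                "F": float(table.loc[raw, "F"]),
                "df_num": int(table.loc[raw, "df"]),
                "df_error": int(fit.df_resid),
                "p": float(table.loc[raw, "PR(>F)"]),
            }
        )
    return pd.DataFrame(rows).set_index("effect")


def two_sample_t(a, b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test: (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def cronbach_alpha(items, reverse_keys=()) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum(item var) / var(total)).

    ``items`` is respondents x items; reverse-keyed columns are recoded
    (5 - response, the 4-point-scale convention) before computing.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need >= 3 respondents and >= 2 items")
    x = x.copy()
    for j in reverse_keys:
        x[:, j] = 5.0 - x[:, j]
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
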