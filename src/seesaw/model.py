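"""Statsmodels-style front end for the brain-behavior analysis.

:class:`BrainBehaviorModel` is built from a cohort DataFrame (one row per
subject with the dominance-dynamics metric, SAS/SDS scores, demographics and
the activation-magnitude confounds); :meth:`fit` returns a
:class:`BrainBehaviorResults` carrying every reported statistic:

* the two headline partial correlations (dwell vs anxiety and vs depression,
  controlling age and gender) with Bonferroni adjustment over the two-test
  family;
* the activation-magnitude sensitivity models (adding the DMN, TPN and
  difference-series average deviations from zero plus the DMN-TPN
  anticorrelation as further covariates);
* the comorbidity-partialled models (each scale controlling the other);
* the anxiety-depression comorbidity correlation;
* the rank-based extreme-group 2x2 ANOVA on the dwell metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import (
    CorrelationResult,
    anova_2x2,
    assign_extreme_groups,
    bonferroni,
    partial_correlation,
    pearson,
)

__all__ = ["BrainBehaviorModel", "BrainBehaviorResults"]

_AD_CONFOUNDS = ["ad_dmn", "ad_tpn", "ad_diff", "anticorr"]


class BrainBehaviorModel:
    """Brain-behavior association model for dominance-dynamics metrics.

    Parameters
    ----------
    data : DataFrame
        One row per (included) subject.  Required columns: the metric
        (default ``mean_dwell_dmn``), ``sas_score``, ``sds_score``, ``age``,
        ``gender``.  The sensitivity models additionally use ``ad_dmn``,
        ``ad_tpn``, ``ad_diff`` and ``anticorr`` when present.
    metric : str
        Column holding the per-subject dynamics statistic.
    """

    def __init__(self, data: pd.DataFrame, metric: str = "mean_dwell_dmn"):
        required = {metric, "sas_score", "sds_score", "age", "gender"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
        data = data.copy()
        if "excluded" in data.columns:
            data = data[~data["excluded"].astype(bool)]
        data = data.dropna(subset=[metric, "sas_score", "sds_score", "age"])
        self.data = data.reset_index(drop=True)
        self.metric = metric
        # gender enters covariate models as a 0/1 indicator
        g = self.data["gender"]
        if g.dtype == object or isinstance(g.dtype, pd.CategoricalDtype):
            levels = sorted(g.unique())
            if len(levels) > 2:
                raise ValueError("gender must have at most 2 levels")
            self._gender01 = (g == levels[-1]).astype(float).to_numpy()
        else:
            self._gender01 = g.astype(float).to_numpy()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, metric: str = "mean_dwell_dmn"):
        return cls(data, metric=metric)

    @property
    def nobs(self) -> int:
        return len(self.data)

    def _covariates(self, extra: list[str] = ()) -> np.ndarray:
        cols = [self.data["age"].to_numpy(float), self._gender01]
        for c in extra:
            cols.append(self.data[c].to_numpy(float))
        return np.column_stack(cols)

    def fit(
        self,
        family_size: int = 2,
        group_size: int = 33,
        anova_covariates: bool = False,
    ) -> "BrainBehaviorResults":
        """Run every association analysis; returns the results container.

        ``anova_covariates`` adds age and gender to the extreme-group ANOVA
        (off by default: the canonical model is covariate-free with error
        df = 4 * group_size - 4).
        """
        d = self.data
        y = d[self.metric].to_numpy(float)
        sas = d["sas_score"].to_numpy(float)
        sds = d["sds_score"].to_numpy(float)
        base_cov = self._covariates()

        headline = {
            "anxiety": partial_correlation(y, sas, base_cov),
            "depression": partial_correlation(y, sds, base_cov),
        }
        adj = bonferroni([headline["anxiety"].p, headline["depression"].p], family_size)
        headline_adjusted = dict(zip(headline, adj))

        sensitivity: dict[str, CorrelationResult] = {}
        have_ad = all(c in d.columns for c in _AD_CONFOUNDS) and len(d) >= 9
        if have_ad:
            ad_cov = self._covariates(_AD_CONFOUNDS)
            sensitivity = {
                "anxiety": partial_correlation(y, sas, ad_cov),
                "depression": partial_correlation(y, sds, ad_cov),
            }

        comorbidity = pearson(sas, sds)
        # the comorbidity-partialled models keep the activation-magnitude
        # confounds when available (7 covariates in total)
        extra = list(_AD_CONFOUNDS) if have_ad else []
        partialled = {
            "anxiety_ctrl_depression": partial_correlation(
                y, sas, self._covariates(extra + ["sds_score"])
            ),
            "depression_ctrl_anxiety": partial_correlation(
                y, sds, self._covariates(extra + ["sas_score"])
            ),
        }

        anova = None
        groups = None
        if group_size >= 2 and 4 * group_size <= len(d):
            tbl = d.copy()
            if "id" not in tbl.columns:
                tbl["id"] = [f"s{i}" for i in range(len(tbl))]
            groups = assign_extreme_groups(tbl, group_size=group_size)
            rows, anx_lvl, dep_lvl = [], [], []
            for name in ("HH", "LL", "LH", "HL"):
                sel = tbl[tbl["id"].isin(groups[name])]
                rows.append(sel)
                anx_lvl += ["high" if name in ("HH", "LH") else "low"] * len(sel)
                dep_lvl += ["high" if name in ("HH", "HL") else "low"] * len(sel)
            sub = pd.concat(rows, ignore_index=True)
            cov_df = None
            if anova_covariates:
                g = sub["gender"]
                g01 = (g == sorted(g.unique())[-1]).astype(float)
                cov_df = pd.DataFrame(
                    {"age": sub["age"].to_numpy(float), "gender01": g01.to_numpy()}
                )
            anova = anova_2x2(
                sub[self.metric].to_numpy(float), anx_lvl, dep_lvl, cov_df
            )

        return BrainBehaviorResults(
            model=self,
            headline=headline,
            headline_adjusted=headline_adjusted,
            sensitivity=sensitivity,
            comorbidity=comorbidity,
            partialled=partialled,
            anova=anova,
            groups=groups,
            family_size=family_size,
        )


@dataclass
class BrainBehaviorResults:
    """Estimates, uncertainties and diagnostics from a fitted model."""

    model: BrainBehaviorModel
    headline: dict
    headline_adjusted: dict
    sensitivity: dict
    comorbidity: CorrelationResult
    partialled: dict
    anova: pd.DataFrame | None
    groups: dict | None
    family_size: int = 2

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: term, r, t, df, p, p_adjusted."""
        rows = []

        def add(term, res: CorrelationResult, p_adj=None):
            rows.append(
                {
                    "term": term,
                    "r": res.r,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "p_adjusted": p_adj,
                }
            )

        for k, res in self.headline.items():
            add(f"dwell_vs_{k}", res, self.headline_adjusted[k])
        for k, res in self.sensitivity.items():
            add(f"dwell_vs_{k}_ad_controlled", res)
        add("comorbidity_sas_sds", self.comorbidity)
        for k, res in self.partialled.items():
            add(f"dwell_vs_{k}", res)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Brain-behavior association results",
            "=" * 50,
            f"metric: {m.metric}    n = {m.nobs}",
            "",
            f"Headline partial correlations (age, gender; Bonferroni m={self.family_size}):",
        ]
        for k, res in self.headline.items():
            lines.append(
                f"  {k:<11} r({res.df}) = {res.r:+.3f}, p = {res.p:.4g}, "
                f"p_adj = {self.headline_adjusted[k]:.4g}"
            )
        if self.sensitivity:
            lines.append("Activation-magnitude controlled (AD + anticorr covariates):")
            for k, res in self.sensitivity.items():
                lines.append(
                    f"  {k:<11} r({res.df}) = {res.r:+.3f}, p = {res.p:.4g}"
                )
        c = self.comorbidity
        lines.append(
            f"Comorbidity (SAS vs SDS): r({c.df}) = {c.r:+.3f}, p = {c.p:.3g}"
        )
        lines.append("Comorbidity-partialled models:")
        for k, res in self.partialled.items():
            lines.append(f"  {k:<26} r({res.df}) = {res.r:+.3f}, p = {res.p:.4g}")
        if self.anova is not None:
            lines.append("Extreme-group 2x2 ANOVA on the metric:")
            for eff, row in self.anova.iterrows():
                lines.append(
                    f"  {eff:<4} F({int(row.df_num)},{int(row.df_error)}) = "
                    f"{row.F:.2f}, p = {row.p:.4g}"
                )
        return "\n".join(lines)
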