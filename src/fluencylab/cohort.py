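"""Cohort-level statistics: exclusions, descriptives, correlations, regression.

The cohort is a pandas DataFrame with one row per participant and columns
``participant_id, n_tokens, nocw, mcs, nos, sr, age, education, mmse``
(demographics optional, NaN when missing). ``n_tokens`` is the total
number of productions, which governs the minimum-word filter; ``sr`` is
NaN when the semantic analysis had insufficient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MEASURES",
    "CANDIDATES",
    "CorrelationTable",
    "RegressionResult",
    "apply_exclusions",
    "describe_cohort",
    "pearson_matrix",
    "stepwise_regression",
]

MEASURES = ("nocw", "mcs", "nos", "sr")
CANDIDATES = ("mcs", "nos", "sr", "age", "education", "mmse")


def apply_exclusions(
    cohort: pd.DataFrame,
    min_words: int = 4,
    sd_threshold: float = 3.0,
    outlier_measures: Sequence[str] = ("mcs", "sr"),
    two_sided: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort exclusion rules, in order.

    1. Participants with fewer than ``min_words`` total productions are
       removed (the semantic index needs at least 3 angles).
    2. On the remaining cohort, participants whose value on any of
       ``outlier_measures`` exceeds mean + ``sd_threshold``·SD are
       removed (one-sided above the mean by default; ``two_sided`` also
       removes values below mean − threshold·SD).

    Returns the retained cohort and an exclusion log with one row per
    excluded participant (columns participant_id, reason, measure, value).
    """
    log_rows: list[dict] = []
    if cohort.empty:
        return cohort.copy(), _empty_log()

    few = cohort["n_tokens"] < min_words
    for _, row in cohort[few].iterrows():
        log_rows.append(
            {
                "participant_id": row["participant_id"],
                "reason": "too_few_words",
                "measure": "n_tokens",
                "value": row["n_tokens"],
            }
        )
    kept = cohort[~few].copy()

    # outlier statistics computed on the post-word-count cohort
    outlier_ids: dict[str, tuple[str, float]] = {}
    for measure in outlier_measures:
        vals = kept[measure].astype(float)
        mean, sd = vals.mean(), vals.std(ddof=1)
        if not math.isfinite(sd) or sd == 0:
            continue
        hi = vals > mean + sd_threshold * sd
        mask = hi | (vals < mean - sd_threshold * sd) if two_sided else hi
        for _, row in kept[mask.fillna(False)].iterrows():
            pid = row["participant_id"]
            if pid not in outlier_ids:  # first triggering measure wins
                outlier_ids[pid] = (measure, float(row[measure]))
    for pid, (measure, value) in outlier_ids.items():
        log_rows.append(
            {
                "participant_id": pid,
                "reason": "outlier",
                "measure": measure,
                "value": value,
            }
        )
    kept = kept[~kept["participant_id"].isin(outlier_ids)].reset_index(drop=True)
    log = pd.DataFrame(log_rows) if log_rows else _empty_log()
    return kept, log


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=["participant_id", "reason", "measure", "value"])


def describe_cohort(
    cohort: pd.DataFrame, measures: Sequence[str] = MEASURES
) -> pd.DataFrame:
    """Mean, SD, and range per measure (rows: mean, sd, min, max).

    Sample SD (ddof=1); a single observation reports SD 0.
    """
    if cohort.empty:
        raise ValueError("cannot describe an empty cohort")
    out = {}
    for m in measures:
        vals = cohort[m].dropna().astype(float)
        if vals.empty:
            out[m] = [np.nan] * 5
            continue
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        out[m] = [vals.mean(), sd, vals.min(), vals.max(), len(vals)]
    return pd.DataFrame(out, index=["mean", "sd", "min", "max", "n"])


@dataclass
class CorrelationTable:
    """Pearson r / two-sided p / pairwise n over a set of measures."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        """r annotated with significance stars (*, **, *** at .05/.01/.001)."""
        def fmt(r, p):
            if pd.isna(r):
                return ""
            s = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            return f"{r:.3f}{s}"

        return pd.DataFrame(
            {
                c: [fmt(self.r.loc[i, c], self.p.loc[i, c]) for i in self.r.index]
                for c in self.r.columns
            },
            index=self.r.index,
        )


def pearson_matrix(
    cohort: pd.DataFrame,
    columns: Sequence[str] = ("nocw", "mcs", "nos", "sr", "age", "education", "mmse"),
) -> CorrelationTable:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    p-values use the t transform with n − 2 degrees of freedom; pairs
    with fewer than 3 complete rows or a zero-variance column are NaN.
    """
    cols = [c for c in columns if c in cohort.columns]
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for i, a in enumerate(cols):
        n.loc[a, a] = int(cohort[a].notna().sum())
        for b in cols[i + 1 :]:
            sub = cohort[[a, b]].dropna().astype(float)
            n.loc[a, b] = n.loc[b, a] = len(sub)
            if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return CorrelationTable(r=r, p=p, n=n)


@dataclass
class RegressionResult:
    """Final stepwise model with collinearity diagnostics and step trace."""

    outcome: str
    predictors: list[str]
    coefficients: dict[str, float]  # includes "const"
    pvalues: dict[str, float]
    f_statistic: Optional[float]
    df_model: int
    df_resid: int
    r_squared: float
    tolerance: dict[str, float]
    vif: dict[str, float]
    steps: list[dict] = field(default_factory=list)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictors": self.predictors,
            "coefficients": self.coefficients,
            "pvalues": self.pvalues,
            "f_statistic": self.f_statistic,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "r_squared": self.r_squared,
            "tolerance": self.tolerance,
            "vif": self.vif,
            "steps": self.steps,
            "n": self.n,
        }


def _fit_ols(y: pd.Series, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _collinearity(X: pd.DataFrame) -> tuple[dict[str, float], dict[str, float]]:
    """Tolerance (1 − R² of each predictor on the rest) and VIF = 1/tol."""
    tol, vif = {}, {}
    for col in X.columns:
        others = [c for c in X.columns if c != col]
        if not others:
            tol[col], vif[col] = 1.0, 1.0
            continue
        r2 = _fit_ols(X[col], X[others]).rsquared
        t = max(1.0 - r2, 1e-12)
        tol[col], vif[col] = t, 1.0 / t
    return tol, vif


def stepwise_regression(
    cohort: pd.DataFrame,
    outcome: str = "nocw",
    candidates: Sequence[str] = CANDIDATES,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionResult:
    """Stepwise (forward entry, backward removal) multiple regression.

    At each step the candidate with the smallest coefficient p-value
    below ``p_enter`` (given the current model) enters; any included
    predictor whose p-value rises above ``p_remove`` is then removed.
    Rows with missing values in the outcome or any candidate are dropped
    (listwise). An empty final model is reported with R² = 0.
    """
    cand = [c for c in candidates if c in cohort.columns]
    data = cohort[[outcome, *cand]].dropna().astype(float)
    nrows = len(data)
    y = data[outcome]
    included: list[str] = []
    steps: list[dict] = []
    tol_min = 1e-4  # candidates (near-)collinear with the model never enter
    while True:
        changed = False
        # forward step
        best_p, best_c = None, None
        for c in cand:
            if c in included:
                continue
            if included:
                r2_on_model = _fit_ols(data[c], data[included]).rsquared
                if 1.0 - r2_on_model < tol_min:
                    continue
            try:
                model = _fit_ols(y, data[included + [c]])
            except Exception:
                continue
            pval = model.pvalues.get(c, np.nan)
            if np.isnan(pval):
                continue
            if pval < p_enter and (best_p is None or pval < best_p):
                best_p, best_c = pval, c
        if best_c is not None:
            included.append(best_c)
            model = _fit_ols(y, data[included])
            steps.append(
                {"action": "add", "predictor": best_c, "p": float(best_p),
                 "r_squared": float(model.rsquared)}
            )
            changed = True
        # backward step
        if included:
            model = _fit_ols(y, data[included])
            worst_p, worst_c = None, None
            for c in included:
                pval = model.pvalues.get(c, np.nan)
                if pval > p_remove and (worst_p is None or pval > worst_p):
                    worst_p, worst_c = pval, c
            if worst_c is not None:
                included.remove(worst_c)
                rsq = _fit_ols(y, data[included]).rsquared if included else 0.0
                steps.append(
                    {"action": "remove", "predictor": worst_c,
                     "p": float(worst_p), "r_squared": float(rsq)}
                )
                changed = True
        if not changed:
            break

    if not included:
        return RegressionResult(
            outcome=outcome, predictors=[], coefficients={}, pvalues={},
            f_statistic=None, df_model=0, df_resid=max(nrows - 1, 0),
            r_squared=0.0, tolerance={}, vif={}, steps=steps, n=nrows,
        )
    model = _fit_ols(y, data[included])
    tol, vif = _collinearity(data[included])
    return RegressionResult(
        outcome=outcome,
        predictors=list(included),
        coefficients={k: float(v) for k, v in model.params.items()},
        pvalues={k: float(v) for k, v in model.pvalues.items()},
        f_statistic=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        r_squared=float(model.rsquared),
        tolerance=tol,
        vif=vif,
        steps=steps,
        n=nrows,
    )
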