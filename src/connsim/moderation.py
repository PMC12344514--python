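"""Does group similarity moderate predictive performance?

OLS of observed ~ predicted + ICC + predicted*ICC (+ optional covariate main
effects), with Johnson-Neyman regions of significance for the conditional
slope of the predicted score, and single-covariate screens of ICC.

Predictors enter uncentered, so the predicted-score main effect is the slope
at ICC = 0 and the JN region is over raw ICC values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .prediction import ScoreTable
from .similarity import SimilarityTable

__all__ = [
    "ModerationResult",
    "JNRegion",
    "fit_moderation",
    "johnson_neyman",
    "covariate_screen",
]

TERM_INTERCEPT = "intercept"
TERM_PREDICTED = "predicted"
TERM_ICC = "icc"
TERM_INTERACTION = "predicted_x_icc"


@dataclass
class ModerationResult:
    """OLS fit of observed ~ predicted * ICC (+ covariates)."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    df_resid: float
    nobs: int
    r_squared: float
    icc_range: tuple[float, float]
    measure: str = ""
    set_label: str = ""
    alpha: float = 0.05

    @property
    def interaction(self) -> float:
        return float(self.params[TERM_INTERACTION])

    @property
    def interaction_p(self) -> float:
        return float(self.pvalues[TERM_INTERACTION])

    def to_frame(self) -> pd.DataFrame:
        t = self.params / self.bse
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.values,
                "se": self.bse.values,
                "t": t.values,
                "p": self.pvalues.values,
            }
        )


def _expand_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric columns pass through; categoricals become drop-first indicators."""
    pieces = []
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            pieces.append(series.astype(float).to_frame(col))
        else:
            levels = series.astype(str)
            if levels.nunique() < 2:
                raise ValueError(
                    f"categorical covariate {col!r} has a single level"
                )
            dummies = pd.get_dummies(levels, prefix=col, drop_first=True)
            pieces.append(dummies.astype(float))
    return pd.concat(pieces, axis=1)


def _check_rank(design: pd.DataFrame) -> None:
    mat = design.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # walk columns to name the offenders
        collinear = []
        kept: list[int] = []
        for j in range(mat.shape[1]):
            trial = mat[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                collinear.append(design.columns[j])
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")


def fit_moderation(
    scores: ScoreTable,
    icc: SimilarityTable,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> ModerationResult:
    """OLS moderation fit on subjects present in both tables.

    ``covariates`` (optional) is indexed by ``subject_id`` with typed columns;
    categoricals enter as drop-first indicators, all covariates as main
    effects only.
    """
    if scores.degenerate:
        raise ValueError(
            "prediction model is degenerate (no selected features); "
            "moderation is undefined for constant predictions"
        )
    merged = scores.frame.merge(
        icc.table[["subject_id", "icc"]], on="subject_id", how="inner"
    )
    if covariates is not None:
        cov = covariates.copy()
        if "subject_id" in cov.columns:
            cov = cov.set_index("subject_id")
        expanded = _expand_covariates(cov)
        expanded.index.name = "subject_id"
        merged = merged.merge(
            expanded.reset_index(), on="subject_id", how="inner"
        )
        cov_cols = [c for c in expanded.columns]
    else:
        cov_cols = []
    merged = merged.dropna()
    if len(merged) < 10:
        raise ValueError(f"need >= 10 aligned subjects, have {len(merged)}")
    if np.ptp(merged["predicted"].to_numpy()) == 0:
        raise ValueError("predicted score is constant; moderation is undefined")

    design = pd.DataFrame(
        {
            TERM_INTERCEPT: 1.0,
            TERM_PREDICTED: merged["predicted"].to_numpy(),
            TERM_ICC: merged["icc"].to_numpy(),
            TERM_INTERACTION: (merged["predicted"] * merged["icc"]).to_numpy(),
        }
    )
    for c in cov_cols:
        design[c] = merged[c].to_numpy()
    _check_rank(design)
    fit = sm.OLS(merged["observed"].to_numpy(), design.to_numpy()).fit()
    names = list(design.columns)
    return ModerationResult(
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        cov_params=pd.DataFrame(fit.cov_params(), index=names, columns=names),
        df_resid=float(fit.df_resid),
        nobs=int(fit.nobs),
        r_squared=float(fit.rsquared),
        icc_range=(float(merged["icc"].min()), float(merged["icc"].max())),
        measure=scores.measure,
        set_label=scores.set_label,
        alpha=alpha,
    )


@dataclass
class JNRegion:
    """Johnson-Neyman regions of significance for the conditional slope.

    ``boundaries`` are the moderator values where |t| of the conditional
    slope theta(s) = b1 + b3*s equals the critical t; ``segments`` label the
    observed moderator range between boundaries.
    """

    boundaries: tuple[float, ...]
    alpha: float
    t_crit: float
    icc_range: tuple[float, float]
    segments: tuple[tuple[float, float, str], ...] = field(default_factory=tuple)


def conditional_slope(
    result: ModerationResult, s: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """theta(s) and SE(theta(s)) for the predicted-score slope at ICC = s."""
    s = np.asarray(s, dtype=float)
    b1 = float(result.params[TERM_PREDICTED])
    b3 = float(result.params[TERM_INTERACTION])
    v11 = float(result.cov_params.loc[TERM_PREDICTED, TERM_PREDICTED])
    v33 = float(result.cov_params.loc[TERM_INTERACTION, TERM_INTERACTION])
    v13 = float(result.cov_params.loc[TERM_PREDICTED, TERM_INTERACTION])
    theta = b1 + b3 * s
    se = np.sqrt(v11 + s**2 * v33 + 2.0 * s * v13)
    return theta, se


def johnson_neyman(
    result: ModerationResult,
    alpha: float = 0.05,
    icc_range: tuple[float, float] | None = None,
) -> JNRegion:
    """Solve theta(s)^2 = t_crit^2 SE(s)^2 for the moderator boundaries.

    The quadratic has 0, 1 or 2 real roots; significance labels are reported
    only within the observed moderator range.
    """
    if icc_range is None:
        icc_range = result.icc_range
    lo, hi = icc_range
    b1 = float(result.params[TERM_PREDICTED])
    b3 = float(result.params[TERM_INTERACTION])
    v11 = float(result.cov_params.loc[TERM_PREDICTED, TERM_PREDICTED])
    v33 = float(result.cov_params.loc[TERM_INTERACTION, TERM_INTERACTION])
    v13 = float(result.cov_params.loc[TERM_PREDICTED, TERM_INTERACTION])
    if v33 == 0.0:
        raise ValueError("interaction coefficient has zero variance")
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, result.df_resid))
    t2 = t_crit**2
    a = b3**2 - t2 * v33
    b = 2.0 * (b1 * b3 - t2 * v13)
    c = b1**2 - t2 * v11
    roots: list[float] = []
    if a == 0.0:
        if b != 0.0:
            roots = [-c / b]
    else:
        disc = b**2 - 4.0 * a * c
        if disc == 0.0:
            roots = [-b / (2.0 * a)]
        elif disc > 0.0:
            sq = np.sqrt(disc)
            roots = sorted([(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)])
    boundaries = tuple(float(r) for r in roots)

    cuts = [lo] + [r for r in boundaries if lo < r < hi] + [hi]
    segments = []
    for seg_lo, seg_hi in zip(cuts[:-1], cuts[1:]):
        mid = (seg_lo + seg_hi) / 2.0
        theta, se = conditional_slope(result, mid)
        t_val = float(theta / se)
        if abs(t_val) >= t_crit:
            label = "significant_positive" if t_val > 0 else "significant_negative"
        else:
            label = "not_significant"
        segments.append((float(seg_lo), float(seg_hi), label))
    return JNRegion(
        boundaries=boundaries,
        alpha=alpha,
        t_crit=t_crit,
        icc_range=(float(lo), float(hi)),
        segments=tuple(segments),
    )


def covariate_screen(
    icc: SimilarityTable,
    covariates: pd.DataFrame,
    alpha: float = 0.01,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Separate OLS of ICC on each covariate, flagged at the Bonferroni alpha.

    Categorical covariates enter as drop-first indicator sets within their own
    model (one model per covariate, per the sensitivity-analysis design).
    """
    cov = covariates.copy()
    if "subject_id" in cov.columns:
        cov = cov.set_index("subject_id")
    if columns is None:
        columns = list(cov.columns)
    merged = icc.table.set_index("subject_id")[["icc"]].join(cov, how="inner")
    rows = []
    for col in columns:
        sub = merged[["icc", col]].dropna()
        expanded = _expand_covariates(sub[[col]])
        design = sm.add_constant(expanded.to_numpy())
        fit = sm.OLS(sub["icc"].to_numpy(), design).fit()
        names = ["intercept"] + list(expanded.columns)
        for i, term in enumerate(names):
            if term == "intercept":
                continue
            rows.append(
                {
                    "covariate": col,
                    "term": term,
                    "estimate": float(fit.params[i]),
                    "se": float(fit.bse[i]),
                    "t": float(fit.tvalues[i]),
                    "p": float(fit.pvalues[i]),
                    "significant": bool(fit.pvalues[i] < alpha),
                }
            )
    return pd.DataFrame(rows)
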