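"""Summary-statistic t-tests and the brain-behavior regression model.

The regression predicts a vocabulary standard score from per-subject
cluster-mean power changes (theta, alpha, beta) with age, gender,
dual-language experience, working memory and reading ability as covariates,
using ordinary least squares with classical standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist


@dataclass(frozen=True)
class SummaryTTest:
    t: float
    df: int
    p: float
    pooled_sd: float


def pooled_ttest_from_summary(m1: float, sd1: float, n1: int,
                              m2: float, sd2: float, n2: int) -> SummaryTTest:
    """Classical pooled-variance independent-samples t test from summary
    statistics (means, SDs, group sizes)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("SDs must be non-negative and not both zero")
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    t = (m1 - m2) / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * t_dist.sf(abs(t), df)
    return SummaryTTest(t=t, df=df, p=p, pooled_sd=sp)


def one_sample_ttest_from_summary(mean: float, sd: float, n: int,
                                  mu0: float) -> SummaryTTest:
    """One-sample t test of ``mean`` against ``mu0`` from summary statistics."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("SD must be positive")
    df = n - 1
    t = (mean - mu0) / (sd / math.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), df)
    return SummaryTTest(t=t, df=df, p=p, pooled_sd=sd)


#: Default predictor set for the vocabulary model (cluster-mean band changes
#: plus demographic / cognitive covariates).
DEFAULT_TERMS = ("age", "gender", "dual_language", "working_memory",
                 "reading", "theta", "alpha", "beta")


@dataclass
class RegressionFit:
    terms: list[str]          # includes "(Intercept)"
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    df_resid: int
    r_squared: float
    residuals: np.ndarray

    def conf_int(self, term: str, alpha: float = 0.05) -> tuple[float, float]:
        i = self.terms.index(term)
        half = t_dist.ppf(1.0 - alpha / 2.0, self.df_resid) * self.std_errors[i]
        return self.coefficients[i] - half, self.coefficients[i] + half

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "coefficient": self.coefficients,
            "std_error": self.std_errors,
            "t_value": self.t_values,
            "p_value": self.p_values,
        })


def ols_fit(table: pd.DataFrame, outcome: str = "vocabulary",
            terms: tuple[str, ...] = DEFAULT_TERMS) -> RegressionFit:
    """Ordinary least squares of ``outcome`` on ``terms`` plus an intercept.

    Uses classical (non-robust) standard errors.  Raises on rank deficiency,
    naming the collinear terms.
    """
    missing = [t for t in terms if t not in table.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    if outcome not in table.columns:
        raise ValueError(f"missing outcome column: {outcome}")
    n = len(table)
    if n <= len(terms) + 1:
        raise ValueError(f"need n > {len(terms) + 1} observations, got {n}")
    X = table.loc[:, list(terms)].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # identify offending columns by incremental rank
        bad, cols = [], Xc[:, :1]
        for j, name in enumerate(terms):
            cand = np.column_stack([cols, Xc[:, j + 1]])
            if np.linalg.matrix_rank(cand) == cols.shape[1]:
                bad.append(name)
            else:
                cols = cand
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    res = sm.OLS(y, Xc).fit()
    names = ["(Intercept)"] + list(terms)
    return RegressionFit(
        terms=names,
        coefficients=np.asarray(res.params),
        std_errors=np.asarray(res.bse),
        t_values=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        df_resid=int(res.df_resid),
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
    )
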