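"""Partial correlations and brain-score ~ CSF-biomarker regressions.

Covers the two downstream questions the pipeline answers once the PLS
patterns are in hand: do nucleus metrics relate to demographics/CSF
biomarkers after adjusting for covariates, and does a latent pattern's
subject expression (brain score) track pTau181 or Aß42?  Age is never a
covariate in the brain-score models because the voxel maps feeding the PLS
were already age-residualized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class PartialCorrResult:
    r: float
    t: float
    p: float
    df: int
    n: int


@dataclass
class RegressionResult:
    """Standardized biomarker effect from an OLS fit with covariates."""

    beta: float           # standardized coefficient of the biomarker
    se: float
    t: float
    p: float
    p_adj: float          # Bonferroni over m tests
    aic: float
    n: int
    params: dict          # all coefficients by name


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if covariates is None or covariates.size == 0:
        return y - y.mean()
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != y.shape[0]:
        cov = cov.T
    design = np.column_stack([np.ones(y.shape[0]), cov])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation(x, y, covariates=None) -> PartialCorrResult:
    """Pearson correlation of x and y after removing covariates from both.

    Both variables are residualized on [1, covariates] by OLS; the
    correlation of the residuals is tested with t = r·sqrt(df/(1−r²)) at
    df = n − 2 − k, two-tailed.  Without covariates this is exactly the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if covariates is None:
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, float))
        k = cov.shape[1] if cov.shape[0] == n else cov.shape[0]
    if n <= k + 3:
        raise ValueError("need n > k + 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero residual variance")
    rx = _residualize(x, covariates)
    ry = _residualize(y, covariates)
    sx, sy = rx.std(), ry.std()
    df = n - 2 - k
    # a variable fully explained by the covariates has no residual signal;
    # its residuals are float noise, so the partial correlation is zero
    if sx <= 1e-12 * x.std() or sy <= 1e-12 * y.std():
        return PartialCorrResult(r=0.0, t=0.0, p=1.0, df=df, n=n)
    r = float(rx @ ry / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = 2.0 * sps.t.sf(abs(t), df)
    return PartialCorrResult(r=r, t=float(t), p=float(max(p, np.finfo(float).tiny)),
                             df=df, n=n)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant variable cannot be standardized")
    return (v - v.mean()) / sd


def brainscore_biomarker_regression(score, biomarker, sex, education,
                                    m: int = 2) -> RegressionResult:
    """OLS of a brain score on a CSF biomarker with sex/education covariates.

    Continuous variables (score, biomarker, education) are z-scored so the
    biomarker coefficient is a standardized β; sex stays 0/1.  The p-value
    is Bonferroni-adjusted over ``m`` tests (default 2: pTau181 and Aß42
    per brain score).
    """
    score = np.asarray(score, dtype=float)
    biomarker = np.asarray(biomarker, dtype=float)
    sex = np.asarray(sex, dtype=float)
    education = np.asarray(education, dtype=float)
    keep = np.all(np.isfinite(np.column_stack([score, biomarker, sex, education])),
                  axis=1)
    if keep.sum() < 20:
        raise ValueError("need at least 20 complete cases")
    score, biomarker, sex, education = (a[keep] for a in
                                        (score, biomarker, sex, education))
    if biomarker.std(ddof=1) == 0:
        raise ValueError("constant biomarker")
    design = np.column_stack([_zscore(biomarker), sex, _zscore(education)])
    x = sm.add_constant(design)
    fit = sm.OLS(_zscore(score), x).fit()
    beta, se, t, p = fit.params[1], fit.bse[1], fit.tvalues[1], fit.pvalues[1]
    names = ["const", "biomarker", "sex", "education"]
    return RegressionResult(
        beta=float(beta), se=float(se), t=float(t), p=float(p),
        p_adj=float(min(1.0, m * p)), aic=float(fit.aic), n=int(keep.sum()),
        params=dict(zip(names, np.asarray(fit.params, float))))


@dataclass
class AicDecision:
    keep_interaction: bool
    aic_base: float
    aic_interaction: float


def interaction_aic_check(score, biomarker, sex, education, delay) -> AicDecision:
    """Does a biomarker × CSF-delay interaction improve the model by AIC?

    Both models include the delay main effect; "keep" only when the
    interaction model's AIC is strictly lower.
    """
    score = _zscore(np.asarray(score, dtype=float))
    biomarker = _zscore(np.asarray(biomarker, dtype=float))
    education = _zscore(np.asarray(education, dtype=float))
    delay = _zscore(np.asarray(delay, dtype=float))
    sex = np.asarray(sex, dtype=float)
    base = sm.add_constant(np.column_stack([biomarker, sex, education, delay]))
    inter = sm.add_constant(np.column_stack([biomarker, sex, education, delay,
                                             biomarker * delay]))
    aic_base = float(sm.OLS(score, base).fit().aic)
    aic_int = float(sm.OLS(score, inter).fit().aic)
    return AicDecision(keep_interaction=aic_int < aic_base,
                       aic_base=aic_base, aic_interaction=aic_int)
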