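"""Sample QC, covariate screening and robust per-transcript differential expression.

The stage mirrors a standard microarray workflow on already-normalized
log2-scale data: samples are screened for outliers in principal-component
space, candidate covariates are screened for a systemic effect on
expression, and each transcript is tested for a case-control difference
with a robust (Huber) multiple regression.  Transcripts nominally
significant at p <= alpha feed network construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)


def flag_pca_outliers(expr: pd.DataFrame, n_pc: int = 3, k_sd: float = 4.0) -> list[str]:
    """Flag samples that are outliers on at least two of the first ``n_pc`` PCs.

    Each sample is held out in turn: principal components are computed from
    the remaining samples of the transcript-standardized matrix and the
    held-out sample is projected onto them.  The sample is flagged when its
    projection lies beyond ``k_sd`` standard deviations of the training
    scores on >= 2 of the first ``n_pc`` components.  The leave-one-out
    projection is essential: with the candidate included, PCA rotates one
    axis onto the outlier, so no single aberrant array can ever be extreme
    on two components.
    """
    n_samples = expr.shape[1]
    if n_samples < 4:
        raise ValueError("need at least 4 samples for PCA outlier screening")
    if n_pc > min(expr.shape) - 1:
        raise ValueError(f"n_pc={n_pc} exceeds min(samples, transcripts) - 1")
    x = expr.to_numpy(float)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = ((x - x.mean(axis=1, keepdims=True)) / sd).T   # samples x transcripts
    flagged = []
    for j in range(n_samples):
        train = np.delete(xs, j, axis=0)
        centre = train.mean(axis=0)
        u, s, vt = np.linalg.svd(train - centre, full_matrices=False)
        axes = vt[:n_pc]
        train_scores = (train - centre) @ axes.T
        score_sd = train_scores.std(axis=0, ddof=1)
        score_sd[score_sd == 0] = 1.0
        z = ((xs[j] - centre) @ axes.T) / score_sd
        if int((np.abs(z) > k_sd).sum()) >= 2:
            flagged.append(str(expr.columns[j]))
    return flagged


def screen_covariates(expr: pd.DataFrame, pheno: pd.DataFrame,
                      candidates: list[str], alpha: float = 0.05) -> list[str]:
    """Retain candidates with a systemic effect on expression.

    Each candidate is regressed against every transcript; the fraction of
    transcripts nominally significant at ``alpha`` is compared with the
    alpha expectation by a one-sided binomial test, and candidates with a
    significant excess are retained.
    """
    retained = []
    x = expr.to_numpy(float)
    n = x.shape[1]
    for name in candidates:
        if name not in pheno.columns:
            raise KeyError(f"candidate covariate {name!r} not in phenotype table")
        c = pheno.loc[expr.columns, name].to_numpy(float)
        if np.std(c) == 0:
            raise ValueError(f"candidate covariate {name!r} is constant")
        r = _rowwise_cor(x, c)
        p = _cor_pvalue(r, n)
        k = int((p < alpha).sum())
        excess = stats.binomtest(k, x.shape[0], alpha, alternative="greater")
        if excess.pvalue < alpha:
            retained.append(name)
    return retained


def _rowwise_cor(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xs = x - x.mean(axis=1, keepdims=True)
    ys = y - y.mean()
    denom = np.sqrt((xs ** 2).sum(axis=1) * (ys ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xs @ ys) / denom
    return np.clip(np.nan_to_num(r), -1.0, 1.0)


def _cor_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(np.asarray(r, float), -0.9999999999, 0.9999999999)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    return 2.0 * stats.t.sf(np.abs(t), df)


@dataclass
class DiffExprResult:
    table: pd.DataFrame          # transcript_id, effect, p, kept
    covariates_used: list[str]
    method: str


def differential_expression(expr: pd.DataFrame, pheno: pd.DataFrame,
                            covariates: list[str] | None = None,
                            method: str = "robust",
                            alpha: float = 0.05,
                            ) -> tuple[DiffExprResult, pd.DataFrame]:
    """Per-transcript robust regression of expression on case status.

    Fits expression ~ case + covariates by iteratively reweighted least
    squares with a Huber loss (tuning constant 1.345); p-values use the t
    reference with n - k degrees of freedom.  Returns the result table and
    the expression matrix filtered to transcripts with p <= alpha.
    Zero-variance transcripts get p = 1; non-convergent fits fall back to
    ordinary least squares with a logged warning.
    """
    covariates = list(covariates or [])
    ph = pheno.loc[expr.columns]
    if set(ph["case"].unique()) - {0, 1}:
        raise ValueError("case column must be binary 0/1")
    design = np.column_stack([np.ones(expr.shape[1]), ph["case"].to_numpy(float)]
                             + [ph[c].to_numpy(float) for c in covariates])
    n, k = design.shape
    df_resid = n - k
    rows = []
    for tid, y in zip(expr.index, expr.to_numpy(float)):
        if np.std(y) == 0:
            rows.append((tid, 0.0, 1.0))
            continue
        eff, p = _fit_one(y, design, df_resid, method, tid)
        rows.append((tid, eff, p))
    table = pd.DataFrame(rows, columns=["transcript_id", "effect", "p"])
    table["kept"] = table["p"] <= alpha
    kept = expr.loc[table.loc[table.kept, "transcript_id"]]
    return DiffExprResult(table, covariates, method), kept


def _fit_one(y: np.ndarray, design: np.ndarray, df_resid: int,
             method: str, tid) -> tuple[float, float]:
    if method == "robust":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=1.345)).fit(
                    maxiter=50, tol=1e-8)
            se = fit.bse[1]
            if not np.isfinite(se) or se == 0:
                raise np.linalg.LinAlgError("degenerate robust fit")
            tval = fit.params[1] / se
            return float(fit.params[1]), float(2 * stats.t.sf(abs(tval), df_resid))
        except Exception:  # non-convergence or degenerate weights
            log.warning("robust fit failed for %s; falling back to OLS", tid)
    fit = sm.OLS(y, design).fit()
    return float(fit.params[1]), float(fit.pvalues[1])
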