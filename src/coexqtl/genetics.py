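"""Genotype QC, cis-eQTL mapping and kernel-machine set-based association.

Imputed genotype probabilities are hard-called above a confidence
threshold; variants are filtered on minor allele frequency and greedily
pruned for linkage disequilibrium; cis-eQTLs are mapped with an additive
linear model (expression ~ dosage + covariates) within a 1 Mb window and
adjusted by Benjamini-Hochberg; variant sets are tested for joint
association with GWAS phenotypes through a variance-component
(SKAT-style) score test with a linear kernel, and phenotype-level p-values
are combined by the Simes procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def hard_call_genotypes(probs: np.ndarray, vm: pd.DataFrame,
                        sample_ids: list[str], threshold: float = 0.98,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hard-call dosages from GEN probability triples.

    A call is the argmax class when its probability exceeds ``threshold``,
    otherwise missing (NaN); variants missing in every sample are dropped
    with a warning.  Returns (dosage matrix, variant map restricted to kept
    variants).
    """
    probs = np.asarray(probs, float)
    if probs.ndim != 3 or probs.shape[2] != 3:
        raise ValueError("probabilities must have shape (variants, samples, 3)")
    if (probs < 0).any():
        raise ValueError("negative genotype probability")
    sums = probs.sum(axis=2)
    if np.any(np.abs(sums - 1.0) > 0.01):
        raise ValueError("probability triples must sum to 1 (tolerance 0.01)")
    best = probs.argmax(axis=2).astype(float)
    best[probs.max(axis=2) <= threshold] = np.nan
    geno = pd.DataFrame(best, index=vm.variant_id.to_numpy(), columns=sample_ids)
    all_missing = geno.isna().all(axis=1)
    if all_missing.any():
        log.warning("dropping %d variants with no confident call", int(all_missing.sum()))
    geno = geno[~all_missing]
    return geno, vm[~all_missing.to_numpy()].reset_index(drop=True)


def folded_maf(dosages: pd.DataFrame) -> pd.Series:
    """Minor allele frequency min(f, 1-f) from dosages, ignoring missing."""
    f = dosages.mean(axis=1, skipna=True) / 2.0
    return np.minimum(f, 1.0 - f).rename("maf")


def prune_variants(geno: pd.DataFrame, ld_r2: float = 0.8, maf_min: float = 0.24,
                   window: int = 50, step: int = 5) -> list[str]:
    """MAF filter, then greedy sliding-window LD pruning.

    Within each window of ``window`` variants (advanced by ``step``), for
    any pair with squared dosage correlation >= ``ld_r2`` the lower-MAF
    member is removed; deterministic given input order.
    """
    maf = folded_maf(geno)
    keep = [v for v in geno.index if maf[v] >= maf_min]
    removed: set[str] = set()
    x = geno.loc[keep].to_numpy(float)
    # mean-impute for the correlation computation
    means = np.nanmean(x, axis=1, keepdims=True)
    x = np.where(np.isnan(x), means, x)
    start = 0
    while start < len(keep):
        idx = [i for i in range(start, min(start + window, len(keep)))
               if keep[i] not in removed]
        if len(idx) > 1:
            sub = x[idx]
            sd = sub.std(axis=1)
            sd[sd == 0] = 1.0
            r = np.corrcoef(sub)
            r2 = np.nan_to_num(r) ** 2
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    va, vb = keep[idx[a]], keep[idx[b]]
                    if va in removed or vb in removed:
                        continue
                    if r2[a, b] >= ld_r2:
                        removed.add(va if maf[va] <= maf[vb] else vb)
        if start + window >= len(keep):
            break
        start += step
    return [v for v in keep if v not in removed]


@dataclass
class EqtlScan:
    table: pd.DataFrame     # variant_id, transcript_id, distance, beta, se, p, q
    n_tests: int
    fdr: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table.q <= self.fdr]


def _cis_distance(pos: int, start: int, end: int) -> int:
    """Distance from a variant to the nearest edge of a gene interval (0 inside)."""
    if start <= pos <= end:
        return 0
    return int(start - pos) if pos < start else int(pos - end)


def cis_eqtl_scan(expr: pd.DataFrame, geno: pd.DataFrame, vm: pd.DataFrame,
                  gene_map: pd.DataFrame, covariates: pd.DataFrame | None = None,
                  window: float = 1e6, fdr: float = 0.10) -> EqtlScan:
    """Additive cis-eQTL scan over (variant, transcript) pairs within ``window``.

    Per pair: least-squares fit of expression ~ dosage + covariates on the
    shared samples (missing dosages mean-imputed per variant); BH q pooled
    over all cis tests.  Gene coordinates are 1-based fully-closed
    intervals; distance is to the nearest gene edge.
    """
    samples = expr.columns.intersection(geno.columns)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
    if len(samples) < 5:
        raise ValueError("too few shared samples between expression and genotypes")
    gm = gene_map.set_index("transcript_id")
    vm_idx = vm.set_index("variant_id")
    y_all = expr[samples].to_numpy(float)
    g_all = geno[samples].to_numpy(float)
    means = np.nanmean(g_all, axis=1, keepdims=True)
    g_all = np.where(np.isnan(g_all), means, g_all)
    cov = (covariates.loc[samples].to_numpy(float)
           if covariates is not None else np.empty((len(samples), 0)))
    base = np.column_stack([np.ones(len(samples)), cov])
    rows = []
    vpos = vm_idx.loc[geno.index]
    for ti, tid in enumerate(expr.index):
        if tid not in gm.index:
            continue
        chrom, start, end = gm.loc[tid, ["chrom", "start", "end"]]
        on_chrom = (vpos.chrom == chrom).to_numpy()
        pos = vpos.pos.to_numpy()
        dist = np.where(pos < start, start - pos, np.where(pos > end, pos - end, 0))
        cis = on_chrom & (dist <= window)
        y = y_all[ti]
        for vi in np.flatnonzero(cis):
            g = g_all[vi]
            if g.std() == 0:
                log.info("variant %s constant after imputation; skipped", geno.index[vi])
                continue
            X = np.column_stack([base, g])
            beta, se, p = _ols_last(y, X)
            rows.append((geno.index[vi], tid, int(dist[vi]), beta, se, p))
    table = pd.DataFrame(rows, columns=["variant_id", "transcript_id", "distance",
                                        "beta", "se", "p"])
    if len(table):
        table["q"] = multipletests(table.p, method="fdr_bh")[1]
    else:
        table["q"] = []
    return EqtlScan(table, len(table), fdr)


def _ols_last(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """OLS; effect, SE and two-sided t p-value for the last column."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - rank
    if df <= 0:
        return float(coef[-1]), np.nan, np.nan
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0)))
    if se == 0:
        p = 0.0 if coef[-1] != 0 else 1.0
    else:
        p = float(2 * stats.t.sf(abs(coef[-1] / se), df))
    return float(coef[-1]), se, p


# ---------------------------------------------------------------------------
# Kernel-machine (SKAT-style) set test

@dataclass
class SetTestResult:
    phenotype: str
    set_name: str
    Q: float
    p: float
    n_variants: int
    adj_p: float | None = None


def kernel_set_test(geno_set: pd.DataFrame, phenotype: pd.Series,
                    covariates: pd.DataFrame | None = None,
                    set_name: str = "set", kind: str = "auto") -> SetTestResult:
    """Variance-component score test of a variant set with a linear kernel.

    Fits the null model phenotype ~ covariates (logistic for binary
    phenotypes, linear otherwise), forms Q = (y - mu)' K (y - mu) with
    K = G'G (unit weights), and evaluates p against the matching
    mixture-of-chi-squares null by moment matching (Liu approximation on
    the eigenvalues of the projected kernel).
    """
    samples = geno_set.columns.intersection(phenotype.index)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
    y = phenotype.loc[samples].to_numpy(float)
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    G = geno_set[samples].to_numpy(float).T  # samples x variants
    G = np.where(np.isnan(G), np.nanmean(G, axis=0, keepdims=True), G)
    X = np.column_stack([np.ones(len(samples))]
                        + ([covariates.loc[samples].to_numpy(float)]
                           if covariates is not None and covariates.shape[1] else []))
    binary = kind == "binary" or (kind == "auto" and set(np.unique(y)) <= {0.0, 1.0})
    if binary:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        mu = fit.fittedvalues
        v = mu * (1.0 - mu)
        resid = y - mu
        # projected kernel eigenvalues: eig of G' P G, P = V - VX(X'VX)^-1 X'V
        VX = X * v[:, None]
        GtVG = (G * v[:, None]).T @ G
        GtVX = G.T @ VX
        middle = np.linalg.pinv(X.T @ VX)
        A = GtVG - GtVX @ middle @ GtVX.T
        Q = float(resid @ (G @ (G.T @ resid)))
        lam = np.linalg.eigvalsh((A + A.T) / 2.0)
    else:
        fit = sm.OLS(y, X).fit()
        resid = y - fit.fittedvalues
        sigma2 = float(resid @ resid) / (len(y) - np.linalg.matrix_rank(X))
        Gp = G - X @ np.linalg.pinv(X.T @ X) @ (X.T @ G)
        A = sigma2 * (Gp.T @ Gp)
        Q = float(resid @ (G @ (G.T @ resid)))
        lam = np.linalg.eigvalsh((A + A.T) / 2.0)
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1.0)]
    if Q <= 0 or lam.size == 0:
        return SetTestResult(str(phenotype.name), set_name, max(Q, 0.0), 1.0, G.shape[1])
    p = mixture_chi2_sf(Q, lam)
    return SetTestResult(str(phenotype.name), set_name, Q, p, G.shape[1])


def mixture_chi2_sf(q: float, lam: np.ndarray, method: str = "imhof") -> float:
    """Tail probability P(sum lam_i chi2_1 >= q).

    ``imhof`` numerically inverts the characteristic function (exact up to
    quadrature error); ``liu`` uses the moment-matching approximation, which
    is faster but conservative in the far tail.
    """
    lam = np.asarray(lam, float)
    if lam.size == 1:   # single component: exact scaled chi-square
        return float(stats.chi2.sf(q / lam[0], 1))
    if method == "liu":
        return _liu_pvalue(q, lam)
    try:
        from scipy.integrate import quad

        def integrand(u: float) -> float:
            theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
            rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
            return np.sin(theta) / (u * rho)

        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val, _ = quad(integrand, 0, np.inf, limit=500)
        p = 0.5 + val / np.pi
        if not np.isfinite(p):
            raise FloatingPointError("imhof integral did not converge")
        return float(min(max(p, 1e-14), 1.0))
    except Exception:
        log.warning("Imhof evaluation failed; falling back to moment matching")
        return _liu_pvalue(q, lam)


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Moment-matched (Liu et al.) tail probability of sum lam_i chi2_1."""
    c1 = lam.sum()
    c2 = (lam ** 2).sum()
    c3 = (lam ** 3).sum()
    c4 = (lam ** 4).sum()
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2 if s2 > 0 else 1.0
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    x = t_star * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, df, delta))
    return float(stats.chi2.sf(x, df))


def simes_correct(pvals: list[float] | np.ndarray) -> tuple[float, np.ndarray]:
    """Simes combination: global p = min_i m p_(i) / i, plus step-up
    adjusted per-hypothesis values (capped at 1, original order)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(adj_sorted, None, 1.0)
    return float(min(ranked.min(), 1.0)), adj
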