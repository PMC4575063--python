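"""miRNA:mRNA integration.

Cross-correlates module eigengenes between the two platforms, correlates
every mRNA hub transcript with every miRNA hub, tests the positive/negative
sign split, filters negative pairs at an FDR threshold
(Benjamini-Hochberg within the negative stratum by default), intersects
them with target predictions, and summarizes cooperative targeting.
A built-in seed-match predictor stands in for full target-prediction
software when only sequences are available; externally computed prediction
tables are accepted interchangeably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def correlate_eigengenes(me_mrna: pd.DataFrame, me_mirna: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson matrix (mRNA modules x miRNA modules) between eigengene tables.

    Sample sets must match exactly (drop the same samples from both
    platforms first).
    """
    if list(me_mrna.index) != list(me_mirna.index):
        raise ValueError("eigengene tables have mismatched sample sets")
    n = len(me_mrna.index)
    a = me_mrna.to_numpy(float)
    b = me_mirna.to_numpy(float)
    az = (a - a.mean(0)) / a.std(0)
    bz = (b - b.mean(0)) / b.std(0)
    r = az.T @ bz / n
    rdf = pd.DataFrame(r, index=me_mrna.columns, columns=me_mirna.columns)
    p = pd.DataFrame(_cor_p(r, n), index=rdf.index, columns=rdf.columns)
    return rdf, p


def _cor_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(np.asarray(r, float), -0.9999999999, 0.9999999999)
    df = max(n - 2, 1)
    t = r * np.sqrt(df / (1.0 - r ** 2))
    return 2.0 * stats.t.sf(np.abs(t), df)


def correlate_hub_pairs(mrna_hub_expr: pd.DataFrame, mirna_hub_expr: pd.DataFrame,
                        ) -> pd.DataFrame:
    """All-pairs Pearson correlation between mRNA and miRNA hub expression.

    Returns one row per (miRNA, mRNA) pair with r, two-sided t-based p and
    BH q over all non-degenerate pairs.  Constant vectors yield r = NA rows
    excluded from the q computation.
    """
    common = mrna_hub_expr.columns.intersection(mirna_hub_expr.columns)
    if len(common) < 3:
        raise ValueError("fewer than 3 shared samples between platforms")
    a = mrna_hub_expr[common].to_numpy(float)
    b = mirna_hub_expr[common].to_numpy(float)
    n = len(common)
    sd_a, sd_b = a.std(1), b.std(1)
    az = (a - a.mean(1, keepdims=True)) / np.where(sd_a == 0, 1, sd_a)[:, None]
    bz = (b - b.mean(1, keepdims=True)) / np.where(sd_b == 0, 1, sd_b)[:, None]
    r = bz @ az.T / n  # miRNA x mRNA
    pairs = pd.DataFrame({
        "mirna_id": np.repeat(mirna_hub_expr.index.to_numpy(), a.shape[0]),
        "mrna_transcript": np.tile(mrna_hub_expr.index.to_numpy(), b.shape[0]),
        "r": r.ravel(),
    })
    degenerate = np.repeat(sd_b == 0, a.shape[0]) | np.tile(sd_a == 0, b.shape[0])
    if degenerate.any():
        log.warning("%d constant-vector pairs set to NA", int(degenerate.sum()))
        pairs.loc[degenerate, "r"] = np.nan
    pairs["p"] = np.where(pairs.r.isna(), np.nan, _cor_p(pairs.r.fillna(0).to_numpy(), n))
    ok = ~pairs.p.isna()
    q = np.full(len(pairs), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(pairs.loc[ok, "p"], method="fdr_bh")[1]
    pairs["q"] = q
    pairs["sign"] = np.sign(pairs.r).fillna(0).astype(int)
    return pairs


@dataclass
class SignBiasReport:
    n_positive: int
    n_negative: int
    chi2: float
    p: float

    @property
    def proportions(self) -> tuple[float, float]:
        tot = self.n_positive + self.n_negative
        return self.n_positive / tot, self.n_negative / tot


def sign_bias_test(pairs: pd.DataFrame) -> SignBiasReport:
    """1-df goodness-of-fit chi-square of positive/negative counts vs 50/50."""
    r = pairs.r.dropna()
    if r.empty:
        raise ValueError("all correlations are NA")
    n_pos = int((r > 0).sum())
    n_neg = int((r < 0).sum())
    chi2, p = stats.chisquare([n_pos, n_neg])
    return SignBiasReport(n_pos, n_neg, float(chi2), float(p))


def filter_negative_pairs(pairs: pd.DataFrame, fdr: float = 0.10,
                          stratum: str = "negative") -> pd.DataFrame:
    """Negative pairs passing BH FDR.

    ``stratum="negative"`` recomputes BH within the negative-sign subset
    (default); ``stratum="all"`` reuses the whole-table q.
    """
    neg = pairs[pairs.r < 0].copy()
    if neg.empty:
        return neg
    if stratum == "negative":
        neg["q"] = multipletests(neg.p, method="fdr_bh")[1]
    elif stratum != "all":
        raise ValueError(f"unknown FDR stratum {stratum!r}")
    return neg[neg.q <= fdr].copy()


# ---------------------------------------------------------------------------
# Seed-match target prediction (simplified)

_COMPLEMENT = str.maketrans("ACGUT", "UGCAA")
SITE_WEIGHTS = {"8mer": 3.0, "7mer-m8": 2.0, "7mer-A1": 1.0}


def _revcomp_rna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    if set(seq) - set("ACGU"):
        raise ValueError(f"invalid alphabet in {what}: {sorted(set(seq) - set('ACGU'))}")
    return seq


def predict_targets(mirna_seqs: dict[str, str], utr_seqs: dict[str, str],
                    ) -> pd.DataFrame:
    """Canonical seed-match target prediction.

    A site is called when the reverse complement of the miRNA seed
    (positions 2-8) occurs in the 3' UTR; site classes 8mer > 7mer-m8 >
    7mer-A1 are weighted 3/2/1 and summed over sites.  Returns rows
    (mirna_id, gene_symbol, score) for pairs with >= 1 site.
    """
    rows = []
    for mir, mseq in mirna_seqs.items():
        mseq = _validate(mseq, mir)
        if len(mseq) < 8:
            raise ValueError(f"miRNA {mir} shorter than 8 nt")
        seed_m8 = _revcomp_rna(mseq[1:8])   # positions 2-8
        seed_a1 = _revcomp_rna(mseq[1:7])   # positions 2-7
        for gene, useq in utr_seqs.items():
            useq = _validate(useq, gene)
            score = 0.0
            i = useq.find(seed_m8)
            while i != -1:
                nxt = useq[i + len(seed_m8): i + len(seed_m8) + 1]
                score += SITE_WEIGHTS["8mer"] if nxt == "A" else SITE_WEIGHTS["7mer-m8"]
                i = useq.find(seed_m8, i + 1)
            j = useq.find(seed_a1)
            while j != -1:
                nxt = useq[j + len(seed_a1): j + len(seed_a1) + 1]
                # a 7mer-A1 only counts when not contained in an m8 site
                part_of_m8 = j >= 1 and useq[j - 1: j + len(seed_a1)] == seed_m8
                if nxt == "A" and not part_of_m8:
                    score += SITE_WEIGHTS["7mer-A1"]
                j = useq.find(seed_a1, j + 1)
            if score > 0:
                rows.append((mir, gene, score))
    return pd.DataFrame(rows, columns=["mirna_id", "gene_symbol", "score"])


def intersect_targeting(neg_pairs: pd.DataFrame, predictions: pd.DataFrame,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner join of FDR-passing negative pairs with predicted targets.

    ``neg_pairs`` must carry a ``gene_symbol`` column (collapse transcripts
    to symbols first).  Returns (targeting-pair table, cooperative summary:
    distinct miRNAs per target gene, descending).
    """
    if "gene_symbol" not in neg_pairs.columns:
        raise KeyError("neg_pairs needs a gene_symbol column (collapse probes first)")
    merged = neg_pairs.merge(predictions, on=["mirna_id", "gene_symbol"], how="inner")
    coop = (merged.groupby("gene_symbol")["mirna_id"].nunique()
            .sort_values(ascending=False).rename("n_mirnas").reset_index())
    return merged, coop
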