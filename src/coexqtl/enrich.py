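"""Hub selection, probe collapsing, marker enrichment and preranked GSEA.

Hubs are the top quartile of module membership (MM) within each
disease-significant module.  Cell-type marker enrichment uses a one-tailed
hypergeometric test with a Bonferroni factor equal to the number of
significant modules.  Gene-set enrichment on MM-ranked lists uses the
weighted Kolmogorov-Smirnov running sum with a gene-label permutation null,
sign-stratified normalization (NES) and the standard pooled FDR estimate,
plus leading-edge extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def select_hubs(gene_stats: pd.DataFrame, sig_modules: list[str],
                quartile: float = 0.75, mm_cut: float | None = None) -> pd.DataFrame:
    """Top-quartile-MM transcripts of each significant module.

    Per module, the ceil((1 - quartile) * size) transcripts with the highest
    MM are hubs (stable order breaks boundary ties, with a logged warning).
    ``mm_cut`` optionally AND-filters hubs to MM >= cut.
    """
    if not sig_modules:
        raise ValueError("empty significant-module list")
    frames = []
    for mod in sig_modules:
        sub = gene_stats[gene_stats.module == mod].copy()
        n_hub = int(np.ceil((1.0 - quartile) * len(sub)))
        order = np.argsort(-sub.MM.to_numpy(), kind="stable")
        hub_idx = set(order[:n_hub])
        if n_hub < len(sub) and n_hub > 0:
            boundary = sub.MM.to_numpy()[order[n_hub - 1]]
            if (sub.MM.to_numpy()[order[n_hub:]] == boundary).any():
                log.warning("MM tie at hub boundary in module %s; stable order used", mod)
        sub["hub"] = [i in hub_idx for i in range(len(sub))]
        if mm_cut is not None:
            sub["hub"] &= sub.MM >= mm_cut
        frames.append(sub)
    return pd.concat(frames)


def collapse_probes(table: pd.DataFrame, probe2gene: pd.DataFrame) -> pd.DataFrame:
    """Collapse probes to gene symbols keeping the max-MM probe per gene.

    ``table`` is indexed by transcript/probe id and must carry an ``MM``
    column; unmapped probes are dropped and counted in the log.
    """
    mapping = probe2gene.set_index("probe_id")["gene_symbol"]
    mapped = table.join(mapping, how="inner")
    dropped = len(table) - len(mapped)
    if dropped:
        log.info("collapse_probes: %d unmapped probes dropped", dropped)
    mapped = mapped.sort_values("MM", ascending=False, kind="stable")
    out = mapped[~mapped.gene_symbol.duplicated()].copy()
    return out


def hypergeom_pval(N: int, K: int, n: int, k: int) -> float:
    """One-tailed enrichment p = P(X >= k), X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def marker_enrichment(module_genes: dict[str, list[str]],
                      marker_sets: dict[str, list[str]],
                      background: list[str],
                      bonferroni_m: int | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """One-tailed hypergeometric enrichment of marker sets in modules.

    Sets are intersected with the background universe; the Bonferroni
    factor defaults to the number of modules tested (matching correction by
    significant-module count); adjusted p capped at 1.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    m = bonferroni_m if bonferroni_m is not None else len(module_genes)
    rows = []
    for mod, genes in module_genes.items():
        mod_set = set(genes) & bg
        for name, members in marker_sets.items():
            kset = set(members) & bg
            overlap = sorted(mod_set & kset)
            p = hypergeom_pval(len(bg), len(kset), len(mod_set), len(overlap))
            rows.append((mod, name, len(bg), len(kset), len(mod_set), len(overlap),
                         p, min(p * m, 1.0), ",".join(overlap)))
    out = pd.DataFrame(rows, columns=["module", "gene_set", "N", "K", "n", "k",
                                      "p", "adj_p", "overlap_genes"])
    out["significant"] = out.adj_p <= alpha
    return out


# ---------------------------------------------------------------------------
# Preranked GSEA

@dataclass
class GseaResult:
    table: pd.DataFrame          # gene_set, size, ES, NES, p, q, es_rank
    leading_edges: dict[str, list[str]]
    ranked_genes: list[str]
    n_excluded: int


def enrichment_score(ranked_scores: np.ndarray, in_set: np.ndarray,
                     weight: float = 1.0) -> tuple[float, int]:
    """Weighted KS enrichment score of a set in a descending-ranked list.

    Hit steps are proportional to |score|^weight (normalized over set
    members); miss steps are uniform.  Returns (ES, 0-based rank of the ES
    extremum).
    """
    n = ranked_scores.size
    k = int(in_set.sum())
    if k == 0 or k == n:
        return 0.0, 0
    w = np.abs(ranked_scores) ** weight
    hit_norm = w[in_set].sum()
    steps = np.where(in_set, w / (hit_norm if hit_norm > 0 else 1.0), -1.0 / (n - k))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def _perm_es(scores: np.ndarray, set_size: int, nperm: int,
             weight: float, rng: np.random.Generator) -> np.ndarray:
    """Gene-label permutation null: random positions for the set members."""
    n = scores.size
    w = np.abs(scores) ** weight
    out = np.empty(nperm)
    miss = -1.0 / (n - set_size)
    for j in range(nperm):
        pos = rng.choice(n, size=set_size, replace=False)
        steps = np.full(n, miss)
        steps[pos] = w[pos] / w[pos].sum()
        running = np.cumsum(steps)
        out[j] = running[np.argmax(np.abs(running))]
    return out


def gsea_preranked(ranked: pd.Series, sets: dict[str, list[str]],
                   nperm: int = 1000, size_bounds: tuple[int, int] = (15, 500),
                   weight: float = 1.0, seed: int = 0,
                   fdr_cut: float = 0.10) -> GseaResult:
    """Preranked GSEA with gene-label permutations.

    ``ranked`` maps gene -> score (sorted internally, descending).  Sets are
    restricted to the ranked universe and excluded outside ``size_bounds``.
    NES divides ES by the mean same-sign permutation ES; q is the standard
    pooled-NES FDR estimate; significance at q <= ``fdr_cut``.
    """
    if nperm < 100:
        raise ValueError("nperm < 100: permutation null too coarse")
    if not np.isfinite(ranked.to_numpy(float)).all():
        raise ValueError("ranked scores must be finite")
    ranked = ranked.sort_values(ascending=False, kind="stable")
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(float)
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    surviving, n_excluded = {}, 0
    for name, members in sets.items():
        idx = sorted(pos_of[g] for g in set(members) if g in pos_of)
        if size_bounds[0] <= len(idx) <= size_bounds[1]:
            surviving[name] = np.asarray(idx)
        else:
            n_excluded += 1
    if not surviving:
        log.warning("no gene set survives the size bounds")
        return GseaResult(pd.DataFrame(columns=["gene_set", "size", "ES", "NES",
                                                "p", "q", "es_rank"]),
                          {}, list(genes), n_excluded)

    rows, nes_null_all = [], []
    for name, idx in surviving.items():
        mask = np.zeros(genes.size, dtype=bool)
        mask[idx] = True
        es, es_rank = enrichment_score(scores, mask, weight)
        null = _perm_es(scores, len(idx), nperm, weight, rng)
        same = null[null * np.sign(es) > 0] if es != 0 else null
        if same.size == 0:
            same = np.abs(null)
        p = (1 + (np.abs(same) >= abs(es)).sum()) / (1 + same.size)
        mean_same = np.abs(same).mean()
        nes = es / mean_same if mean_same > 0 else 0.0
        null_nes = null / np.where(null >= 0,
                                   max(np.abs(null[null > 0]).mean(), 1e-12) if (null > 0).any() else 1.0,
                                   max(np.abs(null[null < 0]).mean(), 1e-12) if (null < 0).any() else 1.0)
        nes_null_all.append(null_nes)
        rows.append((name, len(idx), es, nes, p, es_rank))
    table = pd.DataFrame(rows, columns=["gene_set", "size", "ES", "NES", "p", "es_rank"])
    pooled = np.concatenate(nes_null_all)
    obs = table.NES.to_numpy()
    qs = []
    for nes in obs:
        if nes >= 0:
            num = (pooled >= nes).sum() / max((pooled >= 0).sum(), 1)
            den = (obs >= nes).sum() / max((obs >= 0).sum(), 1)
        else:
            num = (pooled <= nes).sum() / max((pooled < 0).sum(), 1)
            den = (obs <= nes).sum() / max((obs < 0).sum(), 1)
        qs.append(min(num / den if den > 0 else 1.0, 1.0))
    table["q"] = qs
    table["significant"] = table.q <= fdr_cut
    les = {row.gene_set: leading_edge_genes(genes, surviving[row.gene_set],
                                            row.ES, row.es_rank)
           for row in table.itertuples()}
    return GseaResult(table, les, list(genes), n_excluded)


def leading_edge_genes(ranked_genes: np.ndarray, set_idx: np.ndarray,
                       es: float, es_rank: int) -> list[str]:
    """Set members at/before the ES maximum (positive ES) or at/after the
    minimum (negative ES)."""
    if es >= 0:
        sel = set_idx[set_idx <= es_rank]
    else:
        sel = set_idx[set_idx >= es_rank]
    return [str(ranked_genes[i]) for i in sel]


def leading_edge_partition(results: dict[str, GseaResult]) -> pd.DataFrame:
    """Partition significant sets across modules into shared (>= 2 modules)
    and unique (exactly 1), with their leading edges."""
    hits: dict[str, list[str]] = {}
    for module, res in results.items():
        for name in res.table.loc[res.table.significant, "gene_set"]:
            hits.setdefault(name, []).append(module)
    rows = [(name, ",".join(mods), "shared" if len(mods) >= 2 else "unique")
            for name, mods in sorted(hits.items())]
    return pd.DataFrame(rows, columns=["gene_set", "modules", "partition"])
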