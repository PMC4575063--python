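"""Signed weighted co-expression network construction and module statistics.

The network core: a signed similarity s_ij = (1 + r_ij)/2 raised to a soft
threshold beta gives the adjacency; the topological overlap measure (TOM)
turns shared neighborhood into a similarity; average-linkage clustering of
the TOM dissimilarity plus an adaptive branch cut yields modules; module
eigengenes (first principal component of each module) summarize modules and
support trait correlation, module membership (MM) and gene significance
(GS) statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

# conventional size-ranked module palette
COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)
GREY = "grey"


@dataclass
class NetworkParams:
    beta: int | str = "auto"
    betas: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.80
    min_module_size: int = 35
    cut_height: float | None = None      # None = adaptive branch cut
    me_merge_cor: float = 0.80
    signed_mode: str = "shifted"         # "shifted": s=(1+r)/2; "truncated": max(r,0)

    def __post_init__(self):
        if isinstance(self.beta, int) and self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0.0 < self.r2_target < 1.0:
            raise ValueError("r2_target must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


# ---------------------------------------------------------------------------
# Adjacency / TOM

def signed_adjacency(expr: pd.DataFrame, beta: int, mode: str = "shifted") -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + r_ij)/2)^beta with unit diagonal.

    Negative correlations are driven toward 0, selecting for positive
    co-expression.  ``mode="truncated"`` instead zeroes negative r before
    powering.
    """
    x = expr.to_numpy(float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0][:5].tolist()
        raise ValueError(f"zero-variance transcripts (remove first): {bad}")
    r = np.corrcoef(x)
    if mode == "shifted":
        s = (1.0 + r) / 2.0
    elif mode == "truncated":
        s = np.maximum(r, 0.0)
    else:
        raise ValueError(f"unknown signed mode {mode!r}")
    a = np.clip(s, 0.0, 1.0) ** beta
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    a = adj.to_numpy(float)
    return pd.Series(a.sum(axis=1) - np.diag(a), index=adj.index, name="k")


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit: -sign(slope) * R^2 of the regression
    log10(density) ~ log10(mean k) over equal-occupancy connectivity bins.

    Equal-occupancy bins stabilize per-bin means; the occupancy is converted
    to a density (count / bin width) so the degree-distribution shape, not
    the binning, drives the fit.
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    qs = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    qs[-1] += 1e-9
    labels = np.clip(np.searchsorted(qs, k, side="right") - 1, 0, n_bins - 1)
    mean_k, dens = [], []
    for b in range(n_bins):
        sel = labels == b
        width = qs[b + 1] - qs[b]
        if sel.sum() == 0 or width <= 0:
            continue
        mean_k.append(k[sel].mean())
        dens.append(sel.mean() / width)
    if len(mean_k) < 3 or len(set(np.round(np.log10(mean_k), 12))) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(np.log10(mean_k), np.log10(dens))
    if not np.isfinite(r):
        return 0.0
    return float(-np.sign(slope) * r ** 2)


def pick_soft_threshold(expr: pd.DataFrame, betas: tuple[int, ...] = tuple(range(1, 21)),
                        r2_target: float = 0.80, mode: str = "shifted",
                        ) -> tuple[int, pd.DataFrame, bool]:
    """Choose the lowest beta whose signed scale-free fit exceeds ``r2_target``.

    Returns (beta, fit table, fallback flag); with no beta reaching the
    target, the beta maximizing the fit is returned with fallback=True.
    """
    if expr.shape[0] < 50:
        log.warning("fewer than 50 transcripts: degree distribution unstable")
    x = expr.to_numpy(float)
    r = np.corrcoef(x)
    s = (1.0 + r) / 2.0 if mode == "shifted" else np.maximum(r, 0.0)
    np.fill_diagonal(s, 0.0)
    rows = []
    for b in sorted(betas):
        k = (s ** b).sum(axis=1)
        if not np.any(k > 0):
            raise ValueError("all connectivities zero")
        rows.append((b, scale_free_fit(k), float(k.mean())))
    fits = pd.DataFrame(rows, columns=["beta", "signed_r2", "mean_k"])
    ok = fits[fits.signed_r2 > r2_target]
    if len(ok):
        return int(ok.beta.iloc[0]), fits, False
    best = int(fits.loc[fits.signed_r2.idxmax(), "beta"])
    log.warning("no beta reached R^2 target %.2f; falling back to beta=%d", r2_target, best)
    return best, fits, True


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM similarity: w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj over u != i, j; unit diagonal."""
    a = adj.to_numpy(float)
    _check_unit_interval(a, "adjacency")
    k = a.sum(axis=0) - np.diag(a)
    l = a @ a - a * (np.diag(a)[:, None] + np.diag(a)[None, :])  # noqa: E741
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (l + a) / denom
    w = np.nan_to_num(w, nan=0.0)
    np.fill_diagonal(w, 1.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(w, index=adj.index, columns=adj.columns)


def _check_unit_interval(a: np.ndarray, what: str) -> None:
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError(f"{what} matrix not symmetric")
    if a.min() < -1e-10 or a.max() > 1 + 1e-10:
        raise ValueError(f"{what} values outside [0, 1]")


# ---------------------------------------------------------------------------
# Module detection

@dataclass
class ModuleAssignment:
    labels: pd.Series                      # transcript -> color ("grey" = unassigned)
    linkage_matrix: np.ndarray
    cut_height: float
    params: NetworkParams | None = None

    @property
    def modules(self) -> list[str]:
        return [c for c in self.labels.unique() if c != GREY]

    def members(self, color: str) -> list[str]:
        return self.labels.index[self.labels == color].tolist()


def _subtree_leaves(node: int, children: np.ndarray) -> list[int]:
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        if children[v][0] == -1:
            out.append(v)
        else:
            stack.extend(children[v])
    return out


def _components_at(internal: list[int], heights: np.ndarray, children: np.ndarray,
                   leaf_ids: list[int], t: float) -> dict[int, list[int]]:
    """Connected components of a subtree using only merges at height <= t."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for v in internal:
        if heights[v] > t:
            break
        a, b = children[v]
        parent[find(int(a))] = v
        parent[find(int(b))] = v
    groups: dict[int, list[int]] = {}
    for leaf in leaf_ids:
        groups.setdefault(find(leaf), []).append(leaf)
    return groups


def _split_branch(node: int, children: np.ndarray, heights: np.ndarray,
                  min_size: int, max_cuts: int = 200) -> list[list[int]]:
    """Recursive adaptive branch cut.

    Within the branch, candidate cut heights are scanned and the cut
    maximizing the number of size-qualified subclusters is chosen (ties
    resolved toward the highest cut, which keeps branch periphery).  Each
    qualified subcluster is split recursively; a branch with no qualified
    sub-split is returned whole as a candidate module.
    """
    leaf_ids = _subtree_leaves(node, children)
    internal = sorted((v for v in _collect_internal(node, children)), key=lambda v: heights[v])
    if len(leaf_ids) < 2 * min_size or not internal:
        return [leaf_ids]
    uniq = np.unique(heights[internal])
    cand = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else uniq
    if len(cand) > max_cuts:
        cand = cand[np.linspace(0, len(cand) - 1, max_cuts).astype(int)]
    best_t, best_count = None, 1
    for t in cand:
        groups = _components_at(internal, heights, children, leaf_ids, float(t))
        count = sum(1 for g in groups.values() if len(g) >= min_size)
        if count >= best_count:   # tie -> larger t keeps periphery
            best_count, best_t = count, float(t)
    if best_count < 2 or best_t is None:
        return [leaf_ids]
    out: list[list[int]] = []
    groups = _components_at(internal, heights, children, leaf_ids, best_t)
    for root, members in groups.items():
        if len(members) >= min_size:
            out.extend(_split_branch(root, children, heights, min_size, max_cuts))
    return out or [leaf_ids]


def _collect_internal(node: int, children: np.ndarray) -> list[int]:
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        if children[v][0] != -1:
            out.append(v)
            stack.extend(children[v])
    return out


def detect_modules(tom: pd.DataFrame, params: NetworkParams,
                   min_contrast: float = 1.8) -> ModuleAssignment:
    """Average-linkage clustering of TOM dissimilarity with adaptive branch cuts.

    The dendrogram is split top-down: within each branch, candidate cut
    heights are scanned and the cut maximizing the number of
    ``min_module_size``-qualified subclusters is applied recursively, so
    modules that merge at different heights (e.g. trait-coupled modules)
    are still resolved.  A final branch is accepted as a module only when
    its cohesion contrast -- mean within-branch TOM similarity divided by
    the mean similarity of members to non-members -- is at least
    ``min_contrast``; amorphous branches of mutually-close noise sit near
    contrast 1 and go to grey.  With an explicit ``cut_height`` a single
    static cut replaces the adaptive scan.  Modules are renamed in
    size-ranked color order; eigengene-based merging is applied separately
    via :func:`merge_close_modules`.
    """
    w = tom.to_numpy(float)
    _check_unit_interval(w, "TOM")
    n = w.shape[0]
    if n < params.min_module_size:
        log.warning("fewer transcripts than min_module_size: all grey")
        labels = pd.Series(GREY, index=tom.index, name="module")
        return ModuleAssignment(labels, np.zeros((0, 4)), 0.0, params)
    d = 1.0 - w
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    heights = np.zeros(2 * n - 1)
    children = np.full((2 * n - 1, 2), -1, dtype=int)
    for m in range(n - 1):
        children[n + m] = z[m, :2].astype(int)
        heights[n + m] = z[m, 2]
    root = 2 * n - 2

    if params.cut_height is not None:
        internal = sorted(_collect_internal(root, children), key=lambda v: heights[v])
        groups = _components_at(internal, heights, children, list(range(n)),
                                float(params.cut_height))
        clusters = [g for g in groups.values() if len(g) >= params.min_module_size]
        cut_used = float(params.cut_height)
    else:
        clusters = [c for c in _split_branch(root, children, heights,
                                             params.min_module_size)
                    if len(c) >= params.min_module_size]
        cut_used = float(heights[root])

    raw = np.full(n, -1)
    next_id = 0
    for members in clusters:
        if len(members) == n:
            # a candidate spanning the whole input has no outside reference
            # against which cohesion could be established; leave it grey
            continue
        idx = np.asarray(members)
        rest = np.setdiff1d(np.arange(n), idx, assume_unique=True)
        if rest.size:
            # shed members whose similarity to the cluster sits at background
            # level (tagalongs accreted by the cut), then re-check the size
            member_in = (w[np.ix_(idx, idx)].sum(axis=1) - 1.0) / max(len(idx) - 1, 1)
            member_out = w[np.ix_(idx, rest)].mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(member_out > 0, member_in / member_out, np.inf)
            idx = idx[ratio >= min_contrast]
        if len(idx) < params.min_module_size:
            continue
        sub = w[np.ix_(idx, idx)]
        intra = float(sub[np.triu_indices(len(idx), 1)].mean())
        rest = np.setdiff1d(np.arange(n), idx, assume_unique=True)
        extra = float(w[np.ix_(idx, rest)].mean()) if rest.size else 0.0
        cohesive = intra > 0 if extra <= 0 else (intra / extra) >= min_contrast
        if cohesive:
            raw[idx] = next_id
            next_id += 1
    labels = pd.Series(raw, index=tom.index)
    return ModuleAssignment(_rename_by_size(labels), z, cut_used, params)


def _rename_by_size(raw: pd.Series) -> pd.Series:
    sizes = raw[raw != -1].value_counts()
    mapping = {lab: COLORS[i] if i < len(COLORS) else f"module{i}"
               for i, lab in enumerate(sizes.index)}
    mapping[-1] = GREY
    return raw.map(mapping).rename("module")


def merge_close_modules(expr: pd.DataFrame, assignment: ModuleAssignment,
                        me_merge_cor: float = 0.80) -> ModuleAssignment:
    """Iteratively merge module pairs whose eigengenes correlate >= threshold."""
    labels = assignment.labels.copy()
    while True:
        me = module_eigengenes(expr, ModuleAssignment(labels, assignment.linkage_matrix,
                                                      assignment.cut_height))
        if me.shape[1] < 2:
            break
        cors = np.corrcoef(me.to_numpy().T)
        np.fill_diagonal(cors, -np.inf)
        i, j = np.unravel_index(np.argmax(cors), cors.shape)
        if cors[i, j] < me_merge_cor:
            break
        keep, drop = me.columns[i], me.columns[j]
        labels[labels == drop] = keep
    sizes = labels[labels != GREY].value_counts()
    mapping = {lab: COLORS[i] if i < len(COLORS) else f"module{i}"
               for i, lab in enumerate(sizes.index)}
    mapping[GREY] = GREY
    return ModuleAssignment(labels.map(mapping).rename("module"),
                            assignment.linkage_matrix, assignment.cut_height,
                            assignment.params)


def assign_close_transcripts(expr: pd.DataFrame, assignment: ModuleAssignment,
                             min_kme: float = 0.2, max_iter: int = 3) -> ModuleAssignment:
    """Eigengene-membership sweep over all transcripts.

    The adaptive branch cut keeps module cores tight but leaves weakly
    loaded periphery in grey; this refinement reassigns every transcript to
    the module whose eigengene it correlates with most strongly, provided
    that correlation (kME) is at least ``min_kme`` (otherwise grey).  The
    default floor of 0.2 follows the common membership-correlation
    convention for declaring a transcript module-assignable.  Eigengenes
    are recomputed between sweeps; the sweep is a k-means-style refinement
    with module eigengenes as centroids and typically converges in one or
    two passes.
    """
    labels = assignment.labels.copy()
    r_crit = min_kme
    x = expr.to_numpy(float)
    xs = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xs ** 2).sum(axis=1))
    norm[norm == 0] = 1.0
    xs = xs / norm[:, None]
    for _ in range(max_iter):
        current = ModuleAssignment(labels, assignment.linkage_matrix,
                                   assignment.cut_height, assignment.params)
        if not current.modules:
            return current
        me = module_eigengenes(expr, current)
        m = me.to_numpy(float)
        mc = m - m.mean(axis=0)
        ms = mc / np.sqrt((mc ** 2).sum(axis=0))
        kme = xs @ ms
        best = kme.argmax(axis=1)
        best_r = kme[np.arange(len(labels)), best]
        new = np.where(best_r >= r_crit, me.columns.to_numpy()[best], GREY)
        new_labels = pd.Series(new, index=labels.index)
        converged = bool((new_labels == labels).all())
        labels = new_labels
        if converged:
            break
    return ModuleAssignment(_rename_raw(labels), assignment.linkage_matrix,
                            assignment.cut_height, assignment.params)


def _critical_r(alpha: float, n: int) -> float:
    df = max(n - 2, 1)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit ** 2))


def _rename_raw(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    mapping = {lab: COLORS[i] if i < len(COLORS) else f"module{i}"
               for i, lab in enumerate(sizes.index)}
    mapping[GREY] = GREY
    return labels.map(mapping).rename("module")


# ---------------------------------------------------------------------------
# Eigengenes and statistics

def module_eigengenes(expr: pd.DataFrame, modules: ModuleAssignment) -> pd.DataFrame:
    """First principal component per module, unit variance, sign-oriented.

    Each module's member transcripts are standardized; the first right
    singular vector across samples is scaled to unit variance and oriented
    so it correlates positively with the module mean expression profile.
    Grey is excluded.  Returns samples x modules.
    """
    out = {}
    for color in modules.modules:
        members = modules.members(color)
        x = expr.loc[members].to_numpy(float)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        xs = (x - x.mean(axis=1, keepdims=True)) / sd
        if xs.shape[0] == 1:
            me = xs[0]
        else:
            _, _, vt = np.linalg.svd(xs, full_matrices=False)
            me = vt[0]
        me = me - me.mean()
        sd_me = me.std(ddof=1) if me.size > 1 else 0.0
        me = me / (sd_me if sd_me > 0 else 1.0)
        if np.corrcoef(me, xs.mean(axis=0))[0, 1] < 0:
            me = -me
        out[color] = me
    return pd.DataFrame(out, index=expr.columns)


def _cor_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(np.asarray(r, float), -0.9999999999, 0.9999999999)
    df = max(n - 2, 1)
    t = r * np.sqrt(df / (1.0 - r ** 2))
    return 2.0 * stats.t.sf(np.abs(t), df)


@dataclass
class ModuleTraitReport:
    correlations: pd.DataFrame   # modules x traits, Pearson r
    pvalues: pd.DataFrame        # raw p
    adjusted: pd.DataFrame       # Bonferroni by number of non-grey modules
    confounded: list[str] = field(default_factory=list)
    significant: list[str] = field(default_factory=list)   # disease-significant
    signs: dict[str, int] = field(default_factory=dict)


CONFOUNDER_TRAITS = ("ph", "pmi", "age", "rin")


def module_trait_analysis(me: pd.DataFrame, pheno: pd.DataFrame, traits: list[str],
                          alpha: float = 0.05, disease_trait: str = "case",
                          ) -> ModuleTraitReport:
    """Correlate eigengenes with traits; flag confounded modules.

    Pearson correlation per (module, trait) with t-based p (n - 2 df) and a
    Bonferroni factor equal to the number of non-grey modules; modules
    significant for a confounder trait (pH, PMI, age, RIN) are flagged and
    excluded from the disease-significant list.
    """
    ph = pheno.loc[me.index]
    n = len(me.index)
    m = me.shape[1]
    r = pd.DataFrame(index=me.columns, columns=traits, dtype=float)
    for trait in traits:
        tv = ph[trait].to_numpy(float)
        if np.std(tv) == 0:
            raise ValueError(f"trait {trait!r} constant across samples")
        tvs = (tv - tv.mean()) / tv.std()
        for mod in me.columns:
            r.loc[mod, trait] = float(np.corrcoef(me[mod].to_numpy(), tvs)[0, 1])
    p = pd.DataFrame(_cor_p(r.to_numpy(float), n), index=r.index, columns=r.columns)
    adj = (p * m).clip(upper=1.0)
    confounded = [mod for mod in me.columns
                  if any(t in adj.columns and adj.loc[mod, t] <= alpha
                         for t in CONFOUNDER_TRAITS)]
    significant = [mod for mod in me.columns
                   if disease_trait in adj.columns
                   and adj.loc[mod, disease_trait] <= alpha and mod not in confounded]
    signs = {mod: int(np.sign(r.loc[mod, disease_trait])) for mod in significant}
    return ModuleTraitReport(r, p, adj, confounded, significant, signs)


def membership_significance(expr: pd.DataFrame, me: pd.DataFrame,
                            modules: ModuleAssignment, trait: pd.Series) -> pd.DataFrame:
    """Module membership (signed cor with own ME) and gene significance
    (absolute cor with the trait) per transcript, with p-values.

    Grey transcripts get MM against the grey mean profile and are flagged
    non-informative.
    """
    tv = trait.loc[expr.columns].to_numpy(float)
    tvs = (tv - tv.mean()) / tv.std()
    n = expr.shape[1]
    x = expr.to_numpy(float)
    xs = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xs ** 2).sum(axis=1))
    norm[norm == 0] = 1.0
    gs_r = (xs @ tvs) / (norm * np.sqrt((tvs ** 2).sum()))
    grey_profile = None
    grey_members = modules.members(GREY) if (modules.labels == GREY).any() else []
    if grey_members:
        g = expr.loc[grey_members].to_numpy(float)
        gm = g.mean(axis=0)
        grey_profile = (gm - gm.mean()) / (gm.std() if gm.std() > 0 else 1.0)
    rows = []
    for i, tid in enumerate(expr.index):
        color = modules.labels.loc[tid]
        if color == GREY:
            ref = grey_profile
        else:
            ref = me[color].to_numpy()
        mm = float(np.corrcoef(x[i], ref)[0, 1]) if ref is not None else np.nan
        rows.append((tid, color, mm, abs(float(gs_r[i]))))
    stats_df = pd.DataFrame(rows, columns=["transcript_id", "module", "MM", "GS"])
    stats_df["MM_p"] = _cor_p(stats_df.MM.fillna(0).to_numpy(), n)
    stats_df["GS_p"] = _cor_p(stats_df.GS.to_numpy(), n)
    stats_df["informative"] = stats_df.module != GREY
    return stats_df.set_index("transcript_id")
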