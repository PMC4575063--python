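"""Synthetic cohort generator with planted ground truth.

Emulates the structure of a small matched case-control postmortem brain
expression study: two expression platforms (mRNA and miRNA) on the same
subjects, planted co-expression modules whose eigengenes carry case-control
or confounder signal, planted miRNA repression of mRNA hub genes, planted
cis-eQTLs on a synthetic chromosome, and an independent, much larger GWAS
cohort whose liability is driven by a configurable variant subset.

The generative model for a module-q gene i is

    x_i = u_i * e_q + sqrt(1 - u_i^2) * eps,      eps ~ N(0, 1) iid,

with eigengene e_q = sign_q * alpha_q * z + sqrt(1 - alpha_q^2) * eta, where
z is the standardized case indicator (or a standardized continuous
confounder for confounded modules).  Gene loadings u_i are drawn uniformly
from ``loading_range``; by construction cor(x_i, x_j) -> u_i * u_j for two
genes of the same module.  Repression subtracts gamma times the miRNA
profile from the target mRNA, producing a negative expression correlation.
All draws flow from one ``numpy`` Generator, so a seed fully determines
every emitted file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from coexqtl import io

CELL_TYPES = ("Neuron", "Astrocyte", "Microglia", "Oligodendrocyte", "Endothelial")


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``trait_loading`` is the |correlation| of the module eigengene with its
    driver; the driver is the standardized case indicator, or, when
    ``confounder`` names a phenotype column, a mix of the standardized
    confounder (weight ``confounder_mix``) and the case indicator.  The mix
    keeps confounded modules partially case-associated, mirroring confounded
    modules that survive nominal differential-expression filtering before
    being flagged and removed.  ``sign`` gives the direction of the
    association (-1 = downregulated in cases).
    """

    size: int
    trait_loading: float
    sign: int = 1
    confounder: str | None = None
    confounder_mix: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.trait_loading <= 1.0:
            raise ValueError(f"trait loading must be in [0, 1], got {self.trait_loading}")
        if self.sign not in (-1, 1):
            raise ValueError("module sign must be -1 or +1")
        if self.size < 1:
            raise ValueError("module size must be positive")


@dataclass(frozen=True)
class RepressionSpec:
    """Planted repression of mRNA hubs of one module by miRNA hubs of another."""

    mirna_module: int
    mrna_module: int
    gamma: float = 0.6
    n_pairs: int = 20


@dataclass(frozen=True)
class EqtlSpec:
    """One planted cis-eQTL. ``gene=None`` means: pick an unused planted mRNA hub."""

    gene: str | None = None
    maf: float = 0.35
    beta: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"MAF must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class GwasSpec:
    """External case-control cohort driven by a variant subset.

    ``causal_from_eqtl`` plants the association on the first
    ``n_causal`` planted eQTL variants with per-allele log-odds ``b``;
    explicit ``variant_effects`` override that convenience.
    """

    n_subjects: int = 1399
    beta0: float = 0.0
    causal_from_eqtl: bool = True
    n_causal: int = 4
    b: float = 0.5
    symptom_base_rate: float = 3.0
    symptom_scale: float = 0.5
    variant_effects: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 36
    n_mrna: int = 3000
    n_mirna: int = 300
    mrna_modules: tuple[ModuleSpec, ...] = ()
    mirna_modules: tuple[ModuleSpec, ...] = ()
    loading_range: tuple[float, float] = (0.3, 0.95)
    repression_spec: tuple[RepressionSpec, ...] = ()
    eqtl_spec: tuple[EqtlSpec, ...] = ()
    gwas_spec: GwasSpec = field(default_factory=GwasSpec)
    n_variants: int = 600
    decoy_rate: float = 0.3
    marker_overlap: float = 0.8
    marker_size: int = 60
    miss_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.loading_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"loading range must satisfy 0 <= lo <= hi <= 1, got {self.loading_range}")
        if sum(m.size for m in self.mrna_modules) > self.n_mrna:
            raise ValueError("mRNA module sizes exceed transcript count")
        if sum(m.size for m in self.mirna_modules) > self.n_mirna:
            raise ValueError("miRNA module sizes exceed transcript count")
        if not 0.0 <= self.decoy_rate < 1.0:
            raise ValueError("decoy_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Planted ground truth; every identifier resolves in the emitted tables."""

    mrna_modules: dict[str, str] = field(default_factory=dict)   # transcript -> module label
    mirna_modules: dict[str, str] = field(default_factory=dict)
    module_loading: dict[str, float] = field(default_factory=dict)  # label -> signed alpha
    module_confounder: dict[str, str] = field(default_factory=dict)
    gene_loading: dict[str, float] = field(default_factory=dict)    # transcript -> u_i
    mrna_hubs: list[str] = field(default_factory=list)
    mirna_hubs: list[str] = field(default_factory=list)
    repression_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    eqtls: list[tuple[str, str, float]] = field(default_factory=list)  # (variant, gene, beta)
    gwas_causal: dict[str, float] = field(default_factory=dict)
    gene_coords: pd.DataFrame | None = None
    probe2gene: dict[str, str] = field(default_factory=dict)

    def module_map(self, kind: str) -> pd.Series:
        src = self.mrna_modules if kind == "mrna" else self.mirna_modules
        return pd.Series(src, name="module")


def _hub_count(size: int, share: float = 0.25) -> int:
    return math.ceil(share * size)


def _simulate_platform(rng: np.random.Generator, prefix: str, n_transcripts: int,
                       modules: Sequence[ModuleSpec], loading_range: tuple[float, float],
                       z_class: np.ndarray, pheno: pd.DataFrame,
                       ) -> tuple[pd.DataFrame, dict[str, str], dict[str, float],
                                  dict[str, str], dict[str, float], list[str],
                                  dict[str, np.ndarray]]:
    """Simulate one platform; returns expression plus truth pieces."""
    n = z_class.size
    ids = [f"{prefix}_{i:05d}" for i in range(n_transcripts)]
    x = rng.standard_normal((n_transcripts, n))
    module_of: dict[str, str] = {}
    loading_of_module: dict[str, float] = {}
    confounder_of: dict[str, str] = {}
    loading_of_gene: dict[str, float] = {}
    hubs: list[str] = []
    eigengenes: dict[str, np.ndarray] = {}
    start = 0
    for q, spec in enumerate(modules):
        label = f"{prefix}_mod{q}"
        if spec.confounder is not None:
            conf = pheno[spec.confounder].to_numpy(float)
            conf = (conf - conf.mean()) / conf.std()
            w = spec.confounder_mix
            driver = math.sqrt(w) * conf + math.sqrt(1.0 - w) * z_class
            driver = (driver - driver.mean()) / driver.std()
            confounder_of[label] = spec.confounder
        else:
            driver = z_class
        a = spec.trait_loading
        e_q = spec.sign * a * driver + math.sqrt(1.0 - a * a) * rng.standard_normal(n)
        e_q = (e_q - e_q.mean()) / e_q.std()
        eigengenes[label] = e_q
        u = rng.uniform(*sorted(loading_range), size=spec.size)
        members = ids[start:start + spec.size]
        x[start:start + spec.size] = (u[:, None] * e_q[None, :]
                                      + np.sqrt(1.0 - u ** 2)[:, None]
                                      * rng.standard_normal((spec.size, n)))
        for t, ui in zip(members, u):
            module_of[t] = label
            loading_of_gene[t] = float(ui)
        loading_of_module[label] = float(spec.sign * a)
        order = np.argsort(-u, kind="stable")
        hubs.extend(members[i] for i in order[:_hub_count(spec.size)])
        start += spec.size
    expr = pd.DataFrame(x, index=ids, columns=pheno.index)
    return expr, module_of, loading_of_module, confounder_of, loading_of_gene, hubs, eigengenes


def simulate_expression(cfg: SimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate mRNA and miRNA expression, phenotypes and planted truth.

    Returns (mRNA expression, miRNA expression, phenotype table, truth); both
    expression frames are transcripts x samples on a standard-normal
    (log2-like) scale.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i:03d}" for i in range(n)]
    case = np.zeros(n, dtype=int)
    case[: n // 2] = 1
    pheno = pd.DataFrame({
        "case": case,
        "age": np.round(rng.normal(55, 10, n), 1),
        "ph": np.round(rng.normal(6.6, 0.25, n), 2),
        "pmi": np.round(rng.normal(30, 10, n), 1),
        "rin": np.round(rng.normal(7.2, 0.7, n), 1),
        "smoking": rng.integers(0, 2, n),
    }, index=pd.Index(samples, name="sample_id"))
    z = (case - case.mean()) / case.std()

    truth = SimTruth()
    (mrna, truth.mrna_modules, lm, cm, gl, truth.mrna_hubs, _eg_m
     ) = _simulate_platform(rng, "mRNA", cfg.n_mrna, cfg.mrna_modules,
                            cfg.loading_range, z, pheno)
    truth.module_loading.update(lm)
    truth.module_confounder.update(cm)
    truth.gene_loading.update(gl)
    (mirna, truth.mirna_modules, lm2, cm2, gl2, truth.mirna_hubs, _eg_mi
     ) = _simulate_platform(rng, "miRNA", cfg.n_mirna, cfg.mirna_modules,
                            cfg.loading_range, z, pheno)
    truth.module_loading.update(lm2)
    truth.module_confounder.update(cm2)
    truth.gene_loading.update(gl2)

    # Planted repression: strongest hubs on both sides so recovery is well-posed.
    for spec in cfg.repression_spec:
        mi_label = f"miRNA_mod{spec.mirna_module}"
        mr_label = f"mRNA_mod{spec.mrna_module}"
        mi_hubs = [t for t in truth.mirna_hubs if truth.mirna_modules[t] == mi_label]
        mr_hubs = [t for t in truth.mrna_hubs if truth.mrna_modules[t] == mr_label]
        if not mi_hubs or not mr_hubs:
            raise ValueError(f"repression spec references empty module {mi_label}/{mr_label}")
        # hub lists are loading-ordered; take the strongest half so that the
        # planted pairs sit safely inside the recoverable hub sets
        mi_hubs = mi_hubs[: max(len(mi_hubs) // 2, 1)]
        mr_hubs = mr_hubs[: max(len(mr_hubs) // 2, 1)]
        combos = [(a, b) for b in mr_hubs for a in mi_hubs]
        idx = rng.choice(len(combos), size=min(spec.n_pairs, len(combos)), replace=False)
        for i in sorted(idx):
            mi_id, mr_id = combos[i]
            mrna.loc[mr_id] = mrna.loc[mr_id] - spec.gamma * mirna.loc[mi_id]
            truth.repression_pairs.append((mi_id, mr_id, spec.gamma))
    return mrna, mirna, pheno, truth


# ---------------------------------------------------------------------------
# Genotypes and eQTL planting

CHROM = "chr1"
GENE_SPACING = 40_000
GENE_LENGTH = 10_000


def _gene_coordinates(transcripts: Sequence[str]) -> pd.DataFrame:
    """Lay transcripts head to tail on one synthetic chromosome."""
    starts = GENE_SPACING * np.arange(1, len(transcripts) + 1)
    return pd.DataFrame({
        "transcript_id": list(transcripts),
        "chrom": CHROM,
        "start": starts,
        "end": starts + GENE_LENGTH,
    })


def simulate_genotypes(cfg: SimConfig, truth: SimTruth, expr: pd.DataFrame,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate dosages, plant cis-eQTLs, and add their effects to expression.

    Returns (dosage matrix variants x samples, variant map, expression with
    eQTL effects added, updated truth).  Planted variants land within 1 Mb of
    their target gene; decoy variants are placed away from every planted
    target.  Dosages are Binomial(2, MAF) per variant and sample.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    coords = _gene_coordinates(list(expr.index))
    truth.gene_coords = coords
    pos_of = dict(zip(coords.transcript_id, coords.start))

    # resolve auto targets among planted mRNA hubs, strongest loadings first
    used: set[str] = set()
    resolved: list[EqtlSpec] = []
    hub_pool = [t for t in truth.mrna_hubs if t in expr.index]
    for spec in cfg.eqtl_spec:
        if spec.gene is None:
            candidates = [t for t in hub_pool if t not in used]
            if not candidates:
                raise ValueError("no unused planted hub left for auto eQTL target")
            spec = replace(spec, gene=candidates[0])
        if spec.gene not in expr.index:
            raise ValueError(f"eQTL target gene {spec.gene!r} not in expression matrix")
        used.add(spec.gene)
        resolved.append(spec)

    chrom_end = int(coords.end.max()) + GENE_SPACING
    rows, dosage_rows, mafs = [], [], []
    planted_pos = []
    for k, spec in enumerate(resolved):
        centre = pos_of[spec.gene] + GENE_LENGTH // 2
        pos = int(np.clip(centre + rng.integers(-500_000, 500_000), 1, chrom_end))
        vid = f"var_eqtl{k:03d}"
        rows.append((vid, CHROM, pos, "A", "G"))
        mafs.append(spec.maf)
        planted_pos.append((pos_of[spec.gene], pos))
        truth.eqtls.append((vid, spec.gene, spec.beta))
    target_starts = np.array([pos_of[s.gene] for s in resolved], dtype=float)
    n_decoys = max(cfg.n_variants - len(resolved), 0)
    k = 0
    while k < n_decoys:
        pos = int(rng.integers(1, chrom_end))
        # keep decoys > 1 Mb away from every planted target gene
        if target_starts.size and np.min(np.abs(target_starts - pos)) <= 1_000_000:
            continue
        rows.append((f"var_decoy{k:04d}", CHROM, pos, "A", "G"))
        mafs.append(float(rng.uniform(0.05, 0.5)))
        k += 1
    vm = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    vm["maf"] = mafs
    dosages = rng.binomial(2, np.asarray(mafs)[:, None],
                           size=(len(vm), expr.shape[1])).astype(float)
    geno = pd.DataFrame(dosages, index=vm.variant_id.to_numpy(), columns=expr.columns)

    expr = expr.copy()
    for (vid, gene, beta) in truth.eqtls:
        expr.loc[gene] = expr.loc[gene] + beta * geno.loc[vid].to_numpy()
    return geno, vm, expr, truth


def genotype_probabilities(cfg: SimConfig, geno: pd.DataFrame) -> np.ndarray:
    """Turn hard dosages into GEN-style probability triples.

    A fraction ``miss_rate`` of entries gets a flat, sub-threshold triple so
    the hard-call step has genuine missingness to handle.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    d = geno.to_numpy().astype(int)
    probs = np.full((*d.shape, 3), 0.0005)
    np.put_along_axis(probs, d[..., None], 0.999, axis=2)
    fuzz = rng.random(d.shape) < cfg.miss_rate
    probs[fuzz] = np.array([0.4, 0.35, 0.25])
    return probs


# ---------------------------------------------------------------------------
# External GWAS cohort

def simulate_gwas_cohort(cfg: SimConfig, vm: pd.DataFrame, truth: SimTruth | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an independent case-control cohort.

    Case status is Bernoulli(logistic(beta0 + sum b_j G_j)); the symptom
    count is Poisson with log-rate linear in the same genetic score; a null
    quantitative phenotype (max drinks in 24 h) is included as well.
    Returns (dosage matrix variants x subjects, phenotype table).
    """
    spec = cfg.gwas_spec
    if spec.n_subjects < 50:
        raise ValueError("GWAS cohort below 50 subjects: set-based test unreliable")
    rng = np.random.default_rng(cfg.seed + 3)
    effects = dict(spec.variant_effects)
    if not effects and spec.causal_from_eqtl and truth is not None:
        effects = {vid: spec.b for vid, _, _ in truth.eqtls[: spec.n_causal]}
    unknown = [v for v in effects if v not in set(vm.variant_id)]
    if unknown:
        raise ValueError(f"GWAS causal variants absent from variant map: {unknown}")
    mafs = vm.set_index("variant_id").maf.to_numpy(float)
    G = rng.binomial(2, mafs[:, None], size=(len(vm), spec.n_subjects)).astype(float)
    subjects = [f"COGA{i:05d}" for i in range(spec.n_subjects)]
    geno = pd.DataFrame(G, index=vm.variant_id.to_numpy(), columns=subjects)
    score = np.zeros(spec.n_subjects)
    for vid, b in effects.items():
        score += b * geno.loc[vid].to_numpy()
    p_case = 1.0 / (1.0 + np.exp(-(spec.beta0 + score)))
    case = rng.binomial(1, p_case)
    lam = spec.symptom_base_rate * np.exp(spec.symptom_scale * score)
    pheno = pd.DataFrame({
        "AD_DX": case,
        "AD_SX": rng.poisson(lam),
        "MAX24": np.round(np.exp(rng.normal(1.5, 0.6, spec.n_subjects)), 1),
        "age": np.round(rng.normal(38, 12, spec.n_subjects), 1),
        "sex": rng.integers(0, 2, spec.n_subjects),
    }, index=pd.Index(subjects, name="sample_id"))
    if truth is not None:
        truth.gwas_causal = {k: float(v) for k, v in effects.items()}
    return geno, pheno


# ---------------------------------------------------------------------------
# Annotations: probe map, marker and gene-set GMTs, target predictions

def simulate_annotations(cfg: SimConfig, truth: SimTruth,
                         ) -> tuple[dict[str, list[str]], dict[str, list[str]],
                                    pd.DataFrame, pd.DataFrame]:
    """Build marker GMT, a-priori gene-set GMT, probe->gene map and prediction table.

    The probe map includes duplicate probes per gene symbol; marker sets
    overlap their designated module at ``marker_overlap``; gene sets include
    module-enriched sets, random sets, and two sets outside the [15, 500]
    size window to exercise size filtering.  The prediction table holds every
    planted repression pair plus decoys at ``decoy_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    probes = [f"mRNA_{i:05d}" for i in range(cfg.n_mrna)]
    n_genes = max(int(round(0.9 * cfg.n_mrna)), 1)
    symbols = [f"G{i:05d}" for i in range(n_genes)]
    probe2gene = {p: symbols[i] if i < n_genes else symbols[int(rng.integers(0, n_genes))]
                  for i, p in enumerate(probes)}
    truth.probe2gene = dict(probe2gene)
    p2g = pd.DataFrame({"probe_id": probes, "gene_symbol": [probe2gene[p] for p in probes]})

    def to_symbols(probe_list):
        return sorted({probe2gene[p] for p in probe_list if p in probe2gene})

    module_members: dict[str, list[str]] = {}
    for t, label in truth.mrna_modules.items():
        module_members.setdefault(label, []).append(t)

    markers: dict[str, list[str]] = {}
    for q, (label, members) in enumerate(sorted(module_members.items())):
        cell = CELL_TYPES[q % len(CELL_TYPES)]
        n_in = int(round(cfg.marker_overlap * cfg.marker_size))
        inside = list(rng.choice(to_symbols(members), size=min(n_in, len(members)),
                                 replace=False))
        outside_pool = [s for s in symbols if s not in set(inside)]
        outside = list(rng.choice(outside_pool, size=cfg.marker_size - len(inside),
                                  replace=False))
        markers[f"{cell}_markers_{label}"] = sorted(inside + outside)

    genesets: dict[str, list[str]] = {}
    for q, (label, members) in enumerate(sorted(module_members.items())):
        msym = to_symbols(members)
        n_in = min(max(int(0.6 * 50), 15), len(msym))
        inside = list(rng.choice(msym, size=n_in, replace=False))
        outside = list(rng.choice(symbols, size=50 - n_in, replace=False))
        genesets[f"pathway_enriched_{label}"] = sorted(set(inside + outside))
    for r in range(6):
        size = int(rng.integers(15, 101))
        genesets[f"pathway_random_{r}"] = sorted(rng.choice(symbols, size=size, replace=False))
    genesets["pathway_too_small"] = sorted(rng.choice(symbols, size=5, replace=False))
    genesets["pathway_too_large"] = sorted(rng.choice(symbols, size=min(600, n_genes), replace=False))

    planted = [(mi, probe2gene[mr], 1.0) for mi, mr, _ in truth.repression_pairs]
    planted = list(dict.fromkeys(planted))  # dedupe pairs collapsing to one symbol
    n_decoys = int(round(cfg.decoy_rate / (1.0 - cfg.decoy_rate) * len(planted)))
    hub_syms = sorted({probe2gene[t] for t in truth.mrna_hubs})
    mi_pool = sorted(set(truth.mirna_hubs)) or [f"miRNA_{i:05d}" for i in range(cfg.n_mirna)]
    seen = {(a, b) for a, b, _ in planted}
    decoys = []
    while len(decoys) < n_decoys and hub_syms:
        mi = mi_pool[int(rng.integers(0, len(mi_pool)))]
        g = hub_syms[int(rng.integers(0, len(hub_syms)))]
        if (mi, g) not in seen:
            seen.add((mi, g))
            decoys.append((mi, g, 1.0))
    predictions = pd.DataFrame(planted + decoys,
                               columns=["mirna_id", "gene_symbol", "score"])
    return markers, genesets, p2g, predictions


# ---------------------------------------------------------------------------
# Default study configuration and cohort writer

def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default synthetic cohort: 36 samples (18/18), 3000 mRNA probes with
    five planted modules (one confounded by brain pH), 300 miRNA probes with
    three planted modules, planted repression of two mRNA modules by two
    upregulated miRNA modules, eight planted cis-eQTLs, and a 1399-subject
    external GWAS cohort."""
    cfg = SimConfig(
        n_samples=36,
        n_mrna=3000,
        n_mirna=300,
        mrna_modules=(
            ModuleSpec(900, 0.8, sign=-1),
            ModuleSpec(700, 0.7, sign=-1),
            ModuleSpec(550, 0.6, sign=1),
            ModuleSpec(450, 0.6, sign=1),
            ModuleSpec(300, 0.75, sign=1, confounder="ph"),
        ),
        mirna_modules=(
            ModuleSpec(110, 0.7, sign=1),
            ModuleSpec(90, 0.6, sign=1),
            ModuleSpec(70, 0.5, sign=-1),
        ),
        repression_spec=(
            RepressionSpec(mirna_module=0, mrna_module=0, gamma=0.6, n_pairs=25),
            RepressionSpec(mirna_module=1, mrna_module=1, gamma=0.6, n_pairs=20),
        ),
        eqtl_spec=tuple(EqtlSpec() for _ in range(8)),
        gwas_spec=GwasSpec(),
        n_variants=600,
        decoy_rate=0.3,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def simulate_cohort(cfg: SimConfig):
    """Run every generator stage; returns a dict of all artefacts plus truth."""
    mrna, mirna, pheno, truth = simulate_expression(cfg)
    geno, vm, mrna, truth = simulate_genotypes(cfg, truth, mrna)
    gwas_geno, gwas_pheno = simulate_gwas_cohort(cfg, vm, truth)
    markers, genesets, p2g, predictions = simulate_annotations(cfg, truth)
    return {
        "mrna": mrna, "mirna": mirna, "pheno": pheno, "truth": truth,
        "geno": geno, "variant_map": vm, "gen_probs": genotype_probabilities(cfg, geno),
        "gwas_geno": gwas_geno, "gwas_pheno": gwas_pheno,
        "markers": markers, "genesets": genesets,
        "probe2gene": p2g, "predictions": predictions,
    }


def write_cohort(cohort: dict, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_expression(cohort["mrna"], out / "mrna_expression.tsv")
    io.write_expression(cohort["mirna"], out / "mirna_expression.tsv")
    io.write_phenotypes(cohort["pheno"], out / "phenotypes.tsv")
    io.write_dosages(cohort["geno"], out / "dosages.tsv")
    io.write_variant_map(cohort["variant_map"], out / "variant_map.tsv")
    io.write_gen(cohort["variant_map"], cohort["gen_probs"], out / "genotypes.gen")
    io.write_dosages(cohort["gwas_geno"], out / "gwas_dosages.tsv")
    io.write_phenotypes(cohort["gwas_pheno"], out / "gwas_phenotypes.tsv")
    io.write_gmt(cohort["markers"], out / "cell_markers.gmt")
    io.write_gmt(cohort["genesets"], out / "genesets.gmt")
    io.write_table(cohort["probe2gene"], out / "probe2gene.tsv")
    io.write_table(cohort["predictions"], out / "predictions.tsv")
    truth: SimTruth = cohort["truth"]
    io.write_table(truth.gene_coords, out / "gene_coords.tsv")
    io.write_metadata({
        "mrna_modules": truth.mrna_modules,
        "mirna_modules": truth.mirna_modules,
        "module_loading": truth.module_loading,
        "module_confounder": truth.module_confounder,
        "mrna_hubs": truth.mrna_hubs,
        "mirna_hubs": truth.mirna_hubs,
        "repression_pairs": truth.repression_pairs,
        "eqtls": truth.eqtls,
        "gwas_causal": truth.gwas_causal,
    }, out / "truth.json")
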