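"""End-to-end orchestration of the co-expression/eQTL workflow.

Stages run in order: differential-expression preprocessing, signed network
construction for each platform, hub selection and enrichment, miRNA:mRNA
integration, and genetics (cis-eQTL scan plus GWAS set-based enrichment).
Every stage writes its tables plus a JSON metadata record; on synthetic
input with planted truth available a recovery report (module ARI, hub and
repression-pair recall/precision, eQTL recall, set-test decisions) is
emitted.  Re-running a completed stage with unchanged inputs and
parameters is a checksum-based no-op.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from coexqtl import coexnet, enrich, genetics, io, mirnet, preprocess, synthdata

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "coexqtl_out"
    seed: int = 0
    synthetic: bool = True
    input_dir: str | None = None          # cohort files when synthetic=False
    de_alpha: float = 0.05
    pca_k_sd: float = 4.0
    covariate_candidates: tuple[str, ...] = ("smoking",)
    beta_mrna: int | str = "auto"
    beta_mirna: int | str = "auto"
    r2_target: float = 0.80
    min_module_size_mrna: int = 35
    min_module_size_mirna: int = 5
    cut_height: float | None = None
    me_merge_cor: float = 0.80
    min_kme: float = 0.2
    hub_quartile: float = 0.75
    gsea_nperm: int = 1000
    gsea_size_bounds: tuple[int, int] = (15, 500)
    pair_fdr: float = 0.10
    eqtl_window: float = 1e6
    eqtl_fdr: float = 0.10
    maf_min: float = 0.24
    ld_r2: float = 0.8
    hard_call_threshold: float = 0.98
    trait_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.input_dir is not None and not Path(cfg.input_dir).exists():
            raise FileNotFoundError(cfg.input_dir)
        return cfg


def _hash_inputs(*objects) -> str:
    h = hashlib.sha256()
    for obj in objects:
        if isinstance(obj, pd.DataFrame):
            h.update(pd.util.hash_pandas_object(obj, index=True).to_numpy().tobytes())
        elif isinstance(obj, pd.Series):
            h.update(pd.util.hash_pandas_object(obj, index=True).to_numpy().tobytes())
        elif isinstance(obj, np.ndarray):
            h.update(np.ascontiguousarray(obj).tobytes())
        else:
            h.update(repr(obj).encode())
    return h.hexdigest()


class _Stage:
    """Checksum-gated stage runner: skip when inputs+params are unchanged."""

    def __init__(self, out: Path, name: str):
        self.dir = out / name
        self.meta_path = self.dir / "stage_meta.json"
        self.name = name

    def fresh(self, checksum: str) -> bool:
        if self.meta_path.exists():
            meta = io.read_metadata(self.meta_path)
            if meta.get("checksum") == checksum:
                outputs = meta.get("outputs", [])
                if all((self.dir / f).exists() for f in outputs):
                    log.info("stage %s up to date; skipping", self.name)
                    return False
        self.dir.mkdir(parents=True, exist_ok=True)
        return True

    def finish(self, checksum: str, params: dict) -> None:
        outputs = sorted(p.name for p in self.dir.iterdir() if p.name != "stage_meta.json")
        io.write_metadata({"stage": self.name, "checksum": checksum,
                           "params": params, "outputs": outputs}, self.meta_path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns a report bundle dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg)}

    # ----- inputs -----------------------------------------------------------
    if cfg.synthetic:
        cohort = synthdata.simulate_cohort(synthdata.default_config(seed=cfg.seed))
        synthdata.write_cohort(cohort, out / "cohort")
        truth = cohort["truth"]
    else:
        d = Path(cfg.input_dir)
        cohort = {
            "mrna": io.read_expression(d / "mrna_expression.tsv"),
            "mirna": io.read_expression(d / "mirna_expression.tsv"),
            "pheno": io.read_phenotypes(d / "phenotypes.tsv"),
            "geno": io.read_dosages(d / "dosages.tsv"),
            "variant_map": io.read_variant_map(d / "variant_map.tsv"),
            "markers": io.read_gmt(d / "cell_markers.gmt"),
            "genesets": io.read_gmt(d / "genesets.gmt"),
            "probe2gene": io.read_table(d / "probe2gene.tsv"),
            "predictions": io.read_table(d / "predictions.tsv"),
        }
        gc = d / "gene_coords.tsv"
        cohort["gene_coords"] = io.read_table(gc) if gc.exists() else None
        gen = d / "genotypes.gen"
        if gen.exists():
            _, cohort["gen_probs"] = io.read_gen(gen)
        for extra in ("gwas_dosages", "gwas_phenotypes"):
            p = d / f"{extra}.tsv"
            if p.exists():
                cohort[extra.replace("dosages", "geno").replace("phenotypes", "pheno")
                       ] = (io.read_dosages(p) if "dosages" in extra else io.read_phenotypes(p))
        truth = None
    mrna, mirna, pheno = cohort["mrna"], cohort["mirna"], cohort["pheno"]
    gene_coords = truth.gene_coords if truth is not None else cohort.get("gene_coords")

    # ----- preprocess -------------------------------------------------------
    stage = _Stage(out, "preprocess")
    checksum = _hash_inputs(mrna, mirna, pheno, cfg.de_alpha, cfg.pca_k_sd,
                            cfg.covariate_candidates)
    outliers = preprocess.flag_pca_outliers(mrna, k_sd=cfg.pca_k_sd)
    keep_samples = [s for s in mrna.columns if s not in outliers]
    mrna = mrna[keep_samples]
    mirna = mirna[[s for s in mirna.columns if s in keep_samples]]
    pheno = pheno.loc[keep_samples]
    covars = preprocess.screen_covariates(mrna, pheno,
                                          list(cfg.covariate_candidates), cfg.de_alpha)
    de_mrna, mrna_kept = preprocess.differential_expression(
        mrna, pheno, covars, alpha=cfg.de_alpha)
    de_mirna, mirna_kept = preprocess.differential_expression(
        mirna, pheno, covars, alpha=cfg.de_alpha)
    if stage.fresh(checksum):
        io.write_table(de_mrna.table, stage.dir / "de_mrna.tsv")
        io.write_table(de_mirna.table, stage.dir / "de_mirna.tsv")
        io.write_metadata({"outlier_samples": outliers, "covariates": covars,
                           "robust_model": "huber IRLS t=1.345 (reconstruction; "
                           "stepwise screen approximated by binomial excess test)"},
                          stage.dir / "preprocess_meta.json")
        stage.finish(checksum, {"alpha": cfg.de_alpha})
    report["preprocess"] = {"outliers": outliers, "covariates": covars,
                            "n_de_mrna": int(de_mrna.table.kept.sum()),
                            "n_de_mirna": int(de_mirna.table.kept.sum())}

    # ----- networks ---------------------------------------------------------
    nets = {}
    for kind, expr, beta_cfg, min_size in (
            ("mrna", mrna_kept, cfg.beta_mrna, cfg.min_module_size_mrna),
            ("mirna", mirna_kept, cfg.beta_mirna, cfg.min_module_size_mirna)):
        stage = _Stage(out, f"network_{kind}")
        checksum = _hash_inputs(expr, beta_cfg, min_size, cfg.cut_height,
                                cfg.me_merge_cor, cfg.r2_target)
        nets[kind] = _run_network(expr, pheno, beta_cfg, min_size, cfg)
        if stage.fresh(checksum):
            net = nets[kind]
            io.write_table(net["modules"].labels.rename_axis("transcript_id").reset_index(),
                           stage.dir / "modules.tsv")
            io.write_expression(net["me"].T, stage.dir / "eigengenes.tsv")
            io.write_table(net["trait"].correlations.round(4).rename_axis("module").reset_index(),
                           stage.dir / "module_trait_cor.tsv")
            io.write_table(net["stats"].reset_index(), stage.dir / "gene_stats.tsv")
            np.savetxt(stage.dir / "dendrogram_merges.tsv",
                       net["modules"].linkage_matrix, delimiter="\t",
                       header="left\tright\theight\tcount", comments="")
            io.write_metadata({"beta": net["beta"], "fallback": net["fallback"],
                               "cut_height": net["modules"].cut_height,
                               "significant_modules": net["trait"].significant,
                               "confounded_modules": net["trait"].confounded},
                              stage.dir / "network_meta.json")
            stage.finish(checksum, {"beta": net["beta"], "min_module_size": min_size})
        report[f"network_{kind}"] = {
            "beta": nets[kind]["beta"],
            "n_modules": len(nets[kind]["modules"].modules),
            "significant": nets[kind]["trait"].significant,
            "confounded": nets[kind]["trait"].confounded,
        }

    # ----- enrichment -------------------------------------------------------
    stage = _Stage(out, "enrich")
    p2g = cohort["probe2gene"]
    mnet = nets["mrna"]
    sig_mrna = mnet["trait"].significant
    checksum = _hash_inputs(mnet["stats"], tuple(sig_mrna), cfg.hub_quartile,
                            cfg.gsea_nperm, p2g)
    hubs_mrna = (enrich.select_hubs(mnet["stats"], sig_mrna, cfg.hub_quartile)
                 if sig_mrna else pd.DataFrame())
    sig_mirna = nets["mirna"]["trait"].significant
    hubs_mirna = (enrich.select_hubs(nets["mirna"]["stats"], sig_mirna, cfg.hub_quartile)
                  if sig_mirna else pd.DataFrame())
    hub_genes = (enrich.collapse_probes(hubs_mrna[hubs_mrna.hub], p2g)
                 if len(hubs_mrna) else pd.DataFrame())
    module_genes = {}
    background = sorted(set(p2g.set_index("probe_id").gene_symbol
                            .reindex(mnet["modules"].labels.index).dropna()))
    for mod in sig_mrna:
        members = mnet["modules"].members(mod)
        module_genes[mod] = sorted(set(p2g.set_index("probe_id").gene_symbol
                                       .reindex(members).dropna()))
    markers = enrich.marker_enrichment(module_genes, cohort["markers"], background,
                                       bonferroni_m=len(sig_mrna) or 1) \
        if module_genes else pd.DataFrame()
    gsea_results: dict[str, enrich.GseaResult] = {}
    for mod in sig_mrna:
        kme = _kme(mrna_kept, mnet["me"][mod])
        ranked = enrich.collapse_probes(kme.to_frame("MM"), p2g).set_index("gene_symbol").MM
        gsea_results[mod] = enrich.gsea_preranked(
            ranked, cohort["genesets"], nperm=cfg.gsea_nperm,
            size_bounds=cfg.gsea_size_bounds, seed=cfg.seed)
    le = enrich.leading_edge_partition(gsea_results) if gsea_results else pd.DataFrame()
    if stage.fresh(checksum):
        if len(hubs_mrna):
            io.write_table(hubs_mrna.reset_index(), stage.dir / "hubs_mrna.tsv")
        if len(hubs_mirna):
            io.write_table(hubs_mirna.reset_index(), stage.dir / "hubs_mirna.tsv")
        if len(hub_genes):
            io.write_table(hub_genes.reset_index(), stage.dir / "hub_genes.tsv")
        if len(markers):
            io.write_table(markers, stage.dir / "marker_enrichment.tsv")
        for mod, res in gsea_results.items():
            io.write_table(res.table, stage.dir / f"gsea_{mod}.tsv")
        if len(le):
            io.write_table(le, stage.dir / "leading_edge_partition.tsv")
        stage.finish(checksum, {"quartile": cfg.hub_quartile, "nperm": cfg.gsea_nperm})
    report["enrich"] = {
        "n_hub_transcripts_mrna": int(hubs_mrna.hub.sum()) if len(hubs_mrna) else 0,
        "n_hub_genes_mrna": len(hub_genes),
        "n_hub_mirna": int(hubs_mirna.hub.sum()) if len(hubs_mirna) else 0,
        "n_marker_hits": int(markers.significant.sum()) if len(markers) else 0,
        "n_gsea_significant": int(sum(r.table.significant.sum()
                                      for r in gsea_results.values())),
    }

    # ----- miRNA:mRNA integration ------------------------------------------
    stage = _Stage(out, "integrate")
    pairs = targeting = coop = None
    sign_report = None
    if len(hubs_mrna) and len(hubs_mirna) and hubs_mirna.hub.any():
        me_a = mnet["me"][sig_mrna]
        me_b = nets["mirna"]["me"][sig_mirna]
        me_cor, me_p = mirnet.correlate_eigengenes(me_a, me_b)
        hub_ids_mrna = hubs_mrna.index[hubs_mrna.hub]
        hub_ids_mirna = hubs_mirna.index[hubs_mirna.hub]
        pairs = mirnet.correlate_hub_pairs(mrna_kept.loc[hub_ids_mrna],
                                           mirna_kept.loc[hub_ids_mirna])
        sign_report = mirnet.sign_bias_test(pairs)
        neg = mirnet.filter_negative_pairs(pairs, fdr=cfg.pair_fdr)
        symbol_of = p2g.set_index("probe_id").gene_symbol
        neg = neg.assign(gene_symbol=symbol_of.reindex(neg.mrna_transcript).to_numpy())
        neg = neg.dropna(subset=["gene_symbol"])
        targeting, coop = mirnet.intersect_targeting(neg, cohort["predictions"])
        checksum = _hash_inputs(pairs, cfg.pair_fdr)
        if stage.fresh(checksum):
            io.write_table(me_cor.round(4).rename_axis("mrna_module").reset_index(),
                           stage.dir / "me_cross_correlation.tsv")
            io.write_table(pairs, stage.dir / "hub_pairs.tsv")
            io.write_table(neg, stage.dir / "negative_pairs_fdr.tsv")
            io.write_table(targeting, stage.dir / "targeting_pairs.tsv")
            io.write_table(coop, stage.dir / "cooperative_targeting.tsv")
            io.write_metadata({"n_pairs": len(pairs),
                               "positive": sign_report.n_positive,
                               "negative": sign_report.n_negative,
                               "chi2": sign_report.chi2, "p": sign_report.p,
                               "fdr_stratum": "negative"},
                              stage.dir / "sign_bias.json")
            stage.finish(checksum, {"fdr": cfg.pair_fdr})
        report["integrate"] = {
            "n_pairs": len(pairs),
            "prop_positive": sign_report.proportions[0],
            "sign_chi2_p": sign_report.p,
            "n_negative_fdr": len(neg),
            "n_targeting_pairs": len(targeting),
        }
    else:
        report["integrate"] = {"skipped": "no significant hubs on both platforms"}

    # ----- genetics ---------------------------------------------------------
    stage = _Stage(out, "genetics")
    report["genetics"] = {}
    scan = None
    settest_rows = []
    if len(hubs_mrna) and cohort.get("geno") is not None and gene_coords is not None:
        geno, vm = cohort["geno"], cohort["variant_map"]
        if cohort.get("gen_probs") is not None:
            geno, vm = genetics.hard_call_genotypes(
                cohort["gen_probs"], vm, list(geno.columns),
                threshold=cfg.hard_call_threshold)
        kept_variants = genetics.prune_variants(geno, ld_r2=cfg.ld_r2,
                                                maf_min=cfg.maf_min)
        geno_qc = geno.loc[kept_variants]
        covariates = pheno[["case", "smoking"]].astype(float)
        hub_expr = mrna_kept.loc[hubs_mrna.index[hubs_mrna.hub]]
        gm = gene_coords.rename(columns={"transcript_id": "transcript_id"})
        scan = genetics.cis_eqtl_scan(hub_expr, geno_qc, vm, gm,
                                      covariates=covariates,
                                      window=cfg.eqtl_window, fdr=cfg.eqtl_fdr)
        sig_eqtls = scan.significant
        report["genetics"].update({
            "n_variants_after_qc": len(kept_variants),
            "n_cis_tests": scan.n_tests,
            "n_significant_eqtls": len(sig_eqtls),
            "n_egenes": int(sig_eqtls.transcript_id.nunique()),
        })
        if (len(sig_eqtls) and cohort.get("gwas_geno") is not None
                and cohort.get("gwas_pheno") is not None):
            gset = cohort["gwas_geno"].loc[
                sorted(set(sig_eqtls.variant_id) & set(cohort["gwas_geno"].index))]
            gp = cohort["gwas_pheno"]
            gcov = gp[["age", "sex"]].astype(float)
            for pname in ("AD_DX", "AD_SX", "MAX24"):
                res = genetics.kernel_set_test(gset, gp[pname], gcov,
                                               set_name="mrna_eqtls")
                settest_rows.append(res)
            global_p, adj = genetics.simes_correct([r.p for r in settest_rows])
            for r, a in zip(settest_rows, adj):
                r.adj_p = float(a)
            report["genetics"]["settest"] = {
                r.phenotype: {"Q": r.Q, "p": r.p, "simes_adj_p": r.adj_p}
                for r in settest_rows}
            report["genetics"]["settest_global_simes_p"] = global_p
        checksum = _hash_inputs(hub_expr, geno_qc, cfg.eqtl_window, cfg.eqtl_fdr)
        if stage.fresh(checksum):
            io.write_table(scan.table, stage.dir / "eqtls.tsv")
            if settest_rows:
                io.write_table(pd.DataFrame([asdict(r) for r in settest_rows]),
                               stage.dir / "settest.tsv")
            stage.finish(checksum, {"window": cfg.eqtl_window, "fdr": cfg.eqtl_fdr,
                                    "maf_min": cfg.maf_min, "ld_r2": cfg.ld_r2})

    # ----- recovery report --------------------------------------------------
    if truth is not None:
        report["recovery"] = recovery_report(
            truth, mnet, nets["mirna"], hubs_mrna, hubs_mirna,
            targeting, scan, settest_rows, cohort)
        io.write_metadata(report["recovery"], out / "recovery_report.json")
    io.write_metadata(report, out / "run_metadata.json")
    return report


def _kme(expr: pd.DataFrame, me: pd.Series) -> pd.Series:
    """Module membership of every transcript against one eigengene."""
    x = expr.to_numpy(float)
    xs = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xs ** 2).sum(axis=1))
    norm[norm == 0] = 1.0
    m = me.to_numpy(float)
    ms = m - m.mean()
    r = xs @ ms / (norm * np.sqrt((ms ** 2).sum()))
    return pd.Series(r, index=expr.index, name="kME")


def _run_network(expr: pd.DataFrame, pheno: pd.DataFrame, beta_cfg, min_size: int,
                 cfg: PipelineConfig) -> dict:
    if isinstance(beta_cfg, str) and beta_cfg == "auto":
        beta, fits, fallback = coexnet.pick_soft_threshold(expr, r2_target=cfg.r2_target)
    else:
        beta, fits, fallback = int(beta_cfg), None, False
    params = coexnet.NetworkParams(beta=beta, min_module_size=min_size,
                                   cut_height=cfg.cut_height,
                                   me_merge_cor=cfg.me_merge_cor)
    adj = coexnet.signed_adjacency(expr, beta)
    tom = coexnet.topological_overlap(adj)
    modules = coexnet.detect_modules(tom, params)
    modules = coexnet.merge_close_modules(expr, modules, cfg.me_merge_cor)
    modules = coexnet.assign_close_transcripts(expr, modules, min_kme=cfg.min_kme)
    me = coexnet.module_eigengenes(expr, modules)
    traits = [t for t in ("case", "ph", "pmi", "age", "rin", "smoking")
              if t in pheno.columns]
    trait_report = coexnet.module_trait_analysis(me, pheno, traits, cfg.trait_alpha) \
        if len(me.columns) else coexnet.ModuleTraitReport(
            pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
    stats_df = coexnet.membership_significance(expr, me, modules, pheno["case"]) \
        if len(me.columns) else pd.DataFrame()
    return {"beta": beta, "fallback": fallback, "fits": fits, "modules": modules,
            "me": me, "trait": trait_report, "stats": stats_df}


def recovery_report(truth: synthdata.SimTruth, mnet: dict, minet: dict,
                    hubs_mrna: pd.DataFrame, hubs_mirna: pd.DataFrame,
                    targeting: pd.DataFrame | None, scan, settest_rows,
                    cohort: dict) -> dict:
    """Compare pipeline output against planted truth."""
    rep: dict = {}
    for kind, net in (("mrna", mnet), ("mirna", minet)):
        detected = net["modules"].labels
        truth_map = truth.module_map(kind).reindex(detected.index).fillna("none")
        rep[f"module_ari_{kind}"] = float(
            adjusted_rand_score(truth_map.to_numpy(), detected.to_numpy()))
    sel = set(hubs_mrna.index[hubs_mrna.hub]) if len(hubs_mrna) else set()
    universe = set(mnet["modules"].labels.index)
    # hubs are defined within disease-significant modules, so confounded
    # planted modules are excluded from the recall denominator by design
    disease_modules = {m for m in set(truth.mrna_modules.values())
                       if m not in truth.module_confounder}
    planted = {t for t in truth.mrna_hubs
               if truth.mrna_modules[t] in disease_modules} & universe
    if planted and sel:
        rep["hub_recall"] = len(sel & planted) / len(planted)
        rep["hub_precision"] = len(sel & planted) / len(sel)
    planted_pairs = {(mi, truth.probe2gene.get(mr, mr))
                     for mi, mr, _ in truth.repression_pairs}
    if targeting is not None and planted_pairs:
        called = set(zip(targeting.mirna_id, targeting.gene_symbol))
        rep["repression_recall"] = len(called & planted_pairs) / len(planted_pairs)
        rep["repression_precision"] = (len(called & planted_pairs) / len(called)
                                       if called else 0.0)
    if scan is not None and truth.eqtls:
        called_eqtls = set(zip(scan.significant.variant_id, scan.significant.transcript_id))
        planted_eqtls = {(v, g) for v, g, _ in truth.eqtls}
        rep["eqtl_recall"] = len(called_eqtls & planted_eqtls) / len(planted_eqtls)
    if settest_rows:
        rep["settest"] = {r.phenotype: {"p": r.p, "simes_adj_p": r.adj_p}
                          for r in settest_rows}
        rep["settest_ad_dx_significant"] = bool(
            next((r.adj_p <= 0.05 for r in settest_rows if r.phenotype == "AD_DX"), False))
    return rep


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    cfg = PipelineConfig.from_yaml(path) if path else PipelineConfig()
    for k, v in overrides.items():
        if v is not None:
            setattr(cfg, k, v)
    return cfg
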