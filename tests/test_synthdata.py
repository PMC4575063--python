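"""Generator contracts: determinism, planted structure, and file round-trips."""

import numpy as np
import pandas as pd
import pytest

from coexqtl import io, synthdata
from coexqtl.synthdata import (EqtlSpec, GwasSpec, ModuleSpec, RepressionSpec,
                               SimConfig, default_config)


class TestConfigValidation:
    def test_module_sizes_exceeding_transcripts_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            SimConfig(n_mrna=100, mrna_modules=(ModuleSpec(80, 0.5), ModuleSpec(30, 0.5)))

    @pytest.mark.parametrize("bad", [-0.1, 1.2])
    def test_loading_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            ModuleSpec(10, bad)

    @pytest.mark.parametrize("maf", [0.0, 0.6, -0.2])
    def test_bad_maf_rejected(self, maf):
        with pytest.raises(ValueError):
            EqtlSpec(maf=maf)


class TestSimulateExpression:
    def test_zero_modules_gives_pure_noise_cohort(self):
        cfg = SimConfig(n_samples=20, n_mrna=50, n_mirna=10, eqtl_spec=(), seed=3)
        mrna, mirna, pheno, truth = synthdata.simulate_expression(cfg)
        assert mrna.shape == (50, 20) and mirna.shape == (10, 20)
        assert truth.mrna_modules == {} and truth.mirna_modules == {}
        assert truth.mrna_hubs == []

    def test_same_seed_reproduces_everything(self):
        cfg = default_config(seed=7, n_mrna=400, n_variants=100,
                             mrna_modules=(ModuleSpec(100, 0.7),),
                             mirna_modules=(ModuleSpec(20, 0.6),),
                             repression_spec=(RepressionSpec(0, 0, 0.6, 5),),
                             eqtl_spec=(EqtlSpec(),),
                             gwas_spec=GwasSpec(n_subjects=120))
        a = synthdata.simulate_cohort(cfg)
        b = synthdata.simulate_cohort(cfg)
        for key in ("mrna", "mirna", "pheno", "geno", "gwas_geno", "gwas_pheno",
                    "probe2gene", "predictions"):
            pd.testing.assert_frame_equal(a[key], b[key])
        assert np.array_equal(a["gen_probs"], b["gen_probs"])
        assert a["truth"].repression_pairs == b["truth"].repression_pairs
        assert a["truth"].eqtls == b["truth"].eqtls

    def test_noise_free_limit_is_perfectly_correlated_with_class(self):
        cfg = SimConfig(n_samples=30, n_mrna=40, n_mirna=5,
                        mrna_modules=(ModuleSpec(20, 1.0),),
                        loading_range=(1.0, 1.0), seed=5)
        mrna, _, pheno, truth = synthdata.simulate_expression(cfg)
        members = [t for t, m in truth.mrna_modules.items()]
        x = mrna.loc[members].to_numpy()
        assert np.allclose(x - x[0], 0.0)   # all module genes identical
        r = np.corrcoef(x[0], pheno["case"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_within_module_correlation_converges_to_loading_product(self):
        cfg = SimConfig(n_samples=8000, n_mrna=40, n_mirna=5,
                        mrna_modules=(ModuleSpec(30, 0.5),), seed=11)
        mrna, _, _, truth = synthdata.simulate_expression(cfg)
        members = list(truth.mrna_modules)[:10]
        x = mrna.loc[members].to_numpy()
        r = np.corrcoef(x)
        for i in range(5):
            for j in range(i + 1, 5):
                expect = truth.gene_loading[members[i]] * truth.gene_loading[members[j]]
                assert r[i, j] == pytest.approx(expect, abs=0.05)

    def test_repression_induces_negative_correlation(self, small_cohort):
        cfg, cohort = small_cohort
        mrna, mirna, truth = cohort["mrna"], cohort["mirna"], cohort["truth"]
        rs = [np.corrcoef(mirna.loc[mi], mrna.loc[mr])[0, 1]
              for mi, mr, _ in truth.repression_pairs]
        assert np.mean(rs) < -0.3
        assert sum(r < 0 for r in rs) >= 0.9 * len(rs)


class TestSimulateGenotypes:
    def test_mean_dosage_matches_binomial_expectation(self):
        cfg = SimConfig(n_samples=800, n_mrna=30, n_mirna=5,
                        mrna_modules=(ModuleSpec(20, 0.6),),
                        eqtl_spec=(EqtlSpec(maf=0.5, beta=0.0),),
                        n_variants=1, seed=2)
        mrna, _, _, truth = synthdata.simulate_expression(cfg)
        geno, vm, _, _ = synthdata.simulate_genotypes(cfg, truth, mrna)
        mean = geno.iloc[0].mean()
        se = np.sqrt(2 * 0.5 * 0.5 / 800)
        assert abs(mean - 1.0) <= 3 * se

    def test_planted_variants_are_cis_and_decoys_are_not(self, small_cohort):
        cfg, cohort = small_cohort
        truth, vm = cohort["truth"], cohort["variant_map"]
        coords = truth.gene_coords.set_index("transcript_id")
        pos = vm.set_index("variant_id").pos
        targets = {g: coords.loc[g] for _, g, _ in truth.eqtls}
        for vid, gene, _ in truth.eqtls:
            row = targets[gene]
            dist = min(abs(pos[vid] - row.start), abs(pos[vid] - row.end))
            assert dist <= 1_000_000 or row.start <= pos[vid] <= row.end
        decoys = [v for v in vm.variant_id if v.startswith("var_decoy")]
        target_starts = np.array([coords.loc[g].start for _, g, _ in truth.eqtls])
        for vid in decoys[:50]:
            assert np.abs(target_starts - pos[vid]).min() > 1_000_000

    def test_eqtl_effect_added_to_target_gene(self, small_cohort):
        cfg, cohort = small_cohort
        truth = cohort["truth"]
        geno, mrna = cohort["geno"], cohort["mrna"]
        vid, gene, beta = truth.eqtls[0]
        r = np.corrcoef(geno.loc[vid], mrna.loc[gene])[0, 1]
        assert r > 0.3   # beta=1 dosage effect visible at n=36

    def test_unknown_target_gene_rejected(self):
        cfg = SimConfig(n_mrna=20, n_mirna=5, eqtl_spec=(EqtlSpec(gene="nope"),))
        mrna, _, _, truth = synthdata.simulate_expression(cfg)
        with pytest.raises(ValueError, match="nope"):
            synthdata.simulate_genotypes(cfg, truth, mrna)


class TestGwasCohort:
    def test_null_effects_give_half_cases(self):
        cfg = SimConfig(n_mrna=20, n_mirna=5, n_variants=30,
                        gwas_spec=GwasSpec(n_subjects=2000, beta0=0.0,
                                           causal_from_eqtl=False), seed=4)
        vm = pd.DataFrame({"variant_id": [f"v{i}" for i in range(30)],
                           "chrom": "chr1", "pos": np.arange(1, 31) * 1000,
                           "ref": "A", "alt": "G", "maf": 0.3})
        geno, pheno = synthdata.simulate_gwas_cohort(cfg, vm)
        se = np.sqrt(0.25 / 2000)
        assert abs(pheno.AD_DX.mean() - 0.5) <= 3 * se
        assert geno.shape == (30, 2000)
        assert set(np.unique(geno.to_numpy())) <= {0.0, 1.0, 2.0}

    def test_risk_allele_enriched_in_cases(self):
        vm = pd.DataFrame({"variant_id": ["v0"], "chrom": "chr1", "pos": [1000],
                           "ref": "A", "alt": "G", "maf": [0.3]})
        diffs = []
        for seed in range(100):
            cfg = SimConfig(n_mrna=5, n_mirna=2, seed=seed,
                            gwas_spec=GwasSpec(n_subjects=200, causal_from_eqtl=False,
                                               variant_effects=(("v0", 0.5),)))
            geno, pheno = synthdata.simulate_gwas_cohort(cfg, vm)
            d = geno.loc["v0"].to_numpy()
            case = pheno.AD_DX.to_numpy().astype(bool)
            if case.any() and (~case).any():
                diffs.append(d[case].mean() - d[~case].mean())
        assert np.mean(diffs) > 0

    def test_tiny_cohort_refused(self):
        cfg = SimConfig(n_mrna=5, n_mirna=2, gwas_spec=GwasSpec(n_subjects=10))
        vm = pd.DataFrame({"variant_id": ["v0"], "chrom": "chr1", "pos": [1],
                           "ref": "A", "alt": "G", "maf": [0.3]})
        with pytest.raises(ValueError, match="50"):
            synthdata.simulate_gwas_cohort(cfg, vm)


class TestAnnotations:
    def test_zero_decoys_reproduce_planted_pairs_exactly(self):
        cfg = default_config(seed=9, n_mrna=400, n_mirna=60,
                             mrna_modules=(ModuleSpec(120, 0.7),),
                             mirna_modules=(ModuleSpec(30, 0.7),),
                             repression_spec=(RepressionSpec(0, 0, 0.6, 8),),
                             eqtl_spec=(), decoy_rate=0.0)
        mrna, mirna, pheno, truth = synthdata.simulate_expression(cfg)
        _, _, p2g, pred = synthdata.simulate_annotations(cfg, truth)
        planted = {(mi, truth.probe2gene[mr]) for mi, mr, _ in truth.repression_pairs}
        assert set(zip(pred.mirna_id, pred.gene_symbol)) == planted

    def test_full_overlap_marker_set_is_subset_of_module(self):
        cfg = default_config(seed=9, n_mrna=400, n_mirna=60,
                             mrna_modules=(ModuleSpec(200, 0.7),),
                             mirna_modules=(ModuleSpec(30, 0.7),),
                             repression_spec=(), eqtl_spec=(),
                             marker_overlap=1.0, marker_size=40)
        mrna, _, _, truth = synthdata.simulate_expression(cfg)
        markers, _, p2g, _ = synthdata.simulate_annotations(cfg, truth)
        module_syms = {truth.probe2gene[t] for t in truth.mrna_modules}
        (name, genes), = markers.items()
        assert set(genes) <= module_syms

    def test_gmt_round_trip(self, tmp_path):
        sets = {"alpha": ["G1", "G2", "G3"], "beta": ["G9"]}
        io.write_gmt(sets, tmp_path / "x.gmt", descriptions={"alpha": "d"})
        assert io.read_gmt(tmp_path / "x.gmt") == sets

    def test_truth_identifiers_resolve_in_emitted_tables(self, small_cohort):
        cfg, cohort = small_cohort
        truth = cohort["truth"]
        assert set(truth.mrna_hubs) <= set(cohort["mrna"].index)
        assert set(truth.mirna_hubs) <= set(cohort["mirna"].index)
        variant_ids = set(cohort["variant_map"].variant_id)
        for vid, gene, _ in truth.eqtls:
            assert vid in variant_ids and gene in cohort["mrna"].index
        assert set(truth.gwas_causal) <= set(cohort["gwas_geno"].index)
        probe_ids = set(cohort["probe2gene"].probe_id)
        for mi, mr, _ in truth.repression_pairs:
            assert mi in cohort["mirna"].index and mr in probe_ids


class TestCohortFiles:
    def test_round_trip_through_disk(self, small_cohort, tmp_path):
        cfg, cohort = small_cohort
        synthdata.write_cohort(cohort, tmp_path)
        mrna = io.read_expression(tmp_path / "mrna_expression.tsv")
        pd.testing.assert_frame_equal(
            mrna, cohort["mrna"].rename_axis("transcript_id").rename_axis(None, axis=1))
        vm, probs = io.read_gen(tmp_path / "genotypes.gen")
        assert probs.shape == cohort["gen_probs"].shape
        assert list(vm.variant_id) == list(cohort["variant_map"].variant_id)
        truth_meta = io.read_metadata(tmp_path / "truth.json")
        assert len(truth_meta["eqtls"]) == len(cohort["truth"].eqtls)
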