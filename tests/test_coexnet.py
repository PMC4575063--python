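"""Signed network construction, TOM, module detection and module statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexqtl import coexnet, synthdata
from coexqtl.coexnet import NetworkParams
from tests.conftest import make_expression


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    k = a.shape[0]
    w = np.zeros_like(a)
    for i in range(k):
        for j in range(k):
            if i == j:
                w[i, j] = 1.0
                continue
            l = sum(a[i, u] * a[u, j] for u in range(k) if u != i and u != j)
            ki = sum(a[i, u] for u in range(k) if u != i)
            kj = sum(a[j, u] for u in range(k) if u != j)
            w[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return w


def random_adjacency(rng: np.random.Generator, k: int) -> pd.DataFrame:
    a = rng.random((k, k))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a)


class TestSignedAdjacency:
    def test_perfectly_correlated_pair_has_unit_adjacency(self):
        e = make_expression(np.vstack([np.arange(10.0), np.arange(10.0) * 2 + 1]))
        for beta in (1, 6, 14):
            a = coexnet.signed_adjacency(e, beta)
            assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair_is_driven_to_zero(self):
        e = make_expression(np.vstack([np.arange(10.0), -np.arange(10.0)]))
        a = coexnet.signed_adjacency(e, 6)
        assert a.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_pair_closed_form(self, rng):
        # construct exactly orthogonal vectors so r = 0
        x = rng.standard_normal(50)
        x -= x.mean()
        y = rng.standard_normal(50)
        y -= y.mean()
        y -= (x @ y) / (x @ x) * x
        a = coexnet.signed_adjacency(make_expression(np.vstack([x, y])), 14)
        assert a.iloc[0, 1] == pytest.approx(0.5 ** 14, rel=1e-9)

    def test_zero_variance_transcript_named_in_error(self):
        e = make_expression(np.vstack([np.ones(8), np.arange(8.0)]))
        with pytest.raises(ValueError, match="g0"):
            coexnet.signed_adjacency(e, 6)

    def test_adjacency_strictly_decreases_with_beta(self, rng):
        e = make_expression(rng.standard_normal((20, 30)))
        a6 = coexnet.signed_adjacency(e, 6).to_numpy()
        a14 = coexnet.signed_adjacency(e, 14).to_numpy()
        off = ~np.eye(20, dtype=bool)
        strict = (a6 > 0) & (a6 < 1) & off
        assert np.all(a14[strict] < a6[strict])

    def test_matrix_invariants(self, rng):
        a = coexnet.signed_adjacency(make_expression(rng.standard_normal((15, 12))), 5)
        v = a.to_numpy()
        assert np.allclose(v, v.T)
        assert v.min() >= 0 and v.max() <= 1
        assert np.allclose(np.diag(v), 1.0)


class TestSoftThreshold:
    def test_planted_structure_reaches_scale_free_target(self, small_cohort):
        _, cohort = small_cohort
        beta, fits, fallback = coexnet.pick_soft_threshold(cohort["mrna"])
        assert not fallback
        assert fits.loc[fits.beta == beta, "signed_r2"].iloc[0] > 0.80

    def test_pure_noise_raises_fallback_flag(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            e = make_expression(r.standard_normal((200, 36)))
            _, _, fallback = coexnet.pick_soft_threshold(e, betas=tuple(range(1, 13)))
            hits += fallback
        assert hits == 20

    def test_paper_defaults_recorded_in_config(self):
        # the published powers and sizes are the config defaults for real data
        from coexqtl.pipeline import PipelineConfig
        cfg = PipelineConfig()
        assert cfg.min_module_size_mrna == 35 and cfg.min_module_size_mirna == 5
        assert cfg.r2_target == 0.80 and cfg.me_merge_cor == 0.80


class TestTopologicalOverlap:
    def test_isolated_dyad_has_unit_overlap(self):
        a = pd.DataFrame(np.eye(4))
        a.iloc[0, 1] = a.iloc[1, 0] = 1.0
        w = coexnet.topological_overlap(a)
        assert w.iloc[0, 1] == pytest.approx(1.0)

    def test_empty_graph_has_zero_overlap(self):
        w = coexnet.topological_overlap(pd.DataFrame(np.eye(6)))
        off = w.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.all(off == 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=10, max_value=30))
    def test_matches_brute_force_oracle(self, seed, k):
        adj = random_adjacency(np.random.default_rng(seed), k)
        w = coexnet.topological_overlap(adj).to_numpy()
        assert np.abs(w - brute_force_tom(adj.to_numpy())).max() < 1e-12


class TestModuleDetection:
    @staticmethod
    def blocks(rng, sizes, n=12, noise=0.01):
        rows = []
        for size in sizes:
            e = rng.standard_normal(n)
            rows.append(np.tile(e, (size, 1)) + noise * rng.standard_normal((size, n)))
        return make_expression(np.vstack(rows))

    def test_two_separated_blocks_recovered_exactly(self, rng):
        e = self.blocks(rng, (20, 20))
        tom = coexnet.topological_overlap(coexnet.signed_adjacency(e, 6))
        mods = coexnet.detect_modules(tom, NetworkParams(beta=6, min_module_size=10))
        labels = mods.labels
        assert len(mods.modules) == 2
        first = set(labels.iloc[:20].unique())
        second = set(labels.iloc[20:].unique())
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_detection_invariant_to_beta_on_noise_free_blocks(self, rng):
        e = self.blocks(rng, (15, 15, 12))
        out = []
        for beta in (6, 14):
            tom = coexnet.topological_overlap(coexnet.signed_adjacency(e, beta))
            mods = coexnet.detect_modules(tom, NetworkParams(beta=beta, min_module_size=10))
            out.append(tuple(mods.labels))
        assert out[0] == out[1]

    def test_block_below_minimum_size_goes_grey(self, rng):
        e = self.blocks(rng, (9,), n=40)
        # noise orthogonal to the block profile: nothing can pad the block
        profile = e.iloc[0].to_numpy()
        raw = rng.standard_normal((40, 40))
        raw -= np.outer(raw @ profile / (profile @ profile), profile)
        noise = make_expression(raw, prefix="n")
        noise.index = [f"g{i + 9}" for i in range(40)]
        full = pd.concat([e, noise])
        tom = coexnet.topological_overlap(coexnet.signed_adjacency(full, 6))
        mods = coexnet.detect_modules(tom, NetworkParams(beta=6, min_module_size=10))
        assert set(mods.labels.iloc[:9]) == {"grey"}

    def test_pure_noise_is_entirely_grey(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            e = make_expression(r.standard_normal((300, 36)))
            tom = coexnet.topological_overlap(coexnet.signed_adjacency(e, 6))
            mods = coexnet.detect_modules(tom, NetworkParams(beta=6, min_module_size=35))
            assert set(mods.labels) == {"grey"}, f"seed {seed}"

    def test_modules_named_by_size_ranked_colors(self, rng):
        e = self.blocks(rng, (25, 15))
        tom = coexnet.topological_overlap(coexnet.signed_adjacency(e, 6))
        mods = coexnet.detect_modules(tom, NetworkParams(beta=6, min_module_size=10))
        sizes = mods.labels.value_counts()
        assert sizes.index[0] == "turquoise" and sizes.index[1] == "blue"


class TestEigengenes:
    def test_single_gene_module_equals_standardized_gene(self, rng):
        e = make_expression(rng.standard_normal((1, 15)))
        labels = pd.Series(["turquoise"], index=e.index, name="module")
        mods = coexnet.ModuleAssignment(labels, np.zeros((0, 4)), 0.0)
        me = coexnet.module_eigengenes(e, mods)
        r = np.corrcoef(me["turquoise"], e.iloc[0])[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert me["turquoise"].mean() == pytest.approx(0.0, abs=1e-12)
        assert me["turquoise"].std() == pytest.approx(1.0, rel=1e-9)

    def test_rank_one_module_correlates_perfectly_with_members(self, rng):
        base = rng.standard_normal(12)
        e = make_expression(np.tile(base, (6, 1)))
        labels = pd.Series("blue", index=e.index, name="module")
        mods = coexnet.ModuleAssignment(labels, np.zeros((0, 4)), 0.0)
        me = coexnet.module_eigengenes(e, mods)
        for i in range(6):
            assert np.corrcoef(me["blue"], e.iloc[i])[0, 1] == pytest.approx(1.0)

    def test_planted_eigengene_recovered(self, rng):
        n = 36
        e_q = rng.standard_normal(n)
        u = rng.uniform(0.4, 0.95, 80)
        x = u[:, None] * e_q + np.sqrt(1 - u ** 2)[:, None] * rng.standard_normal((80, n))
        expr = make_expression(x)
        labels = pd.Series("turquoise", index=expr.index, name="module")
        mods = coexnet.ModuleAssignment(labels, np.zeros((0, 4)), 0.0)
        me = coexnet.module_eigengenes(expr, mods)
        assert abs(np.corrcoef(me["turquoise"], e_q)[0, 1]) >= 0.95


class TestModuleTraitAnalysis:
    @staticmethod
    def _assignment(index, labels):
        return coexnet.ModuleAssignment(pd.Series(labels, index=index, name="module"),
                                        np.zeros((0, 4)), 0.0)

    def test_me_equal_to_trait_survives_bonferroni(self, rng):
        n = 30
        trait = rng.integers(0, 2, n).astype(float)
        me = pd.DataFrame({"turquoise": (trait - trait.mean()) / trait.std(),
                           "blue": rng.standard_normal(n)},
                          index=[f"s{i}" for i in range(n)])
        pheno = pd.DataFrame({"case": trait}, index=me.index)
        rep = coexnet.module_trait_analysis(me, pheno, ["case"])
        assert rep.correlations.loc["turquoise", "case"] == pytest.approx(1.0)
        assert "turquoise" in rep.significant

    def test_family_wise_error_controlled_under_null(self):
        m, n, sims = 20, 36, 2000
        hits = 0
        r = np.random.default_rng(99)
        for _ in range(sims):
            me = pd.DataFrame(r.standard_normal((n, m)),
                              columns=[f"mod{i}" for i in range(m)],
                              index=[f"s{i}" for i in range(n)])
            pheno = pd.DataFrame({"case": r.integers(0, 2, n)}, index=me.index)
            if pheno.case.std() == 0:
                continue
            rep = coexnet.module_trait_analysis(me, pheno, ["case"])
            hits += bool(rep.significant)
        assert hits / sims <= 0.07

    def test_confounded_module_flagged_and_dropped(self, rng):
        # module driven by brain pH is removed from the disease-significant list
        n = 36
        ph = rng.normal(6.6, 0.25, n)
        case = np.array([0] * 18 + [1] * 18, float)
        me = pd.DataFrame({
            "turquoise": 0.9 * (case - case.mean()) / case.std()
                         + 0.44 * rng.standard_normal(n),
            "blue": 0.9 * (ph - ph.mean()) / ph.std() + 0.44 * rng.standard_normal(n),
        }, index=[f"s{i}" for i in range(n)])
        pheno = pd.DataFrame({"case": case, "ph": ph}, index=me.index)
        rep = coexnet.module_trait_analysis(me, pheno, ["case", "ph"])
        assert "blue" in rep.confounded
        assert rep.significant == ["turquoise"]

    def test_constant_trait_rejected(self, rng):
        me = pd.DataFrame({"turquoise": rng.standard_normal(10)},
                          index=[f"s{i}" for i in range(10)])
        pheno = pd.DataFrame({"case": np.ones(10)}, index=me.index)
        with pytest.raises(ValueError, match="constant"):
            coexnet.module_trait_analysis(me, pheno, ["case"])


class TestMembershipSignificance:
    def test_gene_identical_to_its_eigengene_has_unit_mm(self, rng):
        base = rng.standard_normal(20)
        expr = make_expression(np.tile(base, (5, 1)))
        labels = pd.Series("turquoise", index=expr.index, name="module")
        mods = coexnet.ModuleAssignment(labels, np.zeros((0, 4)), 0.0)
        me = coexnet.module_eigengenes(expr, mods)
        trait = pd.Series(rng.integers(0, 2, 20).astype(float), index=expr.columns)
        stats = coexnet.membership_significance(expr, me, mods, trait)
        assert np.allclose(stats.MM, 1.0)

    def test_gene_significance_uses_absolute_correlation(self):
        n = 40
        trait = pd.Series(np.r_[np.zeros(20), np.ones(20)],
                          index=[f"s{i}" for i in range(n)])
        rng2 = np.random.default_rng(5)
        y = -0.6 * (trait - trait.mean()) / trait.std()
        y = y + 0.8 * rng2.standard_normal(n)
        expr = pd.DataFrame([y.to_numpy()], index=["g0"], columns=trait.index)
        labels = pd.Series("turquoise", index=expr.index, name="module")
        mods = coexnet.ModuleAssignment(labels, np.zeros((0, 4)), 0.0)
        me = coexnet.module_eigengenes(expr, mods)
        stats = coexnet.membership_significance(expr, me, mods, trait)
        r = np.corrcoef(y, trait)[0, 1]
        assert r < 0
        assert stats.GS.iloc[0] == pytest.approx(abs(r))

    def test_mm_gs_positively_associated_in_trait_module(self, small_cohort):
        # the classic hub pattern: membership predicts trait relevance
        from scipy import stats as sps
        cfg, cohort = small_cohort
        truth, mrna, pheno = cohort["truth"], cohort["mrna"], cohort["pheno"]
        members = [t for t, m in truth.mrna_modules.items() if m == "mRNA_mod0"]
        labels = pd.Series("grey", index=mrna.index, name="module")
        labels.loc[members] = "turquoise"
        mods = coexnet.ModuleAssignment(labels, np.zeros((0, 4)), 0.0)
        me = coexnet.module_eigengenes(mrna, mods)
        stats = coexnet.membership_significance(mrna, me, mods,
                                                pheno["case"].astype(float))
        sub = stats[stats.module == "turquoise"]
        fit = sps.linregress(sub.MM, sub.GS)
        assert fit.slope > 0 and fit.pvalue < 0.01


class TestModuleRecoveryPipeline:
    def test_merge_reunites_oversplit_module(self, rng):
        # two halves of one planted module share an eigengene -> merged
        n = 20
        e_q = rng.standard_normal(n)
        u = rng.uniform(0.7, 0.95, 60)
        x = u[:, None] * e_q + np.sqrt(1 - u ** 2)[:, None] * rng.standard_normal((60, n))
        expr = make_expression(x)
        labels = pd.Series(["turquoise"] * 30 + ["blue"] * 30, index=expr.index,
                           name="module")
        mods = coexnet.ModuleAssignment(labels, np.zeros((0, 4)), 0.0)
        merged = coexnet.merge_close_modules(expr, mods, me_merge_cor=0.8)
        assert len(merged.modules) == 1

    def test_kme_sweep_recovers_grey_periphery(self, rng):
        n = 36
        e_q = rng.standard_normal(n)
        u = rng.uniform(0.45, 0.95, 100)
        x = u[:, None] * e_q + np.sqrt(1 - u ** 2)[:, None] * rng.standard_normal((100, n))
        expr = make_expression(x)
        labels = pd.Series("grey", index=expr.index, name="module")
        labels.iloc[:50] = "turquoise"   # only half the module found by the cut
        mods = coexnet.ModuleAssignment(labels, np.zeros((0, 4)), 0.0)
        refined = coexnet.assign_close_transcripts(expr, mods, min_kme=0.2)
        assert (refined.labels != "grey").sum() >= 90
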