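import numpy as np
import pandas as pd
import pytest

from methkin import diffmeth
from methkin.model import RegionSet, SampleRecord


class TestBetaPosterior:
    @pytest.mark.parametrize("m,u,a,b,mean", [
        (5, 5, 6, 6, 0.5),
        (0, 0, 1, 1, 0.5),
        (100, 0, 101, 1, 101 / 102),
    ])
    def test_uniform_prior_updates(self, m, u, a, b, mean):
        post = diffmeth.beta_posterior(m, u)
        assert (post.alpha, post.beta) == (a, b)
        assert post.mean == pytest.approx(mean)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            diffmeth.beta_posterior(-1, 0)


class TestMindiffTest:
    @pytest.mark.parametrize("a,b", [
        ((200, 0), (0, 200)),
        ((50, 50), (50, 50)),
        ((3, 1), (1, 3)),
        ((30, 5), (4, 28)),
    ])
    def test_matches_monte_carlo_oracle(self, a, b, rng):
        res = diffmeth.posterior_mindiff_test(a, b)
        ta = rng.beta(a[0] + 1, a[1] + 1, 1_000_000)
        tb = rng.beta(b[0] + 1, b[1] + 1, 1_000_000)
        mc = float(np.mean(np.abs(ta - tb) < 0.3))
        assert res["p_small"] == pytest.approx(mc, abs=1.5e-3)

    def test_separated_groups_called(self):
        res = diffmeth.posterior_mindiff_test((200, 0), (0, 200))
        assert res["is_dmc"] and res["p_small"] < 1e-6 and res["direction"] == "down"

    def test_identical_groups_not_called(self):
        res = diffmeth.posterior_mindiff_test((50, 50), (50, 50))
        assert not res["is_dmc"] and res["p_small"] > 0.99

    def test_low_coverage_inconclusive(self):
        res = diffmeth.posterior_mindiff_test((3, 1), (1, 3))
        assert not res["is_dmc"] and res["p_small"] > 0.01

    def test_swap_symmetry_exact(self, rng):
        for _ in range(20):
            a = tuple(int(x) for x in rng.integers(0, 200, 2))
            b = tuple(int(x) for x in rng.integers(0, 200, 2))
            r1 = diffmeth.posterior_mindiff_test(a, b)
            r2 = diffmeth.posterior_mindiff_test(b, a)
            assert abs(r1["p_small"] - r2["p_small"]) <= 1e-12
            if abs(r1["level_diff"]) > 1e-12:
                assert r1["direction"] != r2["direction"]

    def test_p_small_monotone_in_delta(self):
        a, b = (60, 20), (20, 60)
        ps = [diffmeth.posterior_mindiff_test(a, b, delta=d)["p_small"]
              for d in (0.1, 0.2, 0.3, 0.4, 0.5)]
        assert ps == sorted(ps)

    def test_both_groups_empty_rejected(self):
        with pytest.raises(ValueError):
            diffmeth.posterior_mindiff_test((0, 0), (0, 0))


def _founder(i):
    return SampleRecord(f"f{i}", "muscle", "B", 9.0, "M" if i % 2 else "F", "P1")


class TestKinship:
    def test_all_founders_identity(self):
        K = diffmeth.kinship_from_pedigree([_founder(i) for i in range(4)])
        assert np.array_equal(K.to_numpy(), np.eye(4))

    def test_parent_offspring_half(self):
        recs = [
            SampleRecord("s", "muscle", "B", 9.0, "M", "P1"),
            SampleRecord("d", "muscle", "B", 9.0, "F", "P1"),
            SampleRecord("o", "muscle", "B", 1.0, "M", "P1", sire_id="s", dam_id="d"),
        ]
        K = diffmeth.kinship_from_pedigree(recs)
        assert K.loc["o", "s"] == 0.5 and K.loc["o", "d"] == 0.5
        assert K.loc["o", "o"] == 1.0  # unrelated parents

    def test_full_sibs_half(self):
        recs = [
            SampleRecord("s", "muscle", "B", 9.0, "M", "P1"),
            SampleRecord("d", "muscle", "B", 9.0, "F", "P1"),
            SampleRecord("o1", "muscle", "B", 1.0, "M", "P1", sire_id="s", dam_id="d"),
            SampleRecord("o2", "muscle", "B", 1.0, "M", "P1", sire_id="s", dam_id="d"),
        ]
        K = diffmeth.kinship_from_pedigree(recs)
        assert K.loc["o1", "o2"] == 0.5

    def test_same_animal_two_tissues_fully_correlated(self):
        recs = [
            SampleRecord("a_mu", "muscle", "B", 4.0, "M", "P1", animal_id="a"),
            SampleRecord("a_te", "testis", "B", 4.0, "M", "P1", animal_id="a"),
        ]
        K = diffmeth.kinship_from_pedigree(recs)
        assert K.loc["a_mu", "a_te"] == 1.0

    def test_cyclic_pedigree_rejected(self):
        recs = [
            SampleRecord("a", "muscle", "B", 9.0, "M", "P1", sire_id="b"),
            SampleRecord("b", "muscle", "B", 9.0, "M", "P1", sire_id="a"),
        ]
        with pytest.raises(ValueError, match="cycl"):
            diffmeth.kinship_from_pedigree(recs)

    def test_study_design_block_structure(self, samples):
        K = diffmeth.kinship_from_pedigree(samples)
        ped = {s.sample_id: s.pedigree_id for s in samples}
        for i in K.index:
            for j in K.columns:
                if ped[i] != ped[j]:
                    assert K.loc[i, j] == 0.0


class TestPqlGlmm:
    def _dataset(self, seed, n=20, beta=1.0):
        rng = np.random.default_rng(seed)
        from scipy.special import expit
        x = rng.random(n)
        X = np.column_stack([np.ones(n), x])
        r = np.maximum(1, rng.poisson(30, n))
        y = rng.binomial(r, expit(-0.3 + beta * x))
        return y, r, X

    def test_sigma_zero_identity_kinship_matches_irls(self):
        import statsmodels.api as sm

        for seed in range(5):
            y, r, X = self._dataset(seed)
            fit = diffmeth.fit_binomial_glmm_pql(y, r, X, np.eye(len(y)), sigma2=0.0)
            glm = sm.GLM(np.column_stack([y, r - y]), X,
                         family=sm.families.Binomial()).fit()
            assert np.allclose(fit.beta_hat, glm.params, atol=1e-3)
            assert np.allclose(fit.se, glm.bse, atol=1e-3)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            diffmeth.fit_binomial_glmm_pql(
                np.array([5.0]), np.array([4.0]), np.ones((1, 1)), np.eye(1))

    def test_rank_deficient_design_rejected(self):
        y, r, X = self._dataset(0)
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            diffmeth.fit_binomial_glmm_pql(y, r, X2, np.eye(len(y)))

    def test_quasi_separation_flagged(self):
        n = 10
        y = np.zeros(n)
        r = np.full(n, 20.0)
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        fit = diffmeth.fit_binomial_glmm_pql(y, r, X, np.eye(n))
        assert "quasi_separation" in fit.flags

    def test_effect_recovered_with_kinship(self, samples):
        from scipy.special import expit

        K = diffmeth.kinship_from_pedigree(samples).to_numpy()
        n = len(samples)
        Lc = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        x = np.array([s.tissue == "testis" for s in samples], dtype=float)
        X = np.column_stack([np.ones(n), x])
        rng = np.random.default_rng(42)
        betas = []
        for _ in range(50):
            g = np.sqrt(0.5) * Lc @ rng.standard_normal(n)
            pi = expit(0.3 + 1.5 * x + g)
            r = np.maximum(1, rng.poisson(30, n))
            y = rng.binomial(r, pi)
            fit = diffmeth.fit_binomial_glmm_pql(y, r, X, K)
            if fit.converged:
                betas.append(fit.beta_hat[1])
        assert np.mean(betas) == pytest.approx(1.5, rel=0.15)


def brute_force_merge(positions, gap):
    """Transitive closure by pairwise linking."""
    positions = sorted(positions)
    groups = []
    for p in positions:
        if groups and p - groups[-1][-1] <= gap:
            groups[-1].append(p)
        else:
            groups.append([p])
    return [(g[0], g[-1] + 1, len(g)) for g in groups]


class TestMergeDmrs:
    def _table(self, positions, chrom="chr1", direction="up"):
        return pd.DataFrame({"chrom": chrom, "pos": positions,
                             "direction": direction})

    def test_gap_rule(self):
        out = diffmeth.merge_dmrs(self._table([100, 400, 1200]), gap=500)
        assert [(r.start, r.end, r.n_sites) for r in out.itertuples()] == [
            (100, 401, 2), (1200, 1201, 1)]

    def test_empty_input(self):
        assert len(diffmeth.merge_dmrs(pd.DataFrame(columns=["chrom", "pos", "direction"]))) == 0

    def test_equals_brute_force_on_random_sites(self, rng):
        pos = np.unique(rng.integers(0, 100_000, 1000))
        out = diffmeth.merge_dmrs(self._table(pos), gap=500)
        assert [(r.start, r.end, r.n_sites) for r in out.itertuples()] == \
            brute_force_merge(pos, 500)

    def test_order_invariant_and_conserves_members(self, rng):
        pos = rng.integers(0, 50_000, 300)
        shuffled = self._table(rng.permutation(pos))
        out1 = diffmeth.merge_dmrs(self._table(np.sort(pos)))
        out2 = diffmeth.merge_dmrs(shuffled)
        assert out1.equals(out2)
        assert out1["n_sites"].sum() == len(pos)

    def test_direction_counts(self):
        t = pd.DataFrame({"chrom": "chr1", "pos": [10, 20, 30],
                          "direction": ["up", "down", "up"]})
        out = diffmeth.merge_dmrs(t)
        assert (out.iloc[0]["n_up"], out.iloc[0]["n_down"]) == (2, 1)


class TestPromoterScreen:
    @pytest.fixture()
    def promoters(self):
        return RegionSet(pd.DataFrame([("chr1", 1000, 2000, "geneA")],
                                      columns=RegionSet.COLUMNS))

    def _dmr(self, n_up, n_down, start=1500, end=1600):
        return pd.DataFrame([{"chrom": "chr1", "start": start, "end": end,
                              "n_sites": n_up + n_down, "n_up": n_up,
                              "n_down": n_down}])

    def test_synclastic_dmr_kept(self, promoters):
        out = diffmeth.screen_promoter_dmrs(self._dmr(5, 2), promoters)
        assert len(out) == 1 and out.iloc[0]["genes"] == "geneA"

    def test_mixed_direction_dropped(self, promoters):
        assert len(diffmeth.screen_promoter_dmrs(self._dmr(3, 3), promoters)) == 0

    def test_non_overlapping_dropped(self, promoters):
        out = diffmeth.screen_promoter_dmrs(
            self._dmr(6, 0, start=5000, end=5100), promoters)
        assert len(out) == 0


class TestDmcScan:
    def test_constant_factor_rejected(self, small_study):
        records = [r for r in small_study["samples"] if r.tissue == "muscle"]
        sub = small_study["filtered"].subset_samples([r.sample_id for r in records])
        with pytest.raises(ValueError, match="constant"):
            diffmeth.dmc_scan(sub, records, "tissue", method="mindiff")

    def test_single_sample_group_rejected_for_pql(self, small_study):
        records = [r for r in small_study["samples"]]
        # keep one testis sample only
        keep = [r for r in records if r.tissue == "muscle"][:4] + \
               [r for r in records if r.tissue == "testis"][:1]
        sub = small_study["filtered"].subset_samples([r.sample_id for r in keep])
        with pytest.raises(ValueError, match="fewer than"):
            diffmeth.dmc_scan(sub, keep, "tissue", method="pql")

    def test_mindiff_recovers_strong_planted_tissue_sites(self, small_config):
        # a state switch of 4 logits moves levels by ~0.6-0.8, far beyond
        # the delta=0.3 credible-difference threshold, so the pooled
        # beta-posterior scan must recover nearly all of them with few
        # false calls among the untouched sites
        from methkin import qc, simdata

        cfg = simdata.SimulationConfig(**{
            **vars(small_config), "tissue_delta": 4.0, "seed": 21})
        genome, cgis, genes = simdata.simulate_genome(cfg)
        samples = simdata.simulate_pedigree(cfg)
        matrix, truth = simdata.simulate_methylomes(genome, cgis, samples, cfg,
                                                    genes=genes)
        filt = qc.apply_site_filter(matrix)
        res = diffmeth.dmc_scan(filt, samples, "tissue", method="mindiff")
        called = set(map(tuple, res[["chrom", "pos", "strand"]].to_numpy()))
        planted = set(map(tuple,
                          truth.dmc["tissue"][["chrom", "pos", "strand"]].to_numpy()))
        other = set()
        for f in ("age", "breed"):
            other |= set(map(tuple, truth.dmc[f][["chrom", "pos", "strand"]].to_numpy()))
        recall = len(called & planted) / len(planted)
        false_calls = called - planted - other
        n_null = filt.n_sites - len(planted) - len(other)
        assert recall >= 0.8
        assert len(false_calls) / n_null <= 0.02


class TestPairwiseAgeScan:
    def test_planted_trend_found_in_extreme_pair(self, small_config):
        # a steep slope makes the 9-vs-1 contrast (~4.8 logits) an
        # unambiguous state switch for the delta=0.3 credible test
        from methkin import qc, simdata

        cfg = simdata.SimulationConfig(**{
            **vars(small_config), "age_slope": 0.6, "seed": 23})
        genome, cgis, genes = simdata.simulate_genome(cfg)
        samples = simdata.simulate_pedigree(cfg)
        matrix, truth_tabs = simdata.simulate_methylomes(genome, cgis, samples, cfg,
                                                         genes=genes)
        filtered = qc.apply_site_filter(matrix)
        out = diffmeth.pairwise_age_scan(filtered, samples)
        truth = truth_tabs.dmc["age"]
        planted = {(r.chrom, r.pos, r.strand): r.direction
                   for r in truth.itertuples()}
        found = {}
        for tissue in ("muscle", "testis"):
            tab = out["per_pair"].get((tissue, "9v1"))
            if tab is None:
                continue
            for r in tab.itertuples():
                found[(r.chrom, r.pos, r.strand)] = r.age_direction
        hits = set(found) & set(planted)
        # the 9-vs-1 contrast carries 8 logit-years of the planted slope
        assert len(hits) / len(planted) >= 0.5
        for k in hits:
            expected = "hyper" if planted[k] == "up" else "hypo"
            assert found[k] == expected

    def test_consensus_intersection(self):
        t1 = pd.DataFrame({"chrom": ["c1", "c1"], "pos": [1, 2], "strand": "+"})
        t2 = pd.DataFrame({"chrom": ["c1"], "pos": [2], "strand": "+"})
        out = diffmeth.consensus_dmcs([t1, t2], mode="intersection")
        assert list(out["pos"]) == [2]
        out = diffmeth.consensus_dmcs([t1, t2], mode="union")
        assert list(out["pos"]) == [1, 2]
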