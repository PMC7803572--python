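import numpy as np
import pytest
from scipy.special import expit

from methkin import context, simdata
from methkin.diffmeth import kinship_from_pedigree


class TestGenome:
    def test_deterministic(self, small_config):
        g1, c1, genes1 = simdata.simulate_genome(small_config)
        g2, c2, genes2 = simdata.simulate_genome(small_config)
        assert g1.chroms == g2.chroms
        assert c1.df.equals(c2.df)
        assert [vars(a) for a in genes1] == [vars(b) for b in genes2]

    def test_zero_cgis_gives_background_only(self):
        cfg = simdata.SimulationConfig(n_chroms=1, chrom_length=30_000,
                                       n_cgis_per_chrom=0, n_genes=0,
                                       frac_tss_in_cgi=0.0)
        genome, cgis, genes = simdata.simulate_genome(cfg)
        assert len(cgis) == 0 and len(genes) == 0
        assert len(context.detect_cgis(genome)) == 0

    def test_planted_islands_pass_criterion_in_isolation(self, small_study):
        genome = small_study["genome"]
        for r in small_study["cgis"].df.itertuples():
            seq = genome.fetch(r.chrom, r.start, r.end)
            assert len(seq) > 200
            assert context.gc_fraction(seq) > 0.50
            assert context.obs_exp_ratio(seq) > 0.60

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            simdata.simulate_genome(simdata.SimulationConfig(
                n_chroms=1, chrom_length=20_000, n_cgis_per_chrom=40))

    def test_tss_in_cgi_fraction(self, small_study):
        cgis = small_study["cgis"].df
        n_in = 0
        for g in small_study["genes"]:
            hit = cgis[(cgis["chrom"] == g.chrom) & (cgis["start"] <= g.tss)
                       & (cgis["end"] > g.tss)]
            n_in += len(hit) > 0
        # at most one gene fits per island, capping the achievable fraction
        expected = min(round(small_study["config"].frac_tss_in_cgi
                             * small_study["config"].n_genes),
                       len(cgis))
        assert n_in >= expected - 1


class TestPedigree:
    def test_default_design_20_samples(self, samples):
        assert len(samples) == 20
        assert sum(s.tissue == "muscle" for s in samples) == 12
        assert sum(s.tissue == "testis" for s in samples) == 8

    def test_offspring_point_to_founders(self, samples):
        by_id = {s.sample_id: s for s in samples}
        for s in samples:
            if s.sire_id is not None:
                assert s.sire_id.startswith(s.pedigree_id)
                assert f"{s.sire_id}_muscle" in by_id

    def test_founder_only_design_identity_kinship(self):
        recs = [r for r in simdata.simulate_pedigree(simdata.SimulationConfig())
                if r.sire_id is None]
        K = kinship_from_pedigree(recs).to_numpy()
        assert np.array_equal(K, np.eye(len(recs)))


class TestMethylomes:
    def test_deterministic(self, small_config, small_study):
        m2, _ = simdata.simulate_methylomes(
            small_study["genome"], small_study["cgis"], small_study["samples"],
            small_config, genes=small_study["genes"])
        m1 = small_study["matrix"]
        assert np.array_equal(m1.meth, m2.meth)
        assert np.array_equal(m1.total, m2.total)

    def test_every_planted_site_in_matrix(self, small_study):
        key = set(map(tuple, small_study["matrix"].sites.to_numpy()))
        for factor, df in small_study["truth"].dmc.items():
            planted = set(map(tuple, df[["chrom", "pos", "strand"]].to_numpy()))
            assert planted <= key

    def test_binomial_limit_recovers_mixture_mean(self, small_config):
        cfg = simdata.SimulationConfig(**{
            **vars(small_config), "sigma2_g": 0.0, "bb_concentration": np.inf,
            "n_tissue_dmc": 0, "n_age_dmc": 0, "n_breed_dmc": 0,
            "n_heritable_windows": 0, "mu_logit_sd": 0.0,
        })
        genome, cgis, genes = simdata.simulate_genome(cfg)
        samples = simdata.simulate_pedigree(cfg)
        matrix, _ = simdata.simulate_methylomes(genome, cgis, samples, cfg)
        lv = matrix.levels()
        in_cgi = np.zeros(matrix.n_sites, dtype=bool)
        for r in cgis.df.itertuples():
            in_cgi |= ((matrix.sites["chrom"] == r.chrom)
                       & (matrix.sites["pos"] >= r.start)
                       & (matrix.sites["pos"] < r.end)).to_numpy()
        assert np.nanmean(lv[in_cgi]) == pytest.approx(cfg.cgi_level, abs=0.02)
        assert np.nanmean(lv[~in_cgi]) == pytest.approx(cfg.noncgi_level, abs=0.02)

    def test_planted_tissue_effect_implies_large_level_difference(self, small_study):
        truth = small_study["truth"].dmc["tissue"]
        assert np.abs(truth["level_delta"]).mean() >= 0.25

    def test_coverage_truncated_at_one(self, small_study):
        assert small_study["matrix"].total.min() >= 1


class TestExpression:
    def test_deterministic(self, small_config, small_study):
        e2, _ = simdata.simulate_expression(
            small_study["genes"], small_study["truth"].promoter_truth, small_config)
        assert np.array_equal(small_study["expression"].values.to_numpy(),
                              e2.values.to_numpy())

    def test_noise_free_strong_negative_coupling_gives_rho_minus_one(self, small_study):
        from scipy import stats

        cfg = simdata.SimulationConfig(**{
            **vars(small_study["config"]),
            "coupling_slope": 5.0, "frac_negative": 1.0, "expr_noise_sd": 0.0})
        expr, coupling = simdata.simulate_expression(
            small_study["genes"], small_study["truth"].promoter_truth, cfg)
        gid = coupling.iloc[0]["gene_id"]
        meth = small_study["truth"].promoter_truth.loc[gid].to_numpy()
        rho, _ = stats.spearmanr(meth, expr.values.loc[gid].to_numpy())
        assert rho == pytest.approx(-1.0)

    def test_unknown_coupled_gene_rejected(self, small_study):
        with pytest.raises(ValueError, match="ghost"):
            simdata.simulate_expression(
                small_study["genes"], small_study["truth"].promoter_truth,
                small_study["config"], coupled_genes=["ghost"])


class TestWriteDataset(object):
    def test_round_trip_through_files(self, tmp_path, small_config):
        from methkin import io as mio

        data = simdata.write_dataset(tmp_path / "d", small_config)
        genome = mio.read_fasta(tmp_path / "d" / "genome.fa")
        assert genome.chroms == data["genome"].chroms
        sheet = mio.read_sample_sheet(tmp_path / "d" / "sample_sheet.tsv")
        assert [s.sample_id for s in sheet] == [s.sample_id for s in data["samples"]]
        # reassemble the matrix from the per-sample bedGraphs
        per_sample = {}
        import pandas as pd
        for s in sheet:
            frames = []
            for strand, suffix in (("+", "plus"), ("-", "minus")):
                frames.append(mio.read_methyldackel_bedgraph(
                    tmp_path / "d" / "counts" / f"{s.sample_id}.{suffix}.bedGraph",
                    s.sample_id, strand=strand))
            per_sample[s.sample_id] = pd.concat(frames, ignore_index=True)
        matrix = mio.assemble_matrix(per_sample, [s.sample_id for s in sheet])
        assert matrix.n_sites == data["matrix"].n_sites
        assert np.array_equal(matrix.meth[~matrix.missing],
                              data["matrix"].meth[~data["matrix"].missing])
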