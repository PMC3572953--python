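import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from crossgwas import io
from crossgwas.errors import ConfigurationError
from crossgwas.phenotype import animal_slopes, summarize_strains
from crossgwas.synthetic import (
    SimulationConfig,
    Study,
    TruthRecord,
    anchor_snp_indices,
    simulate_dataset,
    simulate_gene_maps,
    simulate_phenotypes,
    simulate_strain_panel,
    simulate_summary_stats,
    strain_latent_slopes,
    write_fixtures,
)


def small_config(**kw):
    defaults = dict(n_strains=12, n_snps=100, block_length_snps=10, seed=7, studies=[])
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_strains", 2),
            ("heritability", 1.5),
            ("ld_decay_rho", 1.0),
            ("block_length_snps", 0),
            ("maf_distribution", (0.6, 0.2)),
            ("residual_sd_within_animal", -0.1),
            ("n_families", 0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            small_config(**{field: value})

    def test_causal_index_out_of_range(self):
        with pytest.raises(ConfigurationError, match="causal"):
            small_config(causal_snps=[(100, 0.5)])

    def test_nonpositive_study_n_rejected(self):
        with pytest.raises(ConfigurationError, match="n_samples"):
            small_config(studies=[Study("EVE", 0)])


class TestSimulateStrainPanel:
    def test_shape_and_inbred_coding(self):
        cfg = SimulationConfig(n_strains=31, n_snps=1000, seed=7, studies=[])
        g = simulate_strain_panel(cfg)
        assert g.calls.shape == (31, 1000)
        assert set(np.unique(g.calls)) <= {0.0, 2.0}

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_strains=31, n_snps=1000, seed=7, studies=[])
        a = simulate_strain_panel(cfg)
        b = simulate_strain_panel(cfg)
        assert np.array_equal(a.calls, b.calls)
        pd.testing.assert_frame_equal(a.snp_map, b.snp_map)

    def test_blocks_share_strain_partition(self):
        cfg = small_config(n_snps=500, block_length_snps=50)
        g = simulate_strain_panel(cfg)
        for b in range(10):
            block = g.calls[:, b * 50:(b + 1) * 50]
            assert np.all(block == block[:, [0]])

    def test_different_seeds_differ(self):
        a = simulate_strain_panel(small_config(seed=1))
        b = simulate_strain_panel(small_config(seed=2))
        assert not np.array_equal(a.calls, b.calls)

    def test_positions_sorted_within_chromosomes(self):
        g = simulate_strain_panel(small_config(n_snps=200))
        for _, grp in g.snp_map.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing


class TestSimulatePhenotypes:
    def test_seed_determinism(self):
        cfg = small_config()
        g = simulate_strain_panel(cfg)
        a = simulate_phenotypes(g, cfg)
        b = simulate_phenotypes(g, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_doses_include_saline_and_four_levels(self):
        cfg = small_config(animals_per_strain=2)
        g = simulate_strain_panel(cfg)
        table = simulate_phenotypes(g, cfg)
        one_animal = table[table.animal_id == table.animal_id.iloc[0]]
        assert sorted(one_animal.dose_mg_ml) == [0.0, 1.0, 3.0, 10.0, 30.0]

    def test_zero_heritability_strain_means_differ_by_sampling_only(self):
        # between/total variance ratio of a one-way ANOVA decomposition ~ 0
        ratios = []
        for seed in range(20):
            cfg = small_config(seed=seed, heritability=0.0, n_snps=60)
            g = simulate_strain_panel(cfg)
            slopes = animal_slopes(simulate_phenotypes(g, cfg))
            groups = [grp.slope.to_numpy() for _, grp in slopes.groupby("strain")]
            n_per = len(groups[0])
            msb = n_per * np.var([g.mean() for g in groups], ddof=1)
            msw = np.mean([np.var(g, ddof=1) for g in groups])
            sigma_between = max((msb - msw) / n_per, 0.0)
            total = sigma_between + msw
            ratios.append(sigma_between / total)
        assert np.mean(ratios) < 0.05

    def test_noise_free_causal_effect_separates_two_groups(self):
        base = small_config(heritability=0.0, strain_var=0.0,
                            residual_sd_within_animal=0.0, animals_per_strain=2)
        maf = simulate_strain_panel(base).maf()
        causal = int(np.argmax(maf))  # guaranteed both genotype classes present
        cfg = small_config(
            heritability=0.0, strain_var=0.0, residual_sd_within_animal=0.0,
            causal_snps=[(causal, 0.6)], animals_per_strain=2,
        )
        g = simulate_strain_panel(cfg)
        slopes = animal_slopes(simulate_phenotypes(g, cfg))
        summaries = summarize_strains(slopes)
        means = {s.strain: s.slope_mean for s in summaries}
        carriers = {g.strain_ids[i] for i in np.flatnonzero(g.calls[:, causal] == 2.0)}
        high = [m for s, m in means.items() if s in carriers]
        low = [m for s, m in means.items() if s not in carriers]
        assert np.allclose(high, high[0], atol=1e-9)
        assert np.allclose(low, low[0], atol=1e-9)
        assert high[0] - low[0] == pytest.approx(0.6, abs=1e-9)

    @pytest.mark.parametrize("h2", [0.2, 0.5, 0.8])
    def test_realized_heritability_tracks_config(self, h2):
        # pooled over seeds: var(genetic values) / var(strain means) ~ h2
        genetic_all, means_all = [], []
        for seed in range(20):
            cfg = SimulationConfig(n_strains=31, n_snps=150, block_length_snps=5,
                                   heritability=h2, seed=seed, studies=[])
            g = simulate_strain_panel(cfg)
            latent, genetic = strain_latent_slopes(g, cfg)
            slopes = animal_slopes(simulate_phenotypes(g, cfg))
            strain_means = slopes.groupby("strain").slope.mean()
            genetic_all.append(genetic)
            means_all.append(strain_means.to_numpy())
        # pool raw values over seeds: second moments estimate sigma_g^2 and
        # sigma_g^2 + noise/n without the correlated-draw shrinkage that a
        # per-seed sample variance would introduce
        realized = np.var(np.concatenate(genetic_all)) / np.var(np.concatenate(means_all))
        assert abs(realized - h2) < 0.15

    def test_causal_index_out_of_range_at_generation(self):
        cfg = small_config()
        g = simulate_strain_panel(cfg)
        cfg.causal_snps = [(5000, 0.5)]  # bypass ctor validation
        with pytest.raises(ConfigurationError, match="out of range"):
            simulate_phenotypes(g, cfg)


class TestSimulateSummaryStats:
    @staticmethod
    def _genes_and_config(**kw):
        defaults = dict(
            n_strains=12, n_snps=100, seed=5,
            n_genes=20, snps_per_human_gene=250, ld_decay_rho=0.0,
            studies=[Study("EVE", 10_000)],
        )
        defaults.update(kw)
        cfg = SimulationConfig(**defaults)
        g = simulate_strain_panel(cfg)
        _, human_genes, _ = simulate_gene_maps(g, cfg)
        return human_genes, cfg

    def test_null_p_values_uniform_at_5000_snps(self):
        genes, cfg = self._genes_and_config()
        stats = simulate_summary_stats(genes, cfg)  # no signal genes
        assert len(stats) == 5000
        assert kstest(stats.p_two_sided, "uniform").pvalue > 0.01

    def test_planted_signal_gene_contains_study_minimum(self):
        hits = 0
        for seed in range(20):
            genes, cfg = self._genes_and_config(seed=seed, snps_per_human_gene=25,
                                                signal_snr=6.0)
            stats = simulate_summary_stats(
                genes, cfg, signal_genes={"HGENE004"}, directions={"EVE": 1}
            )
            best = stats.loc[stats.p_two_sided.idxmin()]
            target = [g for g in genes if g.gene_id == "HGENE004"][0]
            inside = (best.chrom == target.chrom) and (target.start <= best.pos <= target.end)
            hits += bool(inside)
        assert hits >= 19

    def test_zero_rho_adjacent_z_uncorrelated(self):
        genes, cfg = self._genes_and_config()
        stats = simulate_summary_stats(genes, cfg)
        z = np.log(stats.effect.to_numpy()) * np.sqrt(stats.n_samples.to_numpy())
        r = np.corrcoef(z[:-1], z[1:])[0, 1]
        assert abs(r) < 0.05

    def test_positive_rho_induces_neighbor_correlation(self):
        genes, cfg = self._genes_and_config(ld_decay_rho=0.6)
        stats = simulate_summary_stats(genes, cfg)
        z = np.log(stats.effect.to_numpy()) * np.sqrt(stats.n_samples.to_numpy())
        r = np.corrcoef(z[:-1], z[1:])[0, 1]
        assert r > 0.4

    def test_p_and_or_mutually_consistent(self):
        from scipy.stats import norm

        genes, cfg = self._genes_and_config(snps_per_human_gene=10)
        stats = simulate_summary_stats(genes, cfg)
        z = np.log(stats.effect.to_numpy()) * np.sqrt(stats.n_samples.to_numpy())
        expected_p = 2 * norm.sf(np.abs(z))
        np.testing.assert_allclose(stats.p_two_sided, expected_p, rtol=1e-8)

    def test_non_sharing_study_has_no_signal(self):
        genes, cfg = self._genes_and_config(
            snps_per_human_gene=25, signal_snr=6.0,
            studies=[Study("EVE", 10_000), Study("DAG", 2_000, shares_signal=False)],
        )
        stats = simulate_summary_stats(genes, cfg, signal_genes={"HGENE004"},
                                       directions={"EVE": 1})
        dag = stats[stats.study == "DAG"]
        assert kstest(dag.p_two_sided, "uniform").pvalue > 0.001

    def test_no_studies_returns_none(self):
        genes, cfg = self._genes_and_config()
        cfg.studies = []
        assert simulate_summary_stats(genes, cfg) is None


class TestDatasetAndFixtures:
    def _config(self, **kw):
        base = SimulationConfig(n_strains=12, n_snps=200, block_length_snps=10,
                                seed=11, studies=[])
        idx = int(anchor_snp_indices(base)[3])
        defaults = dict(
            n_strains=12, n_snps=200, block_length_snps=10, seed=11,
            causal_snps=[(idx, 0.5)],
            studies=[Study("EVE", 10_000), Study("SLLI", 1_200)],
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_truth_links_mouse_and_human_genes(self):
        ds = simulate_dataset(self._config())
        assert len(ds.truth.causal_mouse_genes) == 1
        assert len(ds.truth.causal_human_genes) == 1
        pairs = dict(zip(ds.homology_map.mouse_gene, ds.homology_map.human_gene))
        assert pairs[ds.truth.causal_mouse_genes[0]] == ds.truth.causal_human_genes[0]

    def test_truth_record_json_roundtrip(self):
        ds = simulate_dataset(self._config())
        restored = TruthRecord.from_json(ds.truth.to_json())
        assert restored == ds.truth

    def test_write_fixtures_roundtrip_lossless(self, tmp_path):
        cfg = self._config()
        paths = write_fixtures(tmp_path, cfg)
        ds = simulate_dataset(cfg)
        g = io.read_genotypes(paths["genotypes"])
        assert g.strain_ids == ds.genotypes.strain_ids
        np.testing.assert_array_equal(g.calls, ds.genotypes.calls)
        dr = io.read_dose_response(paths["dose_response"])
        pd.testing.assert_frame_equal(dr, ds.dose_response)
        ss = io.read_summary_stats(paths["summary_stats"])
        pd.testing.assert_frame_equal(ss, ds.summary_stats)
        hm = io.read_homology_map(paths["homology_map"])
        pd.testing.assert_frame_equal(hm, ds.homology_map)
        truth = TruthRecord.from_json(paths["truth"].read_text())
        assert truth == ds.truth

    def test_write_fixtures_byte_identical_same_seed(self, tmp_path):
        cfg = self._config()
        a = write_fixtures(tmp_path / "a", cfg)
        b = write_fixtures(tmp_path / "b", cfg)
        for name in a:
            assert a[name].read_bytes() == b[name].read_bytes(), name

    def test_empty_studies_omits_summary_file(self, tmp_path):
        cfg = self._config(studies=[])
        paths = write_fixtures(tmp_path, cfg)
        assert "summary_stats" not in paths
        assert not (tmp_path / "summary_stats.tsv").exists()
        for name in ("genotypes", "dose_response", "homology_map", "truth"):
            assert paths[name].exists()

    def test_unwritable_path_raises_io_error(self):
        cfg = self._config(studies=[])
        with pytest.raises(OSError):
            write_fixtures("/proc/definitely/not/writable", cfg)
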