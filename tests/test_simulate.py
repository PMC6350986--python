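"""Synthetic pooled read-count generator: determinism, truth, sampling laws."""

from __future__ import annotations

import numpy as np
import pytest

from poolseq_assoc import SimulationConfig, simulate_collection, simulate_study
from poolseq_assoc.association import test_sites as run_site_tests


def small_config(**overrides):
    defaults = dict(seed=7, n_genes=30, n_causal_genes=6, snps_per_gene=(3, 6))
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(delta=1.5),
            dict(n_causal_genes=200),
            dict(pool_individuals=0),
            dict(coverage_mean=-1),
            dict(mode="exact"),
            dict(baseline_freq_range=(0.6, 0.5)),
            dict(seq_error=1.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            small_config(**kwargs)


class TestDeterminismAndTruth:
    def test_same_seed_reproduces_identical_collection(self):
        a = simulate_collection(small_config(), "C1", 0)
        b = simulate_collection(small_config(), "C1", 0)
        assert np.array_equal(a.counts.counts, b.counts.counts)
        assert a.truth.sites.equals(b.truth.sites)
        assert a.truth.genes.equals(b.truth.genes)

    def test_same_seed_reproduces_identical_files(self, tmp_path):
        for sub in ("x", "y"):
            simulate_study(small_config(), tmp_path / sub)
        for name in ("counts_VCP.tsv", "genes.gff3", "categories.tsv",
                     "truth_genes.tsv", "manifest.tsv"):
            assert (tmp_path / "x" / name).read_bytes() == (
                tmp_path / "y" / name
            ).read_bytes()

    def test_different_collections_differ_but_share_layout(self):
        sims = simulate_study(small_config(n_collections=2))
        a, b = sims
        assert a.truth.genes.equals(b.truth.genes)  # shared causal structure
        assert a.categories == b.categories
        assert not a.truth.sites.equals(b.truth.sites)

    def test_causal_gene_count_matches_config(self):
        sim = simulate_collection(small_config(n_causal_genes=6), "C1", 0)
        assert int(sim.truth.genes["is_causal"].sum()) == 6
        assert len(sim.truth.genes) == 30

    def test_null_config_marks_no_causal_genes(self):
        sim = simulate_collection(
            small_config(delta=0.0, n_causal_genes=0, mode="ideal"), "C1", 0
        )
        assert not sim.truth.genes["is_causal"].any()
        assert (
            sim.truth.sites["freq_alt_resistant"]
            == sim.truth.sites["freq_alt_susceptible"]
        ).all()

    def test_every_counts_gene_in_truth_exactly_once(self):
        sim = simulate_collection(small_config(), "C1", 0)
        assert sim.truth.genes["gene_id"].is_unique
        assert set(sim.truth.sites["gene_id"]) <= set(sim.truth.genes["gene_id"])

    def test_gene_intervals_do_not_overlap_within_chromosome(self):
        sim = simulate_collection(small_config(), "C1", 0)
        for _, sub in sim.truth.genes.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].iloc[1:].to_numpy()
                    > sub["end"].iloc[:-1].to_numpy()).all()

    def test_impossible_delta_is_a_hard_error_naming_the_site(self):
        with pytest.raises(ValueError, match=r"delta.*at site .*:\d+"):
            simulate_collection(
                small_config(baseline_freq_range=(0.05, 0.1), delta=0.95),
                "C1", 0,
            )


class TestSamplingLaws:
    def test_pool_resampling_inflates_read_frequency_variance(self):
        # one biallelic site at frequency 0.5, many replicate pools at
        # depth 1e4: the variance across pools must exceed the pure
        # read-sampling bound p(1-p)/depth by far and approach the
        # finite-pool bound p(1-p)/(2*25)
        config = SimulationConfig(
            seed=3, n_genes=1, n_causal_genes=0, delta=0.0,
            snps_per_gene=(1, 1), baseline_freq_range=(0.5, 0.5),
            replicates_per_phenotype=200, coverage_mean=10_000.0,
            coverage_dispersion=1e6, seq_error=0.0, triallelic_fraction=0.0,
        )
        sim = simulate_collection(config, "C1", 0)
        counts = sim.counts.counts[0]  # (400 libraries, 4)
        depth = counts.sum(axis=1)
        ref_idx = "ACGT".index(sim.counts.sites.loc[0, "ref"])
        freq = 1.0 - counts[:, ref_idx] / depth  # alternate-allele frequency
        var = freq.var(ddof=1)
        pool_bound = 0.25 / 50
        read_bound = 0.25 / 10_000
        assert var > 10 * read_bound
        assert var == pytest.approx(pool_bound, rel=0.35)

    def test_ideal_mode_recovers_population_frequency(self):
        config = SimulationConfig(
            seed=5, n_genes=200, n_causal_genes=0, delta=0.0,
            snps_per_gene=(5, 10), mode="ideal", seq_error=0.0,
            triallelic_fraction=0.0,
        )
        sim = simulate_collection(config, "C1", 0)
        counts = sim.counts.counts.sum(axis=1)  # (S, 4) over all libraries
        depth = counts.sum(axis=1)
        ref_idx = np.array(["ACGT".index(r) for r in sim.counts.sites["ref"]])
        alt_freq = 1.0 - counts[np.arange(len(depth)), ref_idx] / depth
        truth = sim.truth.sites["freq_alt_resistant"].to_numpy()
        err = alt_freq - truth
        # mean read frequency recovers the configured population frequency
        mc_se = err.std(ddof=1) / np.sqrt(err.size)
        assert abs(err.mean()) < 3 * mc_se + 1e-9

    def test_null_ideal_phenotypes_are_exchangeable(self):
        config = SimulationConfig(
            seed=6, n_genes=300, n_causal_genes=0, delta=0.0,
            snps_per_gene=(5, 10), mode="ideal", seq_error=0.0,
            triallelic_fraction=0.0,
        )
        sim = simulate_collection(config, "C1", 0)
        table = sim.counts
        res = table.counts[:, table.phenotype_mask("resistant"), :].sum(axis=1)
        sus = table.counts[:, table.phenotype_mask("susceptible"), :].sum(axis=1)
        ref_idx = np.array(["ACGT".index(r) for r in table.sites["ref"]])
        rows = np.arange(table.n_sites)
        f_res = 1 - res[rows, ref_idx] / res.sum(axis=1)
        f_sus = 1 - sus[rows, ref_idx] / sus.sum(axis=1)
        diff = f_res - f_sus
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert abs(diff.mean()) < 3 * se + 1e-9

    def test_sequencing_error_scatters_to_other_nucleotides(self):
        config = SimulationConfig(
            seed=8, n_genes=100, n_causal_genes=0, delta=0.0,
            snps_per_gene=(5, 10), mode="ideal", seq_error=0.05,
            baseline_freq_range=(0.0, 0.0), triallelic_fraction=0.0,
        )
        sim = simulate_collection(config, "C1", 0)
        counts = sim.counts.counts.sum(axis=1)
        depth = counts.sum()
        ref_idx = np.array(["ACGT".index(r) for r in sim.counts.sites["ref"]])
        ref_reads = counts[np.arange(len(counts)), ref_idx].sum()
        observed_error = 1 - ref_reads / depth
        assert observed_error == pytest.approx(0.05, rel=0.1)

    def test_planted_category_rate_is_five_times_background(self):
        config = SimulationConfig(seed=21, n_genes=700, n_causal_genes=140)
        sim = simulate_collection(config, "C1", 0)
        genes = sim.truth.genes
        causal_rate = (genes.loc[genes["is_causal"], "category"] == "TRP").mean()
        null_rate = (genes.loc[~genes["is_causal"], "category"] == "TRP").mean()
        assert causal_rate / null_rate == pytest.approx(5.0, rel=0.25)

    def test_infeasible_plant_mass_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            simulate_collection(
                small_config(category_enrichment={"TRP": 50.0}), "C1", 0
            )

    def test_triallelic_fraction_produces_three_allele_sites(self):
        config = SimulationConfig(
            seed=9, n_genes=200, n_causal_genes=0, delta=0.0,
            snps_per_gene=(5, 10), mode="ideal", seq_error=0.0,
            triallelic_fraction=0.3,
        )
        sim = simulate_collection(config, "C1", 0)
        res = run_site_tests(sim.counts)
        frac_tri = (res["k"] >= 3).mean()
        assert 0.15 < frac_tri < 0.45
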