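import filecmp

import numpy as np
import pytest

from ecckit.annotation import normalized_coverage
from ecckit.core_io import EccDNARecord
from ecckit.synthetic import (
    ChromSpec,
    CountsModel,
    DEConfig,
    SimulationConfig,
    SizePeak,
    simulate,
    simulate_counts,
    simulate_eccdna_population,
    simulate_genome,
)


def _small_config(**overrides):
    defaults = dict(
        seed=13,
        chromosomes=[ChromSpec("chrA", 200_000, 0.5, 10.0, 20.0)],
        n_eccdna=300,
        de=DEConfig(n_differential=30),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestSimulateGenome:
    def test_gc_fraction_realized(self):
        cfg = SimulationConfig(
            seed=1, chromosomes=[ChromSpec("chrA", 100_000, 0.5, 5.0, 10.0)]
        )
        genome, _, _ = simulate_genome(cfg)
        seq = genome.sequences["chrA"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02

    def test_gene_and_flank_counts(self):
        cfg = SimulationConfig(
            seed=2, chromosomes=[ChromSpec("chrA", 1_000_000, 0.4, 10.0, 5.0)]
        )
        _, annotations, genes_df = simulate_genome(cfg)
        assert len(genes_df) == 10
        assert len(annotations["gene"]) == 10
        assert len(annotations["Gene2KbU"]) + len(annotations["Gene2KbD"]) == 20

    def test_infeasible_density_names_class(self):
        cfg = SimulationConfig(
            seed=3, chromosomes=[ChromSpec("chrA", 10_000, 0.4, 300.0, 5.0)]
        )
        with pytest.raises(ValueError, match="gene"):
            simulate_genome(cfg)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = _small_config()
        for d in ("a", "b"):
            simulate(_small_config(), tmp_path / d)
        assert filecmp.cmp(tmp_path / "a/genome.fa", tmp_path / "b/genome.fa", shallow=False)
        assert filecmp.cmp(tmp_path / "a/counts.tsv", tmp_path / "b/counts.tsv", shallow=False)
        assert filecmp.cmp(tmp_path / "a/truth.tsv", tmp_path / "b/truth.tsv", shallow=False)
        for bed in (tmp_path / "a/elements").glob("*.bed"):
            assert filecmp.cmp(bed, tmp_path / "b/elements" / bed.name, shallow=False)


class TestPopulation:
    def test_single_peak_median(self):
        cfg = _small_config(
            n_eccdna=2000,
            size_peaks=[SizePeak(150.0, 10.0, 1.0)],
            de=DEConfig(n_differential=0),
        )
        genome, anns, _ = simulate_genome(cfg)
        pop, _ = simulate_eccdna_population(genome, anns, cfg)
        assert abs(np.median(pop["length"]) - 150) <= 2

    def test_lengths_truncated_at_minimum(self):
        cfg = _small_config(size_peaks=[SizePeak(60.0, 30.0, 1.0)])
        genome, anns, _ = simulate_genome(cfg)
        pop, _ = simulate_eccdna_population(genome, anns, cfg)
        assert (pop["length"] >= cfg.min_length).all()

    def test_records_stay_within_chromosome(self):
        cfg = _small_config()
        genome, anns, _ = simulate_genome(cfg)
        pop, _ = simulate_eccdna_population(genome, anns, cfg)
        lengths = genome.lengths
        assert (pop["start"] >= cfg.edge_margin).all()
        for row in pop.itertuples(index=False):
            assert row.end <= lengths[row.chrom] - cfg.edge_margin

    def test_planted_enrichment_recovered_by_estimator(self):
        # 25 genes/Mb puts ~5% of the genome in Gene2KbU, where the
        # ratio estimator's binomial SE (~0.10 at n=5000) makes the
        # +/-0.3 recovery band a ~3 sigma check
        cfg = _small_config(
            seed=5,
            chromosomes=[ChromSpec("chrA", 1_000_000, 0.45, 25.0, 10.0)],
            n_eccdna=5000,
            element_enrichment={"Gene2KbU": 3.0},
            de=DEConfig(n_differential=0),
        )
        genome, anns, _ = simulate_genome(cfg)
        pop, truth = simulate_eccdna_population(genome, anns, cfg)
        records = [
            EccDNARecord(r.chrom, r.start, r.end) for r in pop.itertuples(index=False)
        ]
        nc = normalized_coverage(records, anns["Gene2KbU"], genome)
        assert abs(nc.ratio - 3.0) <= 0.3
        assert truth.class_enrichment == {"Gene2KbU": 3.0}

    def test_uniform_starts_pass_chi_square(self):
        cfg = _small_config(
            seed=6,
            chromosomes=[ChromSpec("chrA", 1_000_000, 0.45, 5.0, 10.0)],
            n_eccdna=3000,
            element_enrichment={},
            chrom_gene_coupling=0.0,
            de=DEConfig(n_differential=0),
        )
        genome, anns, _ = simulate_genome(cfg)
        pop, _ = simulate_eccdna_population(genome, anns, cfg)
        from scipy import stats

        margin = cfg.edge_margin
        usable = 1_000_000 - 2 * margin
        bins = np.linspace(margin, 1_000_000 - margin, 11)
        observed, _ = np.histogram(pop["start"], bins=bins)
        # starts of long circles cannot fall in the last bins' tail; the
        # effect is < length/usable ~ small; chi-square at p > 0.001
        p = stats.chisquare(observed).pvalue
        assert p > 0.001


class TestCounts:
    def _population(self, n):
        import pandas as pd

        return pd.DataFrame({"eccdna_id": [f"ecc{i}" for i in range(n)]})

    def test_library_factor_scales_totals(self):
        cfg = SimulationConfig(
            seed=7,
            counts=CountsModel(mean=50.0, dispersion=0.05, library_factors={"Y1": 2.0}),
            de=DEConfig(n_differential=0),
        )
        counts, _ = simulate_counts(self._population(3000), cfg.sheet(), cfg)
        baseline = counts[["Y2", "Y3", "O1", "O2", "O3"]].sum().mean()
        assert abs(counts["Y1"].sum() / baseline - 2.0) < 0.1

    def test_planted_fold_change_in_group_means(self):
        cfg = SimulationConfig(
            seed=8, de=DEConfig(n_differential=500, log2fc=2.0, up_fraction=1.0)
        )
        counts, truth = simulate_counts(self._population(2000), cfg.sheet(), cfg)
        up = truth["de_direction"] == "up"
        young = counts[["Y1", "Y2", "Y3"]].to_numpy().sum(axis=1)
        old = counts[["O1", "O2", "O3"]].to_numpy().sum(axis=1)
        realized = np.log2(young[up.to_numpy()].mean() / old[up.to_numpy()].mean())
        assert abs(realized - 2.0) < 0.15

    def test_truth_membership_counts(self):
        cfg = SimulationConfig(seed=9, de=DEConfig(n_differential=120, up_fraction=0.75))
        _, truth = simulate_counts(self._population(1000), cfg.sheet(), cfg)
        assert int(truth["de_status"].sum()) == 120
        assert int((truth["de_direction"] == "up").sum()) == 90

    def test_nonpositive_mean_rejected(self):
        cfg = SimulationConfig(seed=10, counts=CountsModel(mean=0.0))
        with pytest.raises(ValueError):
            simulate_counts(self._population(10), cfg.sheet(), cfg)

    def test_excess_planted_rejected(self):
        cfg = SimulationConfig(seed=11, de=DEConfig(n_differential=50))
        with pytest.raises(ValueError):
            simulate_counts(self._population(10), cfg.sheet(), cfg)


class TestDatasetConsistency:
    def test_truth_rows_match_population(self, sim_dataset):
        assert len(sim_dataset.truth.records) == len(sim_dataset.population)
        assert set(sim_dataset.truth.records["eccdna_id"]) == set(
            sim_dataset.counts.index
        )

    def test_truth_spot_check_rederivable(self, sim_dataset):
        """Any truth row's start-class membership can be re-derived."""
        from ecckit import intervals as iv

        row = sim_dataset.truth.records.iloc[17]
        classes = sorted(
            name
            for name, ann in sim_dataset.annotations.items()
            if iv.point_in(ann.merged(), row["chrom"], int(row["start"]))
        )
        assert ";".join(classes) == row["start_classes"]

    def test_per_sample_beds_match_counts(self, sim_dataset, tmp_path):
        from ecckit.core_io import read_eccdna_bed
        from ecckit.synthetic import write_fixture_set

        paths = write_fixture_set(sim_dataset, tmp_path)
        sample = sim_dataset.sheet.samples[0]
        records = read_eccdna_bed(paths["eccdna_beds"][sample], sample)
        nonzero = sim_dataset.counts[sample][sim_dataset.counts[sample] > 0]
        assert len(records) == len(nonzero)
        assert sum(r.counts[sample] for r in records) == int(nonzero.sum())
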