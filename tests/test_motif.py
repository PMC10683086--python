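import numpy as np
import pytest

from ecckit.core_io import EccDNARecord, Genome
from ecckit.motif import (
    build_motif_profile,
    collect_flanks,
    extract_flanks,
    genome_background_trinuc,
    spacer_scan,
)
from ecckit.synthetic import (
    DEConfig,
    PlantedMotif,
    SimulationConfig,
    plant_junction_motif,
    simulate,
    simulate_eccdna_population,
    simulate_genome,
)


class TestExtractFlanks:
    def test_direct_slicing(self):
        g = Genome({"c": "AAAACCCCGGGGTTTTAAAA"})
        start_flank, end_flank = extract_flanks(g, EccDNARecord("c", 10, 16), w=2)
        assert start_flank == g.sequences["c"][8:12] == "GGGG"
        assert end_flank == g.sequences["c"][14:18] == "TTAA"

    def test_out_of_bounds_record_excluded(self):
        g = Genome({"c": "ACGT" * 30})
        near_edge = EccDNARecord("c", 5, 60)  # start < w
        ok = EccDNARecord("c", 20, 80)
        starts, ends, excluded = collect_flanks(g, [near_edge, ok], w=10)
        assert excluded == 1
        assert len(starts) == len(ends) == 1


class TestBackground:
    def test_homopolymer(self):
        bg = genome_background_trinuc(Genome({"c": "AAAA"}))
        assert bg["AAA"] == 1.0

    def test_enumerated_small_genome(self):
        bg = genome_background_trinuc(Genome({"c": "ACGTACGT"}))
        assert bg["ACG"] == pytest.approx(2 / 6)
        assert bg["CGT"] == pytest.approx(2 / 6)
        assert bg["GTA"] == pytest.approx(1 / 6)
        assert bg["TAC"] == pytest.approx(1 / 6)
        assert bg.sum() == pytest.approx(1.0)

    def test_n_windows_skipped(self):
        # windows AAN, ANA, NAA are dropped; only AAA remains
        bg = genome_background_trinuc(Genome({"c": "AANAAA"}))
        assert bg["AAA"] == 1.0

    def test_all_n_genome_rejected(self):
        with pytest.raises(ValueError):
            genome_background_trinuc(Genome({"c": "NNNNNN"}))

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError):
            genome_background_trinuc(Genome({"c": "AC"}))

    def test_uniform_genome_frequencies(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
        bg = genome_background_trinuc(Genome({"c": seq}))
        se = np.sqrt((1 / 64) * (63 / 64) / 1e6)
        assert np.all(np.abs(bg.to_numpy() - 1 / 64) < 5 * se)


class TestProfile:
    def test_identical_flanks_have_unit_frequencies(self):
        bg = genome_background_trinuc(Genome({"c": "ACGT" * 1000}))
        flanks = ["CCGAAACCGATTGGCCAATT"] * 10
        prof = build_motif_profile(flanks, bg)
        assert prof.trinuc_obs.loc[-10, "CCG"] == 1.0
        assert np.allclose(prof.nucleotide_freq.sum(axis=1), 1.0)
        assert np.allclose(prof.trinuc_obs.sum(axis=1), 1.0)

    def test_enrichment_invariant_under_flank_duplication(self):
        rng = np.random.default_rng(3)
        bg = genome_background_trinuc(Genome({"c": "".join(rng.choice(list("ACGT"), 10000))}))
        flanks = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(50)]
        once = build_motif_profile(flanks, bg).enrichment
        twice = build_motif_profile(flanks * 2, bg).enrichment
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_null_flanks_have_bounded_enrichment(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 200_000))
        bg = genome_background_trinuc(Genome({"c": seq}))
        flanks = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(2000)]
        prof = build_motif_profile(flanks, bg)
        assert prof.enrichment.to_numpy().max() <= 2.0

    def test_planted_motif_dominates_offset(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 100_000))
        bg = genome_background_trinuc(Genome({"c": seq}))
        flanks = []
        for _ in range(1000):
            f = list("".join(rng.choice(list("ACGT"), 20)))
            if rng.random() < 0.8:
                f[4:7] = "CCG"  # offset -6 at w=10
            flanks.append("".join(f))
        prof = build_motif_profile(flanks, bg)
        row = prof.enrichment.loc[-6]
        assert row["CCG"] >= 5 * row.drop("CCG").median()

    def test_empty_flank_set_rejected(self):
        bg = genome_background_trinuc(Genome({"c": "ACGT" * 10}))
        with pytest.raises(ValueError):
            build_motif_profile([], bg)


class TestSpacerScan:
    def _profile_with_planted_pair(self, fraction=1.0, n=500, seed=5):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 100_000))
        bg = genome_background_trinuc(Genome({"c": seq}))
        flanks = []
        for _ in range(n):
            f = list("".join(rng.choice(list("ACGT"), 20)))
            if rng.random() < fraction:
                f[4:7] = "CCG"  # offset -6
                f[10:13] = "CCG"  # offset 0: spacer = 6 - 3 = 3
            flanks.append("".join(f))
        return build_motif_profile(flanks, bg)

    def test_recovers_planted_spacer(self):
        scan = spacer_scan(self._profile_with_planted_pair())
        assert scan.trinucleotide == "CCG"
        assert scan.spacer == 3
        assert scan.offsets == (-6, 0)

    def test_uniform_flanks_score_well_below_planted(self):
        planted = spacer_scan(self._profile_with_planted_pair(fraction=1.0))
        null = spacer_scan(self._profile_with_planted_pair(fraction=0.0))
        assert planted.score >= 3 * null.score

    def test_narrow_window_only_spacer_zero(self):
        bg = genome_background_trinuc(Genome({"c": "ACGT" * 100}))
        prof = build_motif_profile(["ACGTAC"] * 5, bg)  # 2w = 6
        scan = spacer_scan(prof, range(0, 9))
        assert set(scan.per_spacer["spacer"]) == {0}


class TestPlantedGenomeRecovery:
    def test_planted_motif_recovered_end_to_end(self):
        cfg = SimulationConfig(
            seed=21,
            n_eccdna=500,
            planted_motif=PlantedMotif("CCG", 3, 1.0),
            de=DEConfig(n_differential=50),
        )
        ds = simulate(cfg)
        bg = genome_background_trinuc(ds.genome)
        records = [
            EccDNARecord(r.chrom, r.start, r.end)
            for r in ds.population.itertuples(index=False)
        ]
        starts, ends, _ = collect_flanks(ds.genome, records, w=10)
        prof = build_motif_profile(starts + ends, bg)
        scan = spacer_scan(prof)
        assert scan.trinucleotide == "CCG"
        assert scan.spacer == 3

    def test_fraction_zero_leaves_genome_untouched(self):
        cfg = SimulationConfig(seed=3, n_eccdna=200, de=DEConfig(n_differential=50))
        rng = np.random.default_rng(0)
        genome, anns, _ = simulate_genome(cfg, rng)
        pop, _ = simulate_eccdna_population(genome, anns, cfg, rng)
        new_genome, carriers = plant_junction_motif(
            genome, pop, PlantedMotif("CCG", 3, 0.0), rng
        )
        assert not carriers.any()
        assert new_genome.sequences == genome.sequences

    def test_planted_bases_where_expected(self):
        cfg = SimulationConfig(seed=9, n_eccdna=100, de=DEConfig(n_differential=10))
        rng = np.random.default_rng(1)
        genome, anns, _ = simulate_genome(cfg, rng)
        pop, _ = simulate_eccdna_population(genome, anns, cfg, rng)
        new_genome, carriers = plant_junction_motif(
            genome, pop, PlantedMotif("CCG", 3, 1.0), rng
        )
        row = pop.iloc[int(np.flatnonzero(carriers)[0])]
        rec = EccDNARecord(row["chrom"], int(row["start"]), int(row["end"]))
        start_flank, end_flank = extract_flanks(new_genome, rec, w=10)
        # offsets -6 and 0 map to window positions 4 and 10
        assert start_flank[4:7] == "CCG" and start_flank[10:13] == "CCG"
        assert end_flank[4:7] == "CCG" and end_flank[10:13] == "CCG"
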