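"""Determinism and truth-table consistency of the synthetic-data generators."""

import numpy as np
import pytest

from pyronome.simulate import (
    BOUNDARY_PROBES,
    SimConfig,
    simulate_counts,
    simulate_external_table,
    simulate_genome,
    simulate_orthologs,
    simulate_reads,
    simulate_transcriptome,
)


class TestConfig:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(gc_content=1.2)

    def test_positive_lengths(self):
        with pytest.raises(ValueError):
            SimConfig(genome_length=0)


class TestGenome:
    def test_deterministic(self):
        g1, t1 = simulate_genome(SimConfig(seed=7))
        g2, t2 = simulate_genome(SimConfig(seed=7))
        assert g1[0].seq == g2[0].seq and t1 == t2

    def test_seed_changes_output(self):
        g1, _ = simulate_genome(SimConfig(seed=7))
        g2, _ = simulate_genome(SimConfig(seed=8))
        assert g1[0].seq != g2[0].seq

    def test_rate_zero_copies_identical(self):
        g, t = simulate_genome(SimConfig(seed=1, rip_mutation_rate=0.0))
        seq = g[0].seq
        ds, de = t["donor"]
        ms, me = t["mutated"]
        assert seq[ds:de] == seq[ms:me]
        assert t["n_mutations"] == 0

    def test_mutations_only_in_rip_context(self):
        # every donor/copy mismatch is C->T in CpA or G->A in TpG context,
        # judged on the donor (pre-mutation) sequence
        g, t = simulate_genome(SimConfig(seed=3))
        seq = g[0].seq
        ds, de = t["donor"]
        ms, me = t["mutated"]
        donor, copy = seq[ds:de], seq[ms:me]
        n_diff = 0
        for i, (a, b) in enumerate(zip(donor, copy)):
            if a == b:
                continue
            n_diff += 1
            cpa = a == "C" and b == "T" and i + 1 < len(donor) and donor[i + 1] == "A"
            tpg = a == "G" and b == "A" and i > 0 and donor[i - 1] == "T"
            assert cpa or tpg, f"non-RIP mismatch {a}->{b} at {i}"
        assert n_diff == t["n_mutations"] > 0

    def test_rate_one_rule_applied_by_hand(self):
        # at rate 1 every CpA C mutates: CAACA -> TAATA
        g, t = simulate_genome(SimConfig(seed=2, rip_mutation_rate=1.0))
        seq = g[0].seq
        ds, de = t["donor"]
        ms, me = t["mutated"]
        donor, copy = seq[ds:de], seq[ms:me]
        for i in range(len(donor) - 1):
            if donor[i] == "C" and donor[i + 1] == "A":
                assert copy[i] == "T"

    def test_too_short_genome_is_error(self):
        with pytest.raises(ValueError, match="twice"):
            simulate_genome(SimConfig(genome_length=3000, rip_duplication_length=2000))


class TestReads:
    def test_total_bases_match_coverage(self):
        cfg = SimConfig(seed=1, genome_length=20_000, coverage=10)
        g, _ = simulate_genome(cfg)
        reads = simulate_reads(g, cfg)
        assert sum(map(len, reads)) == pytest.approx(10 * 20_000, abs=cfg.read_length)

    def test_deterministic(self):
        cfg = SimConfig(seed=4, genome_length=10_000, coverage=5)
        g, _ = simulate_genome(cfg)
        assert simulate_reads(g, cfg) == simulate_reads(g, cfg)

    def test_coverage_below_one_rejected(self):
        cfg = SimConfig(seed=1, genome_length=10_000, coverage=0.5)
        g, _ = simulate_genome(cfg)
        with pytest.raises(ValueError, match="coverage"):
            simulate_reads(g, cfg)

    def test_error_rate_adds_low_frequency_kmers(self):
        from pyronome.kmer import count_kmers

        cfg0 = SimConfig(seed=6, genome_length=30_000)
        g, _ = simulate_genome(cfg0)
        clean = count_kmers(simulate_reads(g, cfg0), 31)
        noisy = count_kmers(
            simulate_reads(g, SimConfig(seed=6, genome_length=30_000, error_rate=0.01)), 31
        )
        low = lambda h: sum(n for f, n in h.h.items() if f < 10)
        assert low(noisy) > 10 * max(1, low(clean))


class TestTranscriptome:
    def test_truth_consistent_with_bruteforce_filter(self):
        cfg = SimConfig(seed=9)
        g, _ = simulate_genome(cfg)
        _, _, _, coverage, truth = simulate_transcriptome(g, cfg)
        for t in truth:
            expected = t["support"] >= 5 and t["support"] > 0.1 * t["sense_depth"]
            assert t["expect_pass"] == expected
            assert coverage[t["gene"]] == t["sense_depth"]

    def test_boundary_probes_planted(self):
        cfg = SimConfig(seed=9)
        g, _ = simulate_genome(cfg)
        _, _, _, _, truth = simulate_transcriptome(g, cfg)
        probes = {(t["support"], t["sense_depth"]) for t in truth}
        assert set(BOUNDARY_PROBES) <= probes

    def test_deterministic(self):
        cfg = SimConfig(seed=9)
        g, _ = simulate_genome(cfg)
        a = simulate_transcriptome(g, cfg)
        b = simulate_transcriptome(g, cfg)
        assert a[0][0].seq == b[0][0].seq and a[2] == b[2] and a[4] == b[4]


class TestCounts:
    def test_deterministic_and_shape(self):
        cfg = SimConfig(seed=11, n_genes=50)
        cm1, t1 = simulate_counts(cfg)
        cm2, t2 = simulate_counts(cfg)
        assert (cm1.counts == cm2.counts).all() and t1 == t2
        assert cm1.counts.shape == (50, 6)

    def test_planted_genes_elevated_in_sex_only(self):
        cfg = SimConfig(seed=11, n_genes=500)
        cm, truth = simulate_counts(cfg)
        planted = [cm.genes.index(g) for g in truth["planted_genes"]]
        null = [i for i in range(500) if i not in set(planted)]
        sex = cm.counts[:, cm.condition_columns("sex")].mean(axis=1)
        dd = cm.counts[:, cm.condition_columns("DD")].mean(axis=1)
        ratio_planted = np.median(sex[planted] / np.maximum(dd[planted], 1))
        ratio_null = np.median(sex[null] / np.maximum(dd[null], 1))
        assert ratio_planted > 4 * ratio_null

    def test_bad_dispersion_is_error(self):
        with pytest.raises(ValueError, match="dispersion"):
            simulate_counts(SimConfig(seed=1, nb_dispersion=0.0))

    def test_external_table_probabilities_in_unit_interval(self):
        cfg = SimConfig(seed=11, n_genes=100)
        cm, _ = simulate_counts(cfg)
        ext = simulate_external_table(cm)
        assert ext
        for ratio, prob in ext.values():
            assert ratio > 0 and 0.0 <= prob <= 1.0


class TestOrthologs:
    def test_deterministic(self):
        cfg = SimConfig(seed=3, n_genes=40)
        a = simulate_orthologs(cfg, shuffle_fraction=0.5)
        b = simulate_orthologs(cfg, shuffle_fraction=0.5)
        assert a[0] == b[0] and a[1] == b[1] and a[4] == b[4]

    def test_unshuffled_neighbours_all_syntenic(self):
        from pyronome.synteny import reciprocal_best_hits, syntenic_pairs_triplets

        cfg = SimConfig(seed=3, n_genes=40)
        pa, pb, ab, ba, _ = simulate_orthologs(cfg, n_scaffolds=1, spacing=5000)
        m = reciprocal_best_hits(ab, ba)
        n_pairs, _ = syntenic_pairs_triplets(pa, pb, m)
        # every window of 5 consecutive genes (spacing 5 kb, window 20 kb)
        expected = sum(min(4, 40 - 1 - i) for i in range(40))
        assert n_pairs == expected

    def test_full_shuffle_destroys_synteny(self):
        from pyronome.synteny import reciprocal_best_hits, syntenic_pairs_triplets

        cfg = SimConfig(seed=3, n_genes=40)
        pa, pb, ab, ba, _ = simulate_orthologs(cfg, shuffle_fraction=1.0)
        m = reciprocal_best_hits(ab, ba)
        n_pairs, n_triplets = syntenic_pairs_triplets(pa, pb, m)
        assert n_pairs <= 2 and n_triplets == 0
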