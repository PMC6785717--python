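import numpy as np
import pytest

from magcurator import dereplication, quality
from magcurator.dereplication import Catalog, cluster, dereplicate, update_catalog
from magcurator.quality import MAGRecord
from magcurator.sketch_ani import compare, sketch
from magcurator.synthetic_fixtures import (
    generate_genome,
    mutate_to_ani,
    simulate_community,
)

K, S = 21, 10_000


def make_genome(genome_id, sequence, completeness=90.0, contamination=2.0, n50=50_000,
                batch_index=0):
    rec = MAGRecord(genome_id, completeness, contamination, n50, batch_index)
    return rec, sketch([sequence], genome_id, k=K, s=S)


def community_genomes(seed=0, **kwargs):
    com = simulate_community(seed=seed, **kwargs)
    return [
        (g.record, sketch([g.sequence], g.record.genome_id, k=K, s=S))
        for g in com.genomes
    ], com


class TestCluster:
    def test_single_genome_singleton(self):
        g = make_genome("a", generate_genome(5000, seed=0))
        cs = cluster([g], 95)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].members == ("a",)
        assert cs.clusters[0].representative_id == "a"

    def test_empty_input(self):
        assert cluster([], 95).clusters == ()

    def test_threshold_straddles_simulated_ani(self):
        base = generate_genome(50_000, seed=1)
        a = make_genome("a", base)
        b = make_genome("b", mutate_to_ani(base, 99.5, seed=2), completeness=85)
        assert len(cluster([a, b], 99).clusters) == 1
        assert len(cluster([a, b], 99.9).clusters) == 2

    @pytest.mark.parametrize("seed", [0, 1])
    def test_greedy_contract_on_random_sets(self, seed):
        """Every member is above-threshold to its representative and no
        member outscores its representative (brute-force pairwise check)."""
        genomes, _ = community_genomes(
            seed=seed, n_species=5, strains_per_species=3, genome_length=10_000
        )
        by_id = {rec.genome_id: (rec, sk) for rec, sk in genomes}
        cs = cluster(genomes, 99)
        for c in cs.clusters:
            rep_rec, rep_sk = by_id[c.representative_id]
            for member in c.members:
                if member == c.representative_id:
                    continue
                rec, sk = by_id[member]
                assert compare(sk, rep_sk).ani_percent > 99
                assert quality.bin_score(rec) <= quality.bin_score(rep_rec)

    def test_single_linkage_mode_merges_chains(self):
        genomes, _ = community_genomes(
            seed=3, n_species=4, strains_per_species=3, genome_length=10_000
        )
        greedy = cluster(genomes, 99, method="greedy")
        linked = cluster(genomes, 99, method="single_linkage")
        assert len(linked.clusters) <= len(greedy.clusters)
        assert sorted(m for c in linked.clusters for m in c.members) == sorted(
            g[0].genome_id for g in genomes
        )


class TestDereplicate:
    def test_all_fail_prefilter(self):
        g = make_genome("a", generate_genome(5000, seed=4), completeness=70)
        assert dereplicate([g], 95) == []

    def test_winner_rule_on_identical_genomes(self):
        seq = generate_genome(5000, seed=5)
        hi = make_genome("hi", seq, completeness=90)
        lo = make_genome("lo", seq, completeness=80)
        winners = dereplicate([hi, lo], 95)
        assert [w.genome_id for w in winners] == ["hi"]

    def test_species_count_recovered(self):
        # 10 species x 3 strains, all pairwise within-species ANI >= 96
        genomes, com = community_genomes(
            seed=6, n_species=10, strains_per_species=3,
            genome_length=20_000, strain_ani=98.2,
        )
        winners = dereplicate(genomes, 95)
        assert len(winners) == 10
        # one winner per true species
        species_of = {
            g.record.genome_id: g.species_index for g in com.genomes
        }
        assert len({species_of[w.genome_id] for w in winners}) == 10

    def test_idempotent(self):
        genomes, _ = community_genomes(
            seed=7, n_species=5, strains_per_species=2, genome_length=10_000
        )
        winners = dereplicate(genomes, 95)
        by_id = {rec.genome_id: (rec, sk) for rec, sk in genomes}
        again = dereplicate([by_id[w.genome_id] for w in winners], 95)
        assert [w.genome_id for w in again] == [w.genome_id for w in winners]

    def test_species_clusters_fewer_than_strain_clusters(self):
        genomes, _ = community_genomes(seed=8, n_species=6, strains_per_species=3,
                                       genome_length=10_000)
        assert len(dereplicate(genomes, 95)) <= len(dereplicate(genomes, 99))


def brute_force_survivors(genomes, threshold=99.0):
    """Independent oracle: a genome survives iff no above-threshold neighbour
    outscores it (ties broken toward earlier arrival, then id)."""
    order = {
        rec.genome_id: (-quality.bin_score(rec), rec.batch_index, rec.genome_id)
        for rec, _ in genomes
    }
    survivors = set()
    for rec, sk in genomes:
        beaten = False
        for other_rec, other_sk in genomes:
            if other_rec.genome_id == rec.genome_id:
                continue
            if compare(sk, other_sk).ani_percent > threshold:
                if order[other_rec.genome_id] < order[rec.genome_id]:
                    beaten = True
                    break
        if not beaten:
            survivors.add(rec.genome_id)
    return survivors


class TestUpdateCatalog:
    def test_empty_catalog_takes_batch(self):
        genomes, _ = community_genomes(seed=9, n_species=3, strains_per_species=1,
                                       genome_length=10_000)
        catalog = update_catalog(Catalog(), genomes)
        assert set(catalog.records) == {g[0].genome_id for g in genomes}
        assert catalog.history == []

    def test_better_newcomer_replaces_and_logs(self):
        base = generate_genome(30_000, seed=10)
        old = make_genome("old", base, completeness=90, contamination=2, n50=50_000)
        new = make_genome(
            "new", mutate_to_ani(base, 99.8, seed=11),
            completeness=95, contamination=2, n50=50_000, batch_index=1,
        )
        catalog = update_catalog(Catalog(), [old])
        catalog = update_catalog(catalog, [new])
        assert set(catalog.records) == {"new"}
        (event,) = catalog.history
        assert (event.old_id, event.new_id) == ("old", "new")
        assert event.ani > 99
        assert event.new_score > event.old_score

    def test_worse_newcomer_dropped_silently(self):
        base = generate_genome(30_000, seed=12)
        old = make_genome("old", base, completeness=95)
        new = make_genome("new", mutate_to_ani(base, 99.8, seed=13), completeness=85,
                          batch_index=1)
        catalog = update_catalog(update_catalog(Catalog(), [old]), [new])
        assert set(catalog.records) == {"old"}
        assert catalog.history == []

    def test_score_tie_keeps_incumbent(self):
        base = generate_genome(30_000, seed=14)
        old = make_genome("old", base)
        new = make_genome("new", base, batch_index=1)  # identical stats
        catalog = update_catalog(update_catalog(Catalog(), [old]), [new])
        assert set(catalog.records) == {"old"}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_streamed_catalog_matches_bruteforce_optimum(self, seed):
        """Batch-by-batch updates over a shuffled 30-genome stream end at the
        best-score-per-strain-neighbourhood optimum."""
        genomes, _ = community_genomes(
            seed=seed, n_species=10, strains_per_species=3, genome_length=20_000
        )
        rng = np.random.default_rng(seed)
        shuffled = [genomes[i] for i in rng.permutation(len(genomes))]
        catalog = Catalog()
        for start in range(0, len(shuffled), 5):
            catalog = update_catalog(catalog, shuffled[start : start + 5])
        assert set(catalog.records) == brute_force_survivors(genomes)
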