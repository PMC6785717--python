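import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magcurator.errors import ValidationError
from magcurator.formats_io import HitRow
from magcurator.taxonomy_cascade import (
    Method,
    PhyloConfidence,
    Rank,
    RankVote,
    TaxonomicEvidence,
    assign,
    assign_batch,
    best_hits_per_query,
    evidence_from_row,
    evidence_to_row,
    summarize_hits,
)


def hit(query, subject, identity, bitscore=400.0, evalue=1e-50):
    return HitRow(query, subject, identity, 200, evalue, bitscore)


def evidence(genome_id="g", **kwargs):
    return TaxonomicEvidence(genome_id=genome_id, **kwargs)


def vote(rank, taxon, proportion, identity):
    return RankVote(rank, taxon, proportion, identity)


TAXMAP = {
    f"sp{i}": {"species": f"Species {tag}", "genus": f"Genus {tag[0]}"}
    for i, tag in enumerate(["Xx", "Xy", "Ga", "Gb", "Gc", "Hz"])
}


class TestBestHits:
    def test_highest_bitscore_wins(self):
        hits = [hit("q1", "sp0", 90, bitscore=100), hit("q1", "sp1", 80, bitscore=300)]
        assert best_hits_per_query(hits)["q1"].subject_id == "sp1"

    def test_ties_broken_by_evalue_then_subject(self):
        hits = [
            hit("q1", "spB", 90, bitscore=300, evalue=1e-40),
            hit("q1", "spA", 90, bitscore=300, evalue=1e-50),
        ]
        assert best_hits_per_query(hits)["q1"].subject_id == "spA"
        hits = [
            hit("q1", "spB", 90, bitscore=300),
            hit("q1", "spA", 90, bitscore=300),
        ]
        assert best_hits_per_query(hits)["q1"].subject_id == "spA"


class TestSummarizeHits:
    def test_unanimous_species(self):
        hits = [hit(f"q{i}", "sp0", 96.0) for i in range(10)]
        v = summarize_hits(hits, TAXMAP, Rank.species)
        assert v.taxon == "Species Xx"
        assert v.proportion == 1.0
        assert v.mean_identity == pytest.approx(0.96)

    def test_hand_tallied_majority(self):
        # 6 of 10 best hits map to genus "Genus G" (mean identity 91%), 4 elsewhere
        hits = [hit(f"q{i}", ["sp2", "sp3", "sp4"][i % 3], 91.0) for i in range(6)]
        hits += [hit(f"r{i}", "sp5", 80.0) for i in range(4)]
        v = summarize_hits(hits, TAXMAP, Rank.genus)
        assert v.taxon == "Genus G"
        assert v.proportion == pytest.approx(0.6)
        assert v.mean_identity == pytest.approx(0.91)

    def test_empty_hits(self):
        v = summarize_hits([], TAXMAP, Rank.species)
        assert (v.taxon, v.proportion, v.mean_identity) == ("", 0.0, 0.0)

    def test_unmapped_subjects_excluded_from_denominator(self):
        hits = [hit("q1", "sp0", 96.0), hit("q2", "unknown_subject", 96.0)]
        v = summarize_hits(hits, TAXMAP, Rank.species)
        assert v.proportion == 1.0


class TestAssign:
    def test_rule_1_species_vote(self):
        ev = evidence(votes={Rank.species: vote(Rank.species, "X", 0.95, 0.96)})
        a = assign(ev)
        assert (a.rank, a.method, a.rule_index) == (Rank.species, Method.diamond, 1)
        assert a.taxon == "X"

    def test_rule_1_boundaries_inclusive(self):
        at = evidence(votes={Rank.species: vote(Rank.species, "X", 0.9, 0.95)})
        assert assign(at).rule_index == 1
        under_p = evidence(votes={Rank.species: vote(Rank.species, "X", 0.8999, 0.95)})
        assert assign(under_p).rule_index != 1
        under_i = evidence(votes={Rank.species: vote(Rank.species, "X", 0.9, 0.9499)})
        assert assign(under_i).rule_index != 1

    def test_rule_2_sourmash_preempts_weak_species_vote(self):
        ev = evidence(
            votes={Rank.species: vote(Rank.species, "X", 0.5, 0.96)},
            sourmash_score=0.85,
            sourmash_taxon="Y",
        )
        a = assign(ev)
        assert (a.rank, a.method, a.rule_index) == (Rank.species, Method.sourmash, 2)
        assert a.taxon == "Y"

    def test_rule_2_boundary_inclusive(self):
        assert assign(evidence(sourmash_score=0.8, sourmash_taxon="Y")).rule_index == 2
        assert assign(evidence(sourmash_score=0.7999)).rule_index != 2

    def test_rule_3_requires_high_confidence(self):
        ev = evidence(
            phylo_level=Rank.species, phylo_taxon="Z",
            phylo_confidence=PhyloConfidence.high,
        )
        assert assign(ev).rule_index == 3
        medium = evidence(
            phylo_level=Rank.species, phylo_taxon="Z",
            phylo_confidence=PhyloConfidence.medium,
        )
        # medium+species matches no placement rule: falls through to rule 12
        assert assign(medium).rule_index == 12

    def test_rule_5_medium_genus_placement(self):
        ev = evidence(
            phylo_level=Rank.genus, phylo_taxon="G",
            phylo_confidence=PhyloConfidence.medium,
        )
        a = assign(ev)
        assert (a.rank, a.method, a.rule_index) == (Rank.genus, Method.phylophlan, 5)

    def test_low_confidence_never_places(self):
        ev = evidence(
            phylo_level=Rank.genus, phylo_taxon="G",
            phylo_confidence=PhyloConfidence.low,
        )
        assert assign(ev).rule_index == 12

    def test_rule_12_fallthrough(self):
        ev = evidence(checkm_lineage="k__Bacteria;p__Firmicutes")
        a = assign(ev)
        assert (a.rank, a.method, a.rule_index) == (None, Method.checkm, 12)
        assert a.taxon == "k__Bacteria;p__Firmicutes"


# rank fineness for the monotonicity property: smaller index = finer
_FINENESS = {
    Rank.species: 0, Rank.genus: 1, Rank.family: 2,
    Rank.order: 3, Rank.class_: 4, Rank.phylum: 5, None: 6,
}

_proportion = st.floats(0, 1)
_conf = st.sampled_from(list(PhyloConfidence))
_level = st.sampled_from(list(Rank) + [None])


@st.composite
def random_evidence(draw):
    votes = {}
    for rank in Rank:
        p = draw(_proportion)
        votes[rank] = RankVote(rank, "T" if p > 0 else "", p, draw(_proportion))
    level = draw(_level)
    return TaxonomicEvidence(
        genome_id="g",
        votes=votes,
        sourmash_score=draw(_proportion),
        sourmash_taxon="S",
        phylo_level=level,
        phylo_taxon="P" if level else "",
        phylo_confidence=draw(_conf),
        checkm_lineage="k__Bacteria",
    )


class TestCascadeProperties:
    @settings(derandomize=True, max_examples=200)
    @given(random_evidence())
    def test_exhaustive(self, ev):
        a = assign(ev)
        assert 1 <= a.rule_index <= 12

    @settings(derandomize=True, max_examples=200)
    @given(random_evidence(), st.floats(0.01, 0.5))
    def test_strengthening_sourmash_never_coarsens(self, ev, delta):
        before = _FINENESS[assign(ev).rank]
        stronger = TaxonomicEvidence(
            genome_id=ev.genome_id,
            votes=ev.votes,
            sourmash_score=min(1.0, ev.sourmash_score + delta),
            sourmash_taxon=ev.sourmash_taxon,
            phylo_level=ev.phylo_level,
            phylo_taxon=ev.phylo_taxon,
            phylo_confidence=ev.phylo_confidence,
            checkm_lineage=ev.checkm_lineage,
        )
        assert _FINENESS[assign(stronger).rank] <= before

    @settings(derandomize=True, max_examples=200)
    @given(random_evidence(), st.floats(0.01, 0.5), st.floats(0.01, 0.5))
    def test_strengthening_species_vote_never_coarsens(self, ev, dp, di):
        before = _FINENESS[assign(ev).rank]
        old = ev.votes[Rank.species]
        votes = dict(ev.votes)
        votes[Rank.species] = RankVote(
            Rank.species, "T", min(1.0, old.proportion + dp),
            min(1.0, old.mean_identity + di),
        )
        stronger = TaxonomicEvidence(
            genome_id=ev.genome_id,
            votes=votes,
            sourmash_score=ev.sourmash_score,
            sourmash_taxon=ev.sourmash_taxon,
            phylo_level=ev.phylo_level,
            phylo_taxon=ev.phylo_taxon,
            phylo_confidence=ev.phylo_confidence,
            checkm_lineage=ev.checkm_lineage,
        )
        assert _FINENESS[assign(stronger).rank] <= before


class TestAssignBatch:
    def test_tally(self):
        rows = [
            evidence("g1", votes={Rank.species: vote(Rank.species, "X", 0.95, 0.97)}),
            evidence("g2", sourmash_score=0.9, sourmash_taxon="Y"),
            evidence("g3", checkm_lineage="k__Bacteria"),
        ]
        assignments, tally = assign_batch(rows)
        assert [a.rule_index for a in assignments] == [1, 2, 12]
        assert tally == {1: 1, 2: 1, 12: 1}

    def test_duplicate_ids_rejected(self):
        rows = [evidence("g1"), evidence("g1")]
        with pytest.raises(ValidationError, match="g1"):
            assign_batch(rows)


class TestEvidenceSerialization:
    def test_row_roundtrip(self):
        ev = evidence(
            "g9",
            votes={Rank.genus: vote(Rank.genus, "Prevotella", 0.92, 0.93)},
            sourmash_score=0.4,
            phylo_level=Rank.class_,
            phylo_taxon="Clostridia",
            phylo_confidence=PhyloConfidence.medium,
            checkm_lineage="o__Clostridiales",
        )
        back = evidence_from_row(evidence_to_row(ev))
        assert back == ev
        assert assign(back) == assign(ev)
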