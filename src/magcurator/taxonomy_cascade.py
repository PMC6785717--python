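"""Rule-cascade taxonomic assignment for draft genomes.

Evidence from four independent sources is fused by an ordered if/else
cascade: (i) protein-homology votes — for each predicted protein the best
database hit contributes a vote for a taxon at each rank, summarised as the
modal taxon's vote proportion and the mean amino-acid identity of its
supporting hits; (ii) a whole-genome sketch-search score on [0, 1];
(iii) a phylogenetic placement (level + categorical confidence); and (iv) a
marker-gene lineage used as the fallback.  Rules are evaluated strictly in
order and the first satisfied rule wins, so an assignment always carries the
rule index and method that produced it.  The cascade is exhaustive: rule 12
(the marker-lineage fallback) always fires if nothing else does.

Default thresholds::

    rule  1  species vote ≥0.9 and identity ≥0.95   → species (homology)
    rule  2  sketch score ≥0.8                      → species (sketch)
    rule  3  placement high, level genus/species    → that level (placement)
    rule  4  genus vote ≥0.9 and identity ≥0.9      → genus (homology)
    rule  5  placement high/medium, level genus     → genus (placement)
    rule  6  placement high/medium, level family    → family (placement)
    rule  7  family vote ≥0.8 and identity ≥0.6     → family (homology)
    rule  8  placement high/medium, level order     → order (placement)
    rule  9  order vote ≥0.6 and identity ≥0.6      → order (homology)
    rule 10  placement high/medium, level class     → class (placement)
    rule 11  placement high/medium, level phylum    → phylum (placement)
    rule 12  otherwise                              → marker lineage
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

from .errors import ValidationError
from .formats_io import HitRow


class Rank(enum.Enum):
    species = "species"
    genus = "genus"
    family = "family"
    order = "order"
    class_ = "class"
    phylum = "phylum"


class Method(enum.Enum):
    diamond = "diamond"
    sourmash = "sourmash"
    phylophlan = "phylophlan"
    checkm = "checkm"


class PhyloConfidence(enum.Enum):
    high = "high"
    medium = "medium"
    low = "low"
    none = "none"


@dataclass(frozen=True)
class RankVote:
    """Best-supported taxon at one rank from per-protein best hits."""

    rank: Rank
    taxon: str
    proportion: float
    mean_identity: float

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ValidationError(f"vote proportion {self.proportion} outside [0, 1]")
        if not 0.0 <= self.mean_identity <= 1.0:
            raise ValidationError(f"mean identity {self.mean_identity} outside [0, 1]")
        if self.proportion > 0 and not self.taxon:
            raise ValidationError("nonzero vote proportion with empty taxon")


def empty_vote(rank: Rank) -> RankVote:
    return RankVote(rank, "", 0.0, 0.0)


@dataclass(frozen=True)
class TaxonomicEvidence:
    genome_id: str
    votes: dict[Rank, RankVote] = field(default_factory=dict)
    sourmash_score: float = 0.0
    sourmash_taxon: str = ""
    phylo_level: Rank | None = None
    phylo_taxon: str = ""
    phylo_confidence: PhyloConfidence = PhyloConfidence.none
    checkm_lineage: str = ""

    def __post_init__(self):
        if not self.genome_id:
            raise ValidationError("evidence with empty genome_id")
        if not 0.0 <= self.sourmash_score <= 1.0:
            raise ValidationError(
                f"{self.genome_id}: sourmash score {self.sourmash_score} outside [0, 1]"
            )
        votes = dict(self.votes)
        for rank in Rank:
            votes.setdefault(rank, empty_vote(rank))
        object.__setattr__(self, "votes", votes)


@dataclass(frozen=True)
class Assignment:
    """One genome's final call.  ``rank`` is ``None`` only for the rule-12
    marker-lineage fallback, whose taxon is a full lineage string rather than
    a single-rank name."""

    genome_id: str
    rank: Rank | None
    taxon: str
    method: Method
    rule_index: int


@dataclass(frozen=True)
class CascadeThresholds:
    """The vote/identity/sketch thresholds of the cascade; defaults as printed
    in the module docstring."""

    species_proportion: float = 0.9
    species_identity: float = 0.95
    sourmash: float = 0.8
    genus_proportion: float = 0.9
    genus_identity: float = 0.9
    family_proportion: float = 0.8
    family_identity: float = 0.6
    order_proportion: float = 0.6
    order_identity: float = 0.6


DEFAULT_THRESHOLDS = CascadeThresholds()


def best_hits_per_query(hits: list[HitRow]) -> dict[str, HitRow]:
    """Best hit per query: highest bitscore, ties by lowest e-value then
    lexicographic subject id."""
    best: dict[str, HitRow] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or (-hit.bitscore, hit.evalue, hit.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[hit.query_id] = hit
    return best


def summarize_hits(
    hits: list[HitRow],
    taxonomy_map: dict[str, dict[str, str]],
    rank: Rank,
) -> RankVote:
    """Summarise per-protein best hits into a :class:`RankVote` at ``rank``.

    The denominator is the number of queries whose best hit maps to a
    nonempty taxon at this rank; the modal taxon's supporters define the
    proportion and the mean identity (identity on [0, 1]).  Modal ties break
    lexicographically for determinism.
    """
    best = best_hits_per_query(hits)
    taxon_of: dict[str, str] = {}
    for qid, hit in best.items():
        lineage = taxonomy_map.get(hit.subject_id)
        if lineage:
            taxon = lineage.get(rank.value, "")
            if taxon:
                taxon_of[qid] = taxon
    if not taxon_of:
        return empty_vote(rank)
    counts = Counter(taxon_of.values())
    top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    modal_taxon = min((t for t, c in counts.items() if c == top[1]))
    supporters = [
        best[qid].percent_identity / 100.0
        for qid, taxon in taxon_of.items()
        if taxon == modal_taxon
    ]
    return RankVote(
        rank=rank,
        taxon=modal_taxon,
        proportion=counts[modal_taxon] / len(taxon_of),
        mean_identity=sum(supporters) / len(supporters),
    )


def _vote(ev: TaxonomicEvidence, rank: Rank) -> RankVote:
    return ev.votes.get(rank, empty_vote(rank))


def assign(
    evidence: TaxonomicEvidence,
    thresholds: CascadeThresholds = DEFAULT_THRESHOLDS,
) -> Assignment:
    """Run the cascade on one genome's evidence; never returns 'no assignment'."""
    t = thresholds
    ev = evidence
    gid = ev.genome_id
    conf = ev.phylo_confidence
    hm = conf in (PhyloConfidence.high, PhyloConfidence.medium)

    sv = _vote(ev, Rank.species)
    if sv.proportion >= t.species_proportion and sv.mean_identity >= t.species_identity:
        return Assignment(gid, Rank.species, sv.taxon, Method.diamond, 1)
    if ev.sourmash_score >= t.sourmash:
        return Assignment(gid, Rank.species, ev.sourmash_taxon, Method.sourmash, 2)
    if conf is PhyloConfidence.high and ev.phylo_level in (Rank.genus, Rank.species):
        return Assignment(gid, ev.phylo_level, ev.phylo_taxon, Method.phylophlan, 3)
    gv = _vote(ev, Rank.genus)
    if gv.proportion >= t.genus_proportion and gv.mean_identity >= t.genus_identity:
        return Assignment(gid, Rank.genus, gv.taxon, Method.diamond, 4)
    if hm and ev.phylo_level is Rank.genus:
        return Assignment(gid, Rank.genus, ev.phylo_taxon, Method.phylophlan, 5)
    if hm and ev.phylo_level is Rank.family:
        return Assignment(gid, Rank.family, ev.phylo_taxon, Method.phylophlan, 6)
    fv = _vote(ev, Rank.family)
    if fv.proportion >= t.family_proportion and fv.mean_identity >= t.family_identity:
        return Assignment(gid, Rank.family, fv.taxon, Method.diamond, 7)
    if hm and ev.phylo_level is Rank.order:
        return Assignment(gid, Rank.order, ev.phylo_taxon, Method.phylophlan, 8)
    ov = _vote(ev, Rank.order)
    if ov.proportion >= t.order_proportion and ov.mean_identity >= t.order_identity:
        return Assignment(gid, Rank.order, ov.taxon, Method.diamond, 9)
    if hm and ev.phylo_level is Rank.class_:
        return Assignment(gid, Rank.class_, ev.phylo_taxon, Method.phylophlan, 10)
    if hm and ev.phylo_level is Rank.phylum:
        return Assignment(gid, Rank.phylum, ev.phylo_taxon, Method.phylophlan, 11)
    return Assignment(gid, None, ev.checkm_lineage, Method.checkm, 12)


def assign_batch(
    evidence_rows: list[TaxonomicEvidence],
    thresholds: CascadeThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[Assignment], dict[int, int]]:
    """Assign every genome and tally how often each rule fired."""
    ids = [e.genome_id for e in evidence_rows]
    dupes = sorted({g for g, c in Counter(ids).items() if c > 1})
    if dupes:
        raise ValidationError(f"duplicate genome ids in evidence: {dupes}")
    assignments = [assign(e, thresholds) for e in evidence_rows]
    tally = dict(Counter(a.rule_index for a in assignments))
    return assignments, tally


# ---------------------------------------------------------------------------
# evidence TSV (one row per genome)

_RANK_COLS = [r.value if r is not Rank.class_ else "class" for r in Rank]

EVIDENCE_COLUMNS = (
    ["genome_id"]
    + [f"{r}_{f}" for r in _RANK_COLS for f in ("taxon", "proportion", "identity")]
    + [
        "sourmash_score",
        "sourmash_taxon",
        "phylo_level",
        "phylo_taxon",
        "phylo_confidence",
        "checkm_lineage",
    ]
)


def _rank_from_column(name: str) -> Rank:
    return Rank.class_ if name == "class" else Rank(name)


def evidence_to_row(ev: TaxonomicEvidence) -> dict:
    row: dict = {"genome_id": ev.genome_id}
    for col in _RANK_COLS:
        vote = ev.votes[_rank_from_column(col)]
        row[f"{col}_taxon"] = vote.taxon
        row[f"{col}_proportion"] = vote.proportion
        row[f"{col}_identity"] = vote.mean_identity
    row["sourmash_score"] = ev.sourmash_score
    row["sourmash_taxon"] = ev.sourmash_taxon
    row["phylo_level"] = "" if ev.phylo_level is None else (
        "class" if ev.phylo_level is Rank.class_ else ev.phylo_level.value
    )
    row["phylo_taxon"] = ev.phylo_taxon
    row["phylo_confidence"] = ev.phylo_confidence.value
    row["checkm_lineage"] = ev.checkm_lineage
    return row


def evidence_from_row(row: dict) -> TaxonomicEvidence:
    votes = {}
    for col in _RANK_COLS:
        rank = _rank_from_column(col)
        votes[rank] = RankVote(
            rank=rank,
            taxon=str(row.get(f"{col}_taxon", "") or ""),
            proportion=float(row.get(f"{col}_proportion", 0.0) or 0.0),
            mean_identity=float(row.get(f"{col}_identity", 0.0) or 0.0),
        )
    level_raw = str(row.get("phylo_level", "") or "")
    level = _rank_from_column(level_raw) if level_raw else None
    conf_raw = str(row.get("phylo_confidence", "none") or "none")
    return TaxonomicEvidence(
        genome_id=str(row["genome_id"]),
        votes=votes,
        sourmash_score=float(row.get("sourmash_score", 0.0) or 0.0),
        sourmash_taxon=str(row.get("sourmash_taxon", "") or ""),
        phylo_level=level,
        phylo_taxon=str(row.get("phylo_taxon", "") or ""),
        phylo_confidence=PhyloConfidence(conf_raw),
        checkm_lineage=str(row.get("checkm_lineage", "") or ""),
    )
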