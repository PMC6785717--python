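"""ANI-threshold dereplication and the continuous replace-if-better catalog.

Dereplication reduces a genome collection to one representative per ANI
cluster.  The clustering here is greedy and score-ordered: genomes are
visited in descending bin-score order and each either joins the first
existing representative it matches above the ANI threshold or founds a new
cluster.  By construction every representative has the maximal bin score in
its cluster — the "highest scoring genome per cluster is retained" contract —
and the procedure is deterministic (score ties broken by genome id).

A single-linkage mode (connected components of the above-threshold ANI
graph) is available for sensitivity checks; representatives are still the
highest-scoring member of each component.

The continuous catalog models a rolling assembly effort: new genomes arrive
in batches, and a newcomer with >99% ANI to a catalog member (the same
strain) replaces it if its quality statistics — summarised by the bin
score — are better.  Replacements are logged so accession history is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from . import quality
from .errors import ValidationError
from .quality import MAGRecord
from .sketch_ani import GenomeSketch, compare

STRAIN_ANI = 99.0
SPECIES_ANI = 95.0


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    members: tuple[str, ...]
    representative_id: str


@dataclass(frozen=True)
class ClusterSet:
    threshold_ani: float
    clusters: tuple[Cluster, ...]

    @property
    def sizes(self) -> list[int]:
        return [len(c.members) for c in self.clusters]

    def membership_rows(self) -> list[dict]:
        rows = []
        for c in self.clusters:
            for m in c.members:
                rows.append(
                    {
                        "cluster_id": c.cluster_id,
                        "genome_id": m,
                        "is_representative": m == c.representative_id,
                    }
                )
        return rows


@dataclass
class ReplacementEvent:
    old_id: str
    new_id: str
    ani: float
    old_score: float
    new_score: float


@dataclass
class Catalog:
    """Current members of the continuous catalog plus replacement history."""

    records: dict[str, tuple[MAGRecord, GenomeSketch]] = field(default_factory=dict)
    history: list[ReplacementEvent] = field(default_factory=list)
    ani_model: str = "poisson"


def _ani(a: GenomeSketch, b: GenomeSketch, model: str = "poisson") -> float:
    return compare(a, b, model).ani_percent


def _score_order(genomes):
    return sorted(
        genomes, key=lambda g: (-quality.bin_score(g[0]), g[0].genome_id)
    )


def cluster(
    genomes: list[tuple[MAGRecord, GenomeSketch]],
    threshold_ani: float,
    method: str = "greedy",
    ani_model: str = "poisson",
) -> ClusterSet:
    """Partition genomes into ANI clusters (membership requires ANI strictly
    above ``threshold_ani`` to the representative)."""
    if not 80.0 < threshold_ani <= 100.0:
        raise ValidationError(f"ANI threshold {threshold_ani} outside (80, 100]")
    if not genomes:
        return ClusterSet(threshold_ani, ())
    ids = [g[0].genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate genome ids in dereplication input")

    if method == "greedy":
        reps: list[tuple[MAGRecord, GenomeSketch]] = []
        members: dict[str, list[str]] = {}
        for rec, sk in _score_order(genomes):
            for rep_rec, rep_sk in reps:
                if _ani(sk, rep_sk, ani_model) > threshold_ani:
                    members[rep_rec.genome_id].append(rec.genome_id)
                    break
            else:
                reps.append((rec, sk))
                members[rec.genome_id] = [rec.genome_id]
        clusters = tuple(
            Cluster(f"cluster_{i:05d}", tuple(sorted(members[r.genome_id])), r.genome_id)
            for i, (r, _) in enumerate(reps, start=1)
        )
        return ClusterSet(threshold_ani, clusters)

    if method == "single_linkage":
        graph = nx.Graph()
        graph.add_nodes_from(ids)
        for i, (_, ska) in enumerate(genomes):
            for _, skb in genomes[i + 1 :]:
                if _ani(ska, skb, ani_model) > threshold_ani:
                    graph.add_edge(ska.genome_id, skb.genome_id)
        by_id = {rec.genome_id: rec for rec, _ in genomes}
        comps = sorted(nx.connected_components(graph), key=min)
        clusters = []
        for i, comp in enumerate(comps, start=1):
            rep = min(comp, key=lambda g: (-quality.bin_score(by_id[g]), g))
            clusters.append(Cluster(f"cluster_{i:05d}", tuple(sorted(comp)), rep))
        return ClusterSet(threshold_ani, tuple(clusters))

    raise ValidationError(f"unknown clustering method {method!r}")


def dereplicate(
    genomes: list[tuple[MAGRecord, GenomeSketch]],
    threshold_ani: float = SPECIES_ANI,
    method: str = "greedy",
    ani_model: str = "poisson",
) -> list[MAGRecord]:
    """Prefilter (completeness ≥80, contamination ≤10), cluster at the ANI
    threshold, and return one representative per cluster sorted by genome id."""
    keep_ids = {r.genome_id for r in quality.prefilter([g[0] for g in genomes])}
    kept = [g for g in genomes if g[0].genome_id in keep_ids]
    cs = cluster(kept, threshold_ani, method=method, ani_model=ani_model)
    by_id = {rec.genome_id: rec for rec, _ in kept}
    return sorted(
        (by_id[c.representative_id] for c in cs.clusters), key=lambda r: r.genome_id
    )


def update_catalog(
    catalog: Catalog,
    batch: list[tuple[MAGRecord, GenomeSketch]],
    strain_ani: float = STRAIN_ANI,
) -> Catalog:
    """Fold one batch of (prefiltered) genomes into the catalog.

    Each newcomer is compared against current members: with no match above
    the strain threshold it is inserted; otherwise the highest-bin-score
    genome among {matched incumbents, newcomer} survives.  On a score tie the
    incumbent wins, keeping accessioned ids stable.  Mutates and returns
    ``catalog``.
    """
    for rec, sk in batch:
        matches = [
            (mid, _ani(sk, msk, catalog.ani_model))
            for mid, (_, msk) in catalog.records.items()
        ]
        matches = [(mid, ani) for mid, ani in matches if ani > strain_ani]
        if not matches:
            catalog.records[rec.genome_id] = (rec, sk)
            continue
        new_score = quality.bin_score(rec)
        best_incumbent = max(
            matches, key=lambda m: quality.bin_score(catalog.records[m[0]][0])
        )
        best_inc_score = quality.bin_score(catalog.records[best_incumbent[0]][0])
        if new_score > best_inc_score:
            for mid, ani in matches:
                old_rec = catalog.records.pop(mid)[0]
                catalog.history.append(
                    ReplacementEvent(
                        old_id=mid,
                        new_id=rec.genome_id,
                        ani=ani,
                        old_score=quality.bin_score(old_rec),
                        new_score=new_score,
                    )
                )
            catalog.records[rec.genome_id] = (rec, sk)
        # else: incumbents retained, newcomer dropped, no event
    return catalog
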