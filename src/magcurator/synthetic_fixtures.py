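"""Seeded generators for every synthetic input the toolkit consumes.

Each generator is a pure function of its parameters and an integer seed
(NumPy ``default_rng``; no global random state), so fixtures regenerate
bit-identically and every fixture carries its own ground truth: mutation
targets, indel positions, intended cascade rules, true species memberships.

Simulated genomes are i.i.d. base sequences at a target GC — no repeats,
operons or synteny.  That is deliberate: every consumer here (sketching,
dereplication, ORF scanning, richness counting) depends only on k-mer and
codon statistics, not on higher-order genome organisation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ideel_diag
from .errors import ValidationError
from .quality import MAGRecord
from .taxonomy_cascade import (
    PhyloConfidence,
    Rank,
    RankVote,
    TaxonomicEvidence,
)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genomes


def generate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """An i.i.d. random genome of ``length`` bases at the target GC content."""
    if length < 1000:
        raise ValidationError(f"genome length {length} < 1 kb")
    if not 0.0 < gc < 1.0:
        raise ValidationError(f"GC {gc} outside (0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_rng(seed).choice(_BASES, size=length, p=p))


def mutate_to_ani(sequence: str, target_ani: float, seed: int = 0) -> str:
    """Substitute bases i.i.d. at rate (100 − target_ani)/100 (no indels), so
    the true ANI of the pair is ``target_ani`` in expectation."""
    if not 80.0 <= target_ani <= 100.0:
        raise ValidationError(f"target ANI {target_ani} outside [80, 100]")
    rate = (100.0 - target_ani) / 100.0
    if rate == 0.0:
        return sequence
    rng = _rng(seed)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = np.where(rng.random(arr.size) < rate)[0]
    # replace each hit base by one of the three alternatives, uniformly
    alternatives = {
        ord(b): np.frombuffer(
            "ACGT".replace(b, "").encode("ascii"), dtype=np.uint8
        )
        for b in "ACGT"
    }
    for i in hit:
        alts = alternatives.get(int(arr[i]))
        if alts is not None:  # leave N untouched
            arr[i] = alts[rng.integers(3)]
    return arr.tobytes().decode("ascii")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def compute_n50(lengths: list[int]) -> int:
    """Contig length at which the cumulative sorted-descending length crosses
    half the total."""
    if not lengths:
        raise ValidationError("no contig lengths")
    total = sum(lengths)
    acc = 0
    for n in sorted(lengths, reverse=True):
        acc += n
        if 2 * acc >= total:
            return n
    raise AssertionError("unreachable")


def fragment_assembly(
    sequence: str, target_n50: int, seed: int = 0, max_tries: int = 500
) -> tuple[list[str], int]:
    """Cut a genome at random breakpoints until the realised N50 is within
    ±20% of the target; returns (contigs, realised N50).  Contigs concatenate
    back to the input.  A target of at least half the sequence length yields
    the single-contig passthrough."""
    length = len(sequence)
    if target_n50 >= length:
        raise ValidationError(f"target N50 {target_n50} >= sequence length {length}")
    if target_n50 >= length / 2:
        return [sequence], length
    rng = _rng(seed)
    n0 = max(2, round(length / target_n50))
    for _ in range(max_tries):
        n_pieces = int(rng.integers(max(2, n0 // 2), 2 * n0 + 1))
        if n_pieces >= length:
            continue
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_pieces - 1, replace=False))
        bounds = [0, *cuts.tolist(), length]
        pieces = [sequence[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        realized = compute_n50([len(p) for p in pieces])
        if abs(realized - target_n50) <= 0.2 * target_n50:
            return pieces, realized
    raise ValidationError(
        f"could not realise N50 {target_n50}±20% on a {length} bp sequence "
        f"in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# frameshift indels


@dataclass(frozen=True)
class IndelEvent:
    """A single-base indel; ``position`` indexes the original sequence."""

    position: int
    kind: str  # "ins" | "del"
    base: str = ""  # inserted base for "ins"


def inject_frameshifts(
    sequence: str, rate: float, seed: int = 0
) -> tuple[str, list[IndelEvent]]:
    """Inject Poisson(rate · length / 10⁴) single-base indels (50/50
    insertion/deletion) at uniform positions; returns the mutated sequence
    and the events for truth-tracking."""
    if rate < 0:
        raise ValidationError(f"negative indel rate {rate}")
    rng = _rng(seed)
    n_events = int(rng.poisson(rate * len(sequence) / 1e4))
    if n_events == 0:
        return sequence, []
    positions = np.sort(rng.choice(len(sequence), size=min(n_events, len(sequence)), replace=False))
    events = []
    for pos in positions:
        if rng.random() < 0.5:
            events.append(IndelEvent(int(pos), "ins", str(rng.choice(_BASES))))
        else:
            events.append(IndelEvent(int(pos), "del"))
    out = []
    prev = 0
    for ev in events:
        out.append(sequence[prev : ev.position])
        if ev.kind == "ins":
            out.append(ev.base + sequence[ev.position])
        prev = ev.position + 1
    out.append(sequence[prev:])
    return "".join(out), events


def map_mutated_to_original(events: list[IndelEvent]) -> "CoordinateMap":
    return CoordinateMap(events)


class CoordinateMap:
    """Maps coordinates on an indel-mutated sequence back to the original."""

    def __init__(self, events: list[IndelEvent]):
        self._mut_pos: list[int] = []
        self._shift: list[int] = []
        shift = 0  # original = mutated - shift after this event
        for ev in sorted(events, key=lambda e: e.position):
            mut_at = ev.position + shift
            shift += 1 if ev.kind == "ins" else -1
            self._mut_pos.append(mut_at)
            self._shift.append(shift)

    def to_original(self, mutated_coord: int) -> int:
        i = bisect.bisect_right(self._mut_pos, mutated_coord)
        return mutated_coord - (self._shift[i - 1] if i else 0)


# ---------------------------------------------------------------------------
# communities (dereplication / richness ground truth)


@dataclass(frozen=True)
class SimulatedGenome:
    record: MAGRecord
    sequence: str
    species_index: int
    strain_index: int


@dataclass(frozen=True)
class SimulatedCommunity:
    genomes: tuple[SimulatedGenome, ...]
    seed: int
    params: dict = field(default_factory=dict)


def simulate_community(
    n_species: int = 10,
    strains_per_species: int = 3,
    genome_length: int = 20_000,
    strain_ani: float = 99.6,
    gc: float = 0.5,
    seed: int = 0,
) -> SimulatedCommunity:
    """Species are independent random genomes; strains are substitution
    mutants of their species base at ``strain_ani``.  Quality statistics are
    drawn uniformly: completeness 80–100%, contamination 0–10%, N50 10–500 kb
    — every genome passes the dereplication prefilter by construction."""
    rng = _rng(seed)
    genomes = []
    batch = 0
    for sp in range(n_species):
        base = generate_genome(genome_length, gc, seed=int(rng.integers(2**31)))
        for st in range(strains_per_species):
            seq = (
                base
                if st == 0
                else mutate_to_ani(base, strain_ani, seed=int(rng.integers(2**31)))
            )
            record = MAGRecord(
                genome_id=f"SIM{sp:03d}_{st:02d}",
                completeness=float(np.round(rng.uniform(80, 100), 2)),
                contamination=float(np.round(rng.uniform(0, 10), 2)),
                n50=int(rng.integers(10_000, 500_000)),
                batch_index=batch,
            )
            genomes.append(SimulatedGenome(record, seq, sp, st))
            batch += 1
    return SimulatedCommunity(
        genomes=tuple(genomes),
        seed=seed,
        params={
            "n_species": n_species,
            "strains_per_species": strains_per_species,
            "genome_length": genome_length,
            "strain_ani": strain_ani,
            "gc": gc,
        },
    )


def simulate_coverage(
    genome_ids: list[str],
    n_samples: int = 20,
    presence_prob: float = 0.4,
    mean_depth: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genome × sample depth matrix: each genome is present in each sample
    with ``presence_prob``, with exponentially distributed depth when present."""
    rng = _rng(seed)
    present = rng.random((len(genome_ids), n_samples)) < presence_prob
    depth = rng.exponential(mean_depth, size=present.shape) * present
    return pd.DataFrame(
        np.round(depth, 3),
        index=pd.Index(genome_ids, name="genome_id"),
        columns=[f"sample_{i:03d}" for i in range(n_samples)],
    )


# ---------------------------------------------------------------------------
# cascade evidence


_DEFAULT_LINEAGE = {
    "species": "Simulatibacter syntheticus",
    "genus": "Simulatibacter",
    "family": "Simulatibacteraceae",
    "order": "Simulatibacterales",
    "class": "Simulatia",
    "phylum": "Simulatibacteriota",
}


def simulate_evidence(
    true_lineage: dict[str, str] | None = None,
    scenario: int = 1,
    seed: int = 0,
    genome_id: str = "SIMEV",
) -> TaxonomicEvidence:
    """Evidence constructed so the cascade fires exactly rule ``scenario``
    (1–12); thresholds are crossed with a margin of at least 0.02."""
    if scenario not in range(1, 13):
        raise ValidationError(f"scenario {scenario} outside 1..12")
    lineage = dict(_DEFAULT_LINEAGE)
    if true_lineage:
        lineage.update(true_lineage)
    rng = _rng(seed)

    def above(threshold: float) -> float:
        return float(min(1.0, threshold + rng.uniform(0.02, 0.05)))

    def below(threshold: float) -> float:
        return float(max(0.0, threshold - rng.uniform(0.02, 0.1)))

    def vote(rank: Rank, proportion: float, identity: float) -> RankVote:
        name = rank.value if rank is not Rank.class_ else "class"
        return RankVote(rank, lineage[name], proportion, identity)

    # everything starts below every threshold; scenarios strengthen one signal
    votes = {
        Rank.species: vote(Rank.species, below(0.9), below(0.95)),
        Rank.genus: vote(Rank.genus, below(0.9), below(0.9)),
        Rank.family: vote(Rank.family, below(0.8), below(0.6)),
        Rank.order: vote(Rank.order, below(0.6), below(0.6)),
        Rank.class_: vote(Rank.class_, 0.0, 0.0),
        Rank.phylum: vote(Rank.phylum, 0.0, 0.0),
    }
    sourmash_score = below(0.8)
    sourmash_taxon = ""
    phylo_level: Rank | None = None
    phylo_taxon = ""
    phylo_conf = PhyloConfidence.none if rng.random() < 0.5 else PhyloConfidence.low

    def place(level: Rank, conf: PhyloConfidence):
        nonlocal phylo_level, phylo_taxon, phylo_conf
        phylo_level = level
        name = level.value if level is not Rank.class_ else "class"
        phylo_taxon = lineage[name]
        phylo_conf = conf

    hm = PhyloConfidence.high if rng.random() < 0.5 else PhyloConfidence.medium
    if scenario == 1:
        votes[Rank.species] = vote(Rank.species, above(0.9), above(0.95))
    elif scenario == 2:
        sourmash_score = above(0.8)
        sourmash_taxon = lineage["species"]
    elif scenario == 3:
        place(Rank.species if rng.random() < 0.5 else Rank.genus, PhyloConfidence.high)
    elif scenario == 4:
        votes[Rank.genus] = vote(Rank.genus, above(0.9), above(0.9))
    elif scenario == 5:
        place(Rank.genus, PhyloConfidence.medium)
    elif scenario == 6:
        place(Rank.family, hm)
    elif scenario == 7:
        votes[Rank.family] = vote(Rank.family, above(0.8), above(0.6))
    elif scenario == 8:
        place(Rank.order, hm)
    elif scenario == 9:
        votes[Rank.order] = vote(Rank.order, above(0.6), above(0.6))
    elif scenario == 10:
        place(Rank.class_, hm)
    elif scenario == 11:
        place(Rank.phylum, hm)
    # scenario 12: leave everything weak; checkm fallback fires

    return TaxonomicEvidence(
        genome_id=genome_id,
        votes=votes,
        sourmash_score=sourmash_score,
        sourmash_taxon=sourmash_taxon,
        phylo_level=phylo_level,
        phylo_taxon=phylo_taxon,
        phylo_confidence=phylo_conf,
        checkm_lineage="k__Bacteria;p__" + lineage["phylum"],
    )


# ---------------------------------------------------------------------------
# proteins / indel-diagnostic experiment


def random_protein(length: int, seed: int = 0) -> str:
    if length < 1:
        raise ValidationError("protein length < 1")
    return "".join(_rng(seed).choice(_AMINO_ACIDS, size=length))


def simulate_ideel_experiment(
    genome_length: int = 30_000,
    indel_rate: float = 5.0,
    seed: int = 0,
    min_aa: int = ideel_diag.DEFAULT_MIN_AA,
    min_overlap: float = 0.5,
):
    """Closed-loop indel experiment with known truth.

    A clean genome's ORFs act as the reference protein database.  The genome
    is then frameshift-mutated at ``indel_rate`` per 10 kb and re-scanned;
    each re-predicted protein is matched to the reference ORF it overlaps
    most (coordinates mapped back through the indel events, same strand,
    overlap ≥ ``min_overlap`` of the shorter interval).  Returns the
    length-ratio rows plus the event list.
    """
    genome = generate_genome(genome_length, 0.5, seed=seed)
    reference = ideel_diag.find_orfs(genome, "ref", min_aa=min_aa)
    mutated, events = inject_frameshifts(genome, indel_rate, seed=seed + 1)
    queries = ideel_diag.find_orfs(mutated, "qry", min_aa=min_aa)
    coord = CoordinateMap(events)

    ref_by_strand: dict[str, list] = {"+": [], "-": []}
    for i, orf in enumerate(reference):
        ref_by_strand[orf.strand].append((orf.start, orf.end, f"refprot_{i:05d}", orf))

    query_lengths: dict[str, int] = {}
    best_hits: dict[str, tuple[str, int]] = {}
    for j, orf in enumerate(queries):
        qid = f"qryprot_{j:05d}"
        query_lengths[qid] = len(orf.protein)
        o_start = coord.to_original(orf.start)
        o_end = coord.to_original(orf.end)
        best = None
        for r_start, r_end, rid, r_orf in ref_by_strand[orf.strand]:
            overlap = min(o_end, r_end) - max(o_start, r_start)
            if overlap <= 0:
                continue
            shorter = min(o_end - o_start, r_end - r_start)
            if overlap / shorter < min_overlap:
                continue
            # prefer larger overlap; on ties (nested ORFs) prefer the
            # reference whose span is closest to the query's
            key = (overlap, -abs((r_end - r_start) - (o_end - o_start)))
            if best is None or key > best[0]:
                best = (key, rid, len(r_orf.protein))
        if best is not None:
            best_hits[qid] = (best[1], best[2])
    rows, n_without = ideel_diag.length_ratios(query_lengths, best_hits)
    return rows, events, n_without
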