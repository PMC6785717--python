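# Methods

This note documents the models, conventions and numerical choices behind
`magcurator`, in the order a catalog build uses them.

## Quality model

Genome quality is taken as given: completeness and contamination are
marker-gene estimates computed upstream (CheckM-style) and consumed from a
table; the toolkit never recomputes them.  Two derived scores:

* **Quality score** `completeness − 5·contamination` (both in percent).
  The 5× weight makes 1% contamination as costly as 5% missing genome;
  catalogs conventionally cut at score ≥ 50.
* **Bin score** `completeness − 5·contamination + 0.5·log10(N50 in bp)`,
  used to pick dereplication winners.  The logarithm base is not fixed by
  convention; we use base 10 (configurable), which keeps the N50 term in
  roughly 1.5–3.5 for draft assemblies (N50 ~ 3 kb–3 Mb) — a tie-breaker
  among near-equals, never a driver.  Any base preserves the score's
  ordering in each variable, but base e or 2 would triple the term's
  weight against completeness percent.

All tier thresholds (≥90/≤5 high quality; ≥80/≤10 inclusion) are
boundary-inclusive, matching how such criteria are printed.

## Sketch ANI

A genome's sketch is the `s` smallest values of a 64-bit hash over its
canonical k-mers (lexicographic minimum of k-mer and reverse complement,
compared as 2-bit packings; k must be odd so no k-mer is its own reverse
complement).  k-mers containing `N` are skipped, not substituted.
Defaults k = 21, s = 100,000 — standard for bacterial genomes, where
4^21 ≫ genome size makes random k-mer collisions negligible.

The hash is a splitmix64 finalizer applied to `kmer XOR mix(seed)`
(default seed 42).  It is deterministic and statistically uniform, which
is the only property the estimator needs; bit-compatibility with external
sketching tools is a non-goal.  The reported `n_distinct_kmers` counts
distinct hash values; with a 64-bit hash the probability that this
differs from the true distinct-k-mer count is negligible at any genome
size handled here.

Jaccard is estimated from the merged bottom-s sketch: among the s
smallest hashes of the sketch union, the fraction present in both.  The
Mash distance is `D = min(1, −ln(2j/(1+j))/k)`, with j = 0 capped at
D = 1.

**ANI mapping.**  Distances convert to ANI with the Poisson inversion
`ANI = 100·e^(−D)` by default.  Rationale: under an i.i.d. substitution
model at per-base rate p, the expected fraction of conserved k-mers is
(1−p)^k, and substituting it through the Mash formula gives exactly
`D = −ln(1−p)`; hence `e^(−D) = 1−p` recovers the true identity without
bias across the whole 80–100% range where strain/species thresholds
live.  The widely used linear convention `ANI = 100·(1−D)` (kept as
`model="linear"`) agrees to first order near ANI 100 but understates ANI
by ≈ 0.5 at 90% — large enough to matter against the 95% species
threshold — which is why it is not the default.  Both mappings send
D = 0 to ANI 100.  Below roughly ANI 80 the sketch Jaccard of unrelated
bacterial genomes is effectively 0 and the capped distance makes the ANI
value uninformative; only the threshold decisions (>99, ≥95) are
meaningful there.

Novelty bands follow the usual conventions: ANI ≥ 99 same strain,
95 ≤ ANI < 99 new strain of a known species, ANI < 95 new species.

## Dereplication

Clustering is greedy and score-ordered: genomes sorted by bin score
descending (ties by id), each joining the first representative with
ANI *strictly above* the threshold, else founding a cluster.  This
reproduces the "highest-scoring genome per cluster" contract
deterministically in O(n·clusters) comparisons, without the two-stage
sketch-then-alignment pipeline of dRep-class tools; a single-linkage
connected-components mode is available for sensitivity checks (chains of
strains can merge clusters there; the greedy mode never does).

The continuous catalog applies the same logic to a stream: a newcomer
with >99% ANI (strict, so exact-boundary pairs stay separate) to catalog
members either loses to the best incumbent or replaces *all* matched
incumbents, keeping the catalog free of >99%-ANI pairs.  "Better" is
compared on the bin score — a single total order — rather than on raw
completeness/contamination pairs, which can be incomparable
(one better in each).  Score ties keep the incumbent, so accessioned ids
are stable under re-submission.

## Taxonomy cascade

Protein votes are computed from the best hit per query protein (highest
bitscore; ties by lower e-value, then subject id).  The vote denominator
is the number of proteins whose best hit maps to a named taxon at the
rank in question — unmapped proteins carry no signal at that rank, so
they neither support nor dilute.  The mean amino-acid identity is
averaged over the modal taxon's supporting hits only, since that is the
quantity the rule thresholds test.  Modal ties break lexicographically
for determinism.

The 12 rules run strictly in order; thresholds are inclusive and
configurable (defaults: species vote 0.9/identity 0.95, sketch score
0.8, genus 0.9/0.9, family 0.8/0.6, order 0.6/0.6).  Placement
confidence is a categorical input (`high`/`medium`/`low`/`none`);
`low`/`none` never trigger placement rules, and a `medium` placement at
species level matches no rule (only `high` may place at genus/species).
Rule 12 returns the marker-gene lineage string with rank `None` — it is
a lineage, not a single-rank name.  The cascade is exhaustive and, for
the evidence orderings tested, monotone: strengthening any one evidence
channel never coarsens the assigned rank.

## Chao1 richness

`S_chao1 = S_obs + f1²/(2·f2)` (classic form) when doubletons exist,
else the bias-corrected `S_obs + f1(f1−1)/2`.  The classic form is the
default because it is the standard estimator for this occupancy reading
and is exact on the worked example in the README; the corrected form
differs by < 1 species there (3275.1 vs 3276.0) and is only needed to
avoid division by zero.  Cluster "size" counts member genomes, not the
animals they came from.  The discovered fraction `100·S_obs/S_chao1` is
reported at two decimals.  Prevalence counts samples at depth ≥ cutoff
(default 1×, inclusive) and catalog summaries use strict `>` for the
"more than 1/10/200 samples" counts.

## Indel diagnostic

The length ratio is query/subject (predicted protein over best hit), so
truncations sit below 1; the putative-truncation cutoff defaults to 0.9
(no standard printed value exists; it is configurable).  The histogram
uses fixed 0.05-wide bins on [0, 2) plus an overflow bin, so plots from
different runs are comparable.

The bundled ORF caller is deliberately naive: six-frame scan, start
codons ATG/GTG/TTG (translated as M), stops TAA/TAG/TGA, the longest ORF
(first start) per stop-to-stop interval, minimum 30 aa, no
ribosome-binding-site or codon-usage model.  It exists so the diagnostic
closes end-to-end on synthetic genomes; it is not a substitute for a
production gene caller on real data, where its calls on random
intergenic sequence would add noise a trained caller suppresses.

## Protein clustering

Greedy longest-first (ties by id), join-first-representative at
identity ≥ threshold; representatives are therefore the longest member
of each cluster.  Identity = identical aligned residues / shorter
sequence length, from a global alignment with match +1, mismatch 0,
affine gaps −10/−1 — the convention of incremental clustering tools, so
a fragment identical to a prefix of its parent scores 1.0.  Threshold
1.0 therefore means exact full-length duplicates and is implemented as
string grouping.  Clustering at each threshold is flat (independent),
not hierarchically chained through the previous threshold's
representatives; the flat reading keeps each threshold's output
self-contained.  A shared-5-mer prefilter skips hopeless alignments for
inputs ≥ 1,000 sequences; below that, clustering is exact.

## Synthetic fixtures

Generators emulate: i.i.d. genomes at a target GC; strain structure by
i.i.d. substitution to a target ANI (no indels, no recombination);
assembly fragmentation by uniform random breakpoints accepted when the
realised N50 lands within ±20% of target; frameshifts as Poisson
single-base indels (50/50 insertion/deletion); per-rule cascade evidence
with ≥ 0.02 threshold margins; and exponential-depth coverage matrices.
Defaults for community fixtures: 10 species × 3 strains at strain ANI
99.6 (so within-species pairs sit near 99.2, clearly above the species
threshold and above the strain threshold), 20 kb genomes, quality drawn
uniformly from the inclusion region (completeness 80–100, contamination
0–10, N50 10–500 kb).

What they do *not* emulate — repeats, horizontal transfer, uneven
coverage, chimeric bins, real codon usage — bounds what passing tests
show: the toolkit's decision logic and estimators are correct under
their stated models, not that those models capture every failure mode of
real metagenome assemblies.  In particular the ANI recovery tests
certify the estimator under pure substitution divergence; indel-rich
divergence would shift k-mer ANI relative to alignment ANI.

Test and acceptance problem sizes (100 kb genomes for ANI recovery,
30-genome streams for the catalog contract, 20 kb genomes over 40 seeds
for the indel dose response) were chosen as the smallest scales at which
the targeted statistical tolerances (±0.5 ANI, ≥95% trial agreement) are
comfortably resolvable.

## Known limitations

* Sketch ANI is a k-mer identity, not an alignment ANI; agreement with
  fragment-mapping ANI tools degrades below ~90% ANI.
* The greedy dereplication contract guarantees members are within the
  threshold of their *representative* only (radius, not diameter).
* The continuous catalog matches the batch brute-force optimum when
  strain neighbourhoods are well separated (the regime it is designed
  for); adversarial ANI chains that straddle the threshold can make the
  greedy stream order-dependent.
* Protein-clustering thresholds below 1.0 use O(n·representatives)
  alignments and are intended for desk-scale sets, not
  tens-of-millions-protein compendia.
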