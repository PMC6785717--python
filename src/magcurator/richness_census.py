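"""Chao1 catalog-completeness estimation and per-genome sample prevalence.

How complete is a genome catalog?  If species-level clusters are treated as
species and the number of member genomes per cluster as the number of times
that species was observed, the Chao1 estimator extrapolates total richness
from the clusters seen only once (singletons, f1) or twice (doubletons, f2):

    S_chao1 = S_obs + f1² / (2 · f2)

The classic form above is the default; when f2 = 0 the bias-corrected form
``S_obs + f1(f1 − 1)/2`` is used instead.  The discovered fraction is
``100 · S_obs / S_chao1``.

Prevalence summarises a genome × sample read-depth matrix: a genome is
"present" in a sample when its depth meets the cutoff (default 1×,
boundary inclusive), and catalog-level counts report how many genomes exceed
1, 10 and 200 samples (strictly greater, matching the "more than n animals"
phrasing such counts are reported with).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .dereplication import ClusterSet
from .errors import ValidationError

PREVALENCE_SUMMARY_CUTS = (1, 10, 200)


@dataclass(frozen=True)
class OccupancyHistogram:
    """Counts of clusters by size; the sufficient statistic for Chao1."""

    s_obs: int
    f1: int
    f2: int
    histogram: dict[int, int]

    def __post_init__(self):
        if self.f1 + self.f2 > self.s_obs:
            raise ValidationError("f1 + f2 exceeds the number of observed clusters")
        if self.histogram and sum(self.histogram.values()) != self.s_obs:
            raise ValidationError("histogram counts do not sum to s_obs")

    @classmethod
    def from_counts(cls, s_obs: int, f1: int, f2: int) -> "OccupancyHistogram":
        """Build from the three summary counts alone (remaining clusters are
        pooled in a size-3 pseudo-bin to keep the histogram consistent)."""
        hist = {1: f1, 2: f2}
        rest = s_obs - f1 - f2
        if rest:
            hist[3] = rest
        return cls(s_obs=s_obs, f1=f1, f2=f2, histogram={k: v for k, v in hist.items() if v})


@dataclass(frozen=True)
class PrevalenceRow:
    genome_id: str
    n_samples_present: int
    cutoff: float


def histogram_from_clusters(cluster_set: ClusterSet) -> OccupancyHistogram:
    """Occupancy histogram of a cluster partition (cluster size = number of
    member genomes)."""
    sizes = Counter(len(c.members) for c in cluster_set.clusters)
    return OccupancyHistogram(
        s_obs=len(cluster_set.clusters),
        f1=sizes.get(1, 0),
        f2=sizes.get(2, 0),
        histogram=dict(sorted(sizes.items())),
    )


def histogram_from_sizes(sizes: list[int]) -> OccupancyHistogram:
    counts = Counter(sizes)
    if any(s < 1 for s in counts):
        raise ValidationError("cluster sizes must be >= 1")
    return OccupancyHistogram(
        s_obs=len(sizes),
        f1=counts.get(1, 0),
        f2=counts.get(2, 0),
        histogram=dict(sorted(counts.items())),
    )


def chao1(hist: OccupancyHistogram) -> float:
    """Chao1 richness estimate (classic form; bias-corrected when f2 = 0)."""
    if hist.f2 > 0:
        return hist.s_obs + hist.f1**2 / (2.0 * hist.f2)
    return hist.s_obs + hist.f1 * (hist.f1 - 1) / 2.0


def discovered_fraction(hist: OccupancyHistogram) -> float:
    """Percentage of the Chao1-estimated richness already observed, at two
    decimal places."""
    estimate = chao1(hist)
    if estimate <= 0:
        raise ValidationError("Chao1 estimate is zero; discovered fraction undefined")
    return round(100.0 * hist.s_obs / estimate, 2)


def richness_report(hist: OccupancyHistogram) -> dict:
    est = chao1(hist)
    return {
        "s_obs": hist.s_obs,
        "f1": hist.f1,
        "f2": hist.f2,
        "chao1_raw": est,
        "chao1_rounded": int(round(est)),
        "discovered_percent": discovered_fraction(hist),
    }


def prevalence(
    coverage: pd.DataFrame, cutoff: float = 1.0
) -> tuple[list[PrevalenceRow], dict[int, int]]:
    """Per-genome count of samples at depth ≥ cutoff, plus catalog summary
    counts of genomes present in more than 1 / 10 / 200 samples.

    ``coverage`` is a genome × sample depth matrix (index = genome ids).
    """
    if (coverage.values < 0).any():
        raise ValidationError("negative depths in coverage matrix")
    present = (coverage >= cutoff).sum(axis=1)
    rows = [
        PrevalenceRow(genome_id=str(g), n_samples_present=int(n), cutoff=cutoff)
        for g, n in present.items()
    ]
    summary = {cut: int((present > cut).sum()) for cut in PREVALENCE_SUMMARY_CUTS}
    return rows, summary
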