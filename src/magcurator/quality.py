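"""MAG quality scores, quality tiers, and the pre-dereplication filter.

Two scores are in use for draft-genome catalogs.  The Parks score,
``completeness − 5 × contamination``, penalises contamination five-fold and
is cut at 50 for catalog inclusion.  The dereplication bin score adds a mild
N50 tie-breaker, ``completeness − 5 × contamination + 0.5 × log10(N50)``, so
that among near-identical genomes the less fragmented assembly wins.

Tiers follow the two community conventions: *high quality* requires ≥90%
completeness and ≤5% contamination; the catalog-inclusion tier (*rug_pass*)
requires ≥80% completeness and ≤10% contamination.  All thresholds are
inclusive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import ValidationError

PARKS_SCORE_CUTOFF = 50.0


class QualityTier(enum.Enum):
    high_quality = "high_quality"
    rug_pass = "rug_pass"
    fail = "fail"


@dataclass(frozen=True)
class MAGRecord:
    """Identity and quality statistics for one metagenome-assembled genome.

    ``batch_index`` records arrival order for the continuous catalog workflow
    (lower = earlier).
    """

    genome_id: str
    completeness: float
    contamination: float
    n50: int
    batch_index: int = 0

    def __post_init__(self):
        if not self.genome_id:
            raise ValidationError("MAGRecord with empty genome_id")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValidationError(
                f"{self.genome_id}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0:
            raise ValidationError(
                f"{self.genome_id}: negative contamination {self.contamination}"
            )
        if self.n50 < 1:
            raise ValidationError(f"{self.genome_id}: N50 {self.n50} < 1")
        if self.batch_index < 0:
            raise ValidationError(f"{self.genome_id}: negative batch_index")


def parks_score(completeness: float, contamination: float) -> float:
    """Quality score ``completeness − 5 × contamination``."""
    if not 0.0 <= completeness <= 100.0:
        raise ValidationError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0:
        raise ValidationError(f"negative contamination {contamination}")
    return completeness - 5.0 * contamination


def bin_score(record: MAGRecord, log_base: float = 10.0) -> float:
    """Dereplication score ``completeness − 5·contamination + 0.5·log(N50)``.

    The logarithm base defaults to 10, which keeps the N50 term in the
    1.5–3.5 range for typical draft assemblies — a tie-breaker rather than a
    driver of the score.
    """
    if record.n50 < 1:
        raise ValidationError(f"N50 {record.n50} < 1")
    return (
        parks_score(record.completeness, record.contamination)
        + 0.5 * math.log(record.n50, log_base)
    )


def classify_tier(record: MAGRecord) -> QualityTier:
    """Assign the quality tier; all boundaries inclusive as conventionally printed."""
    if record.completeness >= 90.0 and record.contamination <= 5.0:
        return QualityTier.high_quality
    if record.completeness >= 80.0 and record.contamination <= 10.0:
        return QualityTier.rug_pass
    return QualityTier.fail


def prefilter(records: list[MAGRecord]) -> list[MAGRecord]:
    """Keep records suitable for dereplication (completeness ≥80, contamination
    ≤10, i.e. tier ≠ fail); input order preserved.  Idempotent."""
    return [r for r in records if classify_tier(r) is not QualityTier.fail]


def score_table(records: list[MAGRecord]) -> list[dict]:
    """Per-genome score/tier report rows (genome_id, parks_score, bin_score, tier)."""
    return [
        {
            "genome_id": r.genome_id,
            "parks_score": parks_score(r.completeness, r.contamination),
            "bin_score": bin_score(r),
            "tier": classify_tier(r).value,
        }
        for r in records
    ]
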