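"""Readers and writers for the toolkit's on-disk artifacts.

All tabular artifacts are plain TSV with a header line; FASTA is handled
through Biopython's parser with strict validation layered on top (duplicate
IDs and empty files are errors, never silently tolerated).  Report writers
use fixed float formatting so that identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ParseError, ValidationError

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

#: decimal places used for every float we serialise
FLOAT_DECIMALS = 4


@dataclass(frozen=True)
class HitRow:
    """One line of 12-column blast-tab output (DIAMOND/BLAST dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not self.query_id:
            raise ValidationError("hit row has empty query_id")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.aln_length < 1:
            raise ValidationError(f"alignment length {self.aln_length} < 1")
        if self.evalue < 0:
            raise ValidationError(f"negative e-value {self.evalue}")


@dataclass(frozen=True)
class QualityTableRow:
    """CheckM-style per-genome quality statistics."""

    genome_id: str
    completeness: float
    contamination: float
    n50: int
    n_contigs: int

    def __post_init__(self):
        if not self.genome_id:
            raise ValidationError("quality row has empty genome_id")
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
        if self.n_contigs < 1:
            raise ValidationError(f"{self.genome_id}: contig count {self.n_contigs} < 1")


def read_fasta(
    path,
    *,
    mode: Literal["nucleotide", "protein"] = "nucleotide",
    on_invalid: Literal["error", "mask"] = "error",
) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``, order preserved.

    Sequences are uppercased.  In nucleotide mode characters outside
    ``{A, C, G, T, N}`` either raise (``on_invalid="error"``) or are masked
    to ``N`` (``on_invalid="mask"``).  Empty files and duplicate IDs raise.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else ""
            if not rec_id:
                raise ParseError("FASTA record with empty header", path=path)
            if rec_id in seen:
                raise ValidationError(f"duplicate FASTA id {rec_id!r} in {path}")
            seen.add(rec_id)
            seq = seq.upper()
            if mode == "nucleotide":
                bad = set(seq) - NUCLEOTIDE_ALPHABET
                if bad:
                    if on_invalid == "error":
                        raise ValidationError(
                            f"record {rec_id!r}: invalid nucleotide characters "
                            f"{sorted(bad)}"
                        )
                    seq = "".join(c if c in NUCLEOTIDE_ALPHABET else "N" for c in seq)
            records.append((rec_id, seq))
    if not records:
        raise ParseError("FASTA file contains no records", path=path)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_hit_table(path) -> list[HitRow]:
    """Parse a 12-column blast-tab file (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore) into :class:`HitRow` s.

    Extra columns beyond 12 are ignored with a warning; fewer than 12 is a
    parse error that names the offending line.  An empty file yields ``[]``.
    """
    path = Path(path)
    rows: list[HitRow] = []
    warned_extra = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"expected 12 tab-separated columns, found {len(fields)}",
                    path=path,
                    line=lineno,
                )
            if len(fields) > 12 and not warned_extra:
                warnings.warn(
                    f"{path}: lines with >12 columns; extra columns ignored",
                    stacklevel=2,
                )
                warned_extra = True
            try:
                row = HitRow(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except (ValueError, ValidationError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"malformed numeric field: {exc}", path=path, line=lineno)
            rows.append(row)
    return rows


QUALITY_COLUMNS = ["genome_id", "completeness", "contamination", "n50", "n_contigs"]


def read_quality_table(path) -> list[QualityTableRow]:
    """Read the per-genome quality TSV (header: genome_id, completeness,
    contamination, n50, n_contigs)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    missing = [c for c in QUALITY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"quality table missing columns {missing}", path=path)
    rows = [
        QualityTableRow(
            genome_id=r.genome_id,
            completeness=float(r.completeness),
            contamination=float(r.contamination),
            n50=int(r.n50),
            n_contigs=int(r.n_contigs),
        )
        for r in df.itertuples(index=False)
    ]
    dupes = df["genome_id"][df["genome_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate genome ids in quality table: {sorted(set(dupes))}")
    return rows


def read_taxonomy_map(path) -> dict[str, dict[str, str]]:
    """Read the subject→lineage TSV: subject_id then one column per rank
    (superkingdom, phylum, class, order, family, genus, species; any subset)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "subject_id" not in df.columns:
        raise ParseError("taxonomy map missing 'subject_id' column", path=path)
    ranks = [c for c in df.columns if c != "subject_id"]
    return {
        r.subject_id: {rank: getattr(r, rank) for rank in ranks}
        for r in df.itertuples(index=False)
    }


def read_coverage_matrix(path) -> pd.DataFrame:
    """Read the genome × sample depth matrix (first column genome_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValidationError(f"negative depths in coverage matrix {path}")
    return df


def _format_value(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.{FLOAT_DECIMALS}f}"
    return str(value)


def write_report(report, path, format: Literal["tsv", "json"] = "tsv") -> None:
    """Serialise a report deterministically.

    ``tsv`` expects a list of mappings (rows) or a DataFrame; ``json`` accepts
    any JSON-serialisable object.  Floats are written at :data:`FLOAT_DECIMALS`
    decimal places and JSON keys are sorted, so the same report always yields
    byte-identical files.
    """
    path = Path(path)
    if format == "json":
        def _coerce(obj):
            if isinstance(obj, dict):
                return {k: _coerce(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_coerce(v) for v in obj]
            if isinstance(obj, float):
                return round(obj, FLOAT_DECIMALS)
            return obj

        with open(path, "w") as handle:
            json.dump(_coerce(report), handle, sort_keys=True, indent=2)
            handle.write("\n")
        return
    if format == "tsv":
        if isinstance(report, pd.DataFrame):
            rows = report.to_dict("records")
            columns = list(report.columns)
        else:
            rows = list(report)
            columns = list(rows[0].keys()) if rows else []
        with open(path, "w") as handle:
            handle.write("\t".join(columns) + "\n")
            for row in rows:
                handle.write("\t".join(_format_value(row[c]) for c in columns) + "\n")
        return
    raise ValidationError(f"unknown report format {format!r}")
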