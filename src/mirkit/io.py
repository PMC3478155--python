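"""Readers, writers and the report/statistics layer.

All sequences are normalized to the RNA alphabet (``T`` -> ``U``) on read;
the original alphabet is remembered so records round-trip byte-identically.
All coordinates everywhere in the package are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class CoordinateError(ValueError):
    """Raised on invalid 1-based coordinates."""


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a percentage has denominator zero."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, internally always RNA-alphabet.

    ``alphabet`` records whether the source file was DNA or RNA so that
    writing the record back reproduces the original characters.
    """

    id: str
    sequence: str
    quality: Optional[list[int]] = None
    description: str = ""
    alphabet: str = "rna"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ParseError(f"record {self.id!r}: non-nucleotide characters {sorted(bad)}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"record {self.id!r}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicLocation:
    """1-based inclusive interval on a named reference."""

    reference_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"invalid 1-based interval {self.start}-{self.end} on {self.reference_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def to_half_open(self) -> tuple[int, int]:
        """0-based half-open twin; round-trips with :func:`from_half_open`."""
        return self.start - 1, self.end

    @classmethod
    def from_half_open(cls, reference_id: str, start0: int, end0: int, strand: str = "+"):
        return cls(reference_id, start0 + 1, end0, strand)


@dataclass(frozen=True)
class SNPRecord:
    """A single-nucleotide substitution on a reference sequence."""

    reference_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CoordinateError(f"SNP position {self.position} (coordinates are 1-based)")
        for allele in (self.ref_allele, self.alt_allele):
            if len(allele) != 1 or allele not in "ACGU":
                raise ValueError(f"allele {allele!r} is not a single RNA nucleotide")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"{self.reference_id}:{self.position} ref allele equals alt allele"
            )


def format_percentage(numerator: int, denominator: int) -> str:
    """``100 * numerator / denominator`` rounded half-up to two decimals.

    >>> format_percentage(7327921, 11665437)
    '62.82'
    """
    if denominator == 0:
        raise UndefinedRatioError("percentage with zero denominator")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return str(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def average_targets_per_mirna(n_target_mrnas: int, n_mirnas: int) -> float:
    """Mean target mRNAs per miRNA, rounded half-up to one decimal.

    >>> average_targets_per_mirna(206, 83)
    2.5
    """
    if n_mirnas == 0:
        raise UndefinedRatioError("no miRNAs: average undefined")
    ratio = Decimal(n_target_mrnas) / Decimal(n_mirnas)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "repeat")


@dataclass
class ReadAccounting:
    """Read bookkeeping through cleaning and contaminant annotation."""

    raw_count: int
    cleaned_count: int
    contaminant_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cleaned_count > self.raw_count:
            raise ValueError("cleaned_count exceeds raw_count")
        for cls in self.contaminant_counts:
            if cls not in CONTAMINANT_CLASSES:
                raise ValueError(f"unknown contaminant class {cls!r}")

    @property
    def remaining_count(self) -> int:
        return self.cleaned_count - sum(self.contaminant_counts.values())

    @property
    def cleaned_percentage(self) -> str:
        return format_percentage(self.cleaned_count, self.raw_count)

    def contaminant_percentage(self, cls: str) -> str:
        """Percentage of clean reads annotated to one contaminant class."""
        return format_percentage(self.contaminant_counts.get(cls, 0), self.cleaned_count)

    def as_dict(self) -> dict:
        return {
            "raw_count": self.raw_count,
            "cleaned_count": self.cleaned_count,
            "cleaned_percentage": self.cleaned_percentage,
            "contaminants": {
                cls: {
                    "count": n,
                    "percentage": self.contaminant_percentage(cls),
                }
                for cls, n in self.contaminant_counts.items()
            },
            "remaining_count": self.remaining_count,
        }


# ---------------------------------------------------------------------------
# sequence I/O
# ---------------------------------------------------------------------------

def read_sequences(path, format: str = "fasta") -> list[SequenceRecord]:
    """Read FASTA/FASTQ into :class:`SequenceRecord` lists, mapping T to U.

    Round trip through :func:`write_sequences` is the identity on
    (id, sequence, quality). Duplicate ids are kept, with a warning.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            raw = str(rec.seq).upper()
            alphabet = "dna" if "T" in raw else "rna"
            quality = None
            if format == "fastq":
                quality = list(rec.letter_annotations["phred_quality"])
            if rec.id in seen:
                logger.warning("duplicate sequence id %r in %s", rec.id, path)
            seen.add(rec.id)
            records.append(
                SequenceRecord(
                    id=rec.id,
                    sequence=to_rna(raw),
                    quality=quality,
                    description=rec.description,
                    alphabet=alphabet,
                )
            )
    except ValueError as exc:
        # biopython reports the failing record, not the byte offset; the
        # record index pins the line number to within one record
        lines_per_record = 4 if format == "fastq" else 2
        raise ParseError(
            f"{path}: malformed {format} near line {len(records) * lines_per_record + 1}: {exc}"
        ) from exc
    return records


def write_sequences(records: Iterable[SequenceRecord], path, format: str = "fasta") -> None:
    """Write records back out, restoring each record's original alphabet."""
    out = []
    for r in records:
        seq = to_dna(r.sequence) if r.alphabet == "dna" else r.sequence
        rec = SeqRecord(Seq(seq), id=r.id, description=r.description or "")
        if format == "fastq":
            if r.quality is None:
                raise ValueError(f"record {r.id!r} has no quality scores for FASTQ output")
            rec.letter_annotations["phred_quality"] = list(r.quality)
        out.append(rec)
    SeqIO.write(out, str(path), format)


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snp_table(path) -> list[SNPRecord]:
    """Read a TSV of reference_id / position / ref_allele / alt_allele.

    A header line is accepted (detected by a non-numeric position field).
    Rows with ref == alt or position < 1 raise with the offending line number.
    """
    snps: list[SNPRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated columns")
            ref_id, pos_s, ref, alt = fields[:4]
            if not pos_s.strip().lstrip("-").isdigit():
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            try:
                snps.append(
                    SNPRecord(ref_id, int(pos_s), to_rna(ref.strip()), to_rna(alt.strip()))
                )
            except (ValueError, CoordinateError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc
    return snps


def read_snp_vcf(path) -> list[SNPRecord]:
    """Minimal VCF reader mapping CHROM/POS/REF/ALT onto :class:`SNPRecord`.

    Only single-nucleotide, single-allele records are accepted; upstream
    variant calling is outside this package's scope.
    """
    snps: list[SNPRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 VCF columns")
            chrom, pos_s, _id, ref, alt = fields[:5]
            try:
                snps.append(SNPRecord(chrom, int(pos_s), to_rna(ref), to_rna(alt)))
            except (ValueError, CoordinateError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc
    return snps


# ---------------------------------------------------------------------------
# annotations (GFF3 / TSV)
# ---------------------------------------------------------------------------

FEATURE_TYPES = ("pre_miRNA", "miRNA", "miRNA_star", "cluster", "target_site")


@dataclass
class Annotation:
    """A located feature; ``parent`` supports cluster/member nesting."""

    feature_id: str
    feature_type: str
    location: GenomicLocation
    parent: Optional[str] = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")


_GFF_TYPE = {  # SO-style types for GFF3 output
    "pre_miRNA": "miRNA_primary_transcript",
    "miRNA": "miRNA",
    "miRNA_star": "miRNA",
    "cluster": "miRNA_cluster",
    "target_site": "miRNA_target_site",
}


def write_annotation(
    annotations: Sequence[Annotation],
    path,
    format: str = "gff3",
    reference_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write annotations as GFF3 (1-based inclusive) or a mirror TSV.

    If ``reference_lengths`` is given, locations outside their reference
    are refused.
    """
    if format not in ("gff3", "tsv"):
        raise ValueError(f"unsupported annotation format {format!r}")
    if reference_lengths is not None:
        for a in annotations:
            ref_len = reference_lengths.get(a.location.reference_id)
            if ref_len is not None and a.location.end > ref_len:
                raise CoordinateError(
                    f"feature {a.feature_id}: {a.location.start}-{a.location.end} exceeds "
                    f"{a.location.reference_id} length {ref_len}"
                )
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for a in annotations:
                attrs = [f"ID={a.feature_id}"]
                if a.parent:
                    attrs.append(f"Parent={a.parent}")
                attrs += [f"{k}={v}" for k, v in sorted(a.attributes.items())]
                fh.write(
                    "\t".join(
                        [
                            a.location.reference_id,
                            "mirkit",
                            _GFF_TYPE[a.feature_type],
                            str(a.location.start),
                            str(a.location.end),
                            ".",
                            a.location.strand,
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
        else:
            fh.write(
                "feature_id\tfeature_type\treference_id\tstart\tend\tstrand\tparent\tattributes\n"
            )
            for a in annotations:
                attrs = ";".join(f"{k}={v}" for k, v in sorted(a.attributes.items()))
                fh.write(
                    "\t".join(
                        [
                            a.feature_id,
                            a.feature_type,
                            a.location.reference_id,
                            str(a.location.start),
                            str(a.location.end),
                            a.location.strand,
                            a.parent or ".",
                            attrs or ".",
                        ]
                    )
                    + "\n"
                )
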