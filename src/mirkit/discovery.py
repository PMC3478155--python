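"""miRNA discovery: homology arm, small-RNA-read arm, and catalog assembly.

The homology arm aligns known mature miRNAs against reference contigs at a
90% identity threshold, excises candidates with 60-nt bilateral flanks and
validates the folded hairpin against six structural criteria. The read arm
cleans raw small-RNA reads (adapter trimming, poly(A)/quality/length
filters), annotates contaminants (rRNA/tRNA/snRNA/repeat), stacks the
remaining reads into loci on the references and keeps loci whose dominant
read sits on one arm of a criteria-passing hairpin. Both arms merge into a
non-redundant catalog carrying conserved/specific flags, and read stacks
are further mined for isomiRs and miRNA-offset RNAs (moRNAs).

Homology search is a gap-free semi-global scan (identity = matching
positions / query length) rather than BLASTN, and contaminant annotation is
full-length matching with at most one mismatch rather than an e-value
search; both choices are deterministic and dependency-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .fold import (
    HairpinAnnotation,
    SecondaryStructure,
    annotate_regions,
    fold_hairpin,
)
from .io import (
    CONTAMINANT_CLASSES,
    GenomicLocation,
    ReadAccounting,
    SequenceRecord,
    reverse_complement,
    to_rna,
)

logger = logging.getLogger(__name__)

MIN_QUERY_LEN = 18
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_FLANK = 60
DEFAULT_MIN_LOCUS_READS = 2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyHit:
    """A placement of a full mature-miRNA query on a reference."""

    query_id: str
    reference_id: str
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int
    strand: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


@dataclass
class PrecursorHairpin:
    """A validated hairpin precursor with structure, energy and spans."""

    id: str
    sequence: str
    structure: SecondaryStructure
    dg: float
    location: GenomicLocation
    mature_span: tuple[int, int]  # 1-based on the precursor
    star_span: Optional[tuple[int, int]] = None
    annotation: Optional[HairpinAnnotation] = None


@dataclass
class MatureMiRNA:
    """A mature miRNA anchored on its precursor."""

    name: str
    sequence: str
    precursor_id: str
    location: GenomicLocation
    conservation: str = "specific"  # conserved | specific
    family: Optional[str] = None
    expression_count: int = 0


@dataclass
class CatalogEntry:
    mature: MatureMiRNA
    precursor: PrecursorHairpin
    provenance: str  # homology | sequencing | both
    conflict: bool = False


@dataclass
class CleanedRead:
    """A collapsed, adapter-free read of >= 18 nt."""

    sequence: str
    count: int
    annotation_class: str = "unannotated"

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_QUERY_LEN:
            raise ValueError("cleaned reads must be >= 18 nt")
        if self.count < 1:
            raise ValueError("collapsed count must be >= 1")


@dataclass(frozen=True)
class SixCriteriaReport:
    """The six hairpin acceptance criteria, evaluated independently.

    Boundary semantics: dG <= -15 kcal/mol passes; paired fraction of the
    mature >= 0.80 passes; largest single bulge/internal loop <= 18
    unpaired nt passes; hairpin length > 53 nt passes (53 fails); loop
    < 22 nt passes (22 fails); mature-vs-anti-stem mismatches <= 6 passes.
    """

    dg_ok: bool
    stem_coverage_ok: bool
    bulge_ok: bool
    length_ok: bool
    loop_ok: bool
    mismatch_ok: bool
    dg: float = 0.0
    stem_coverage: float = 0.0
    max_bulge: int = 0
    hairpin_length: int = 0
    loop_length: int = 0
    mismatches: int = 0

    @property
    def overall(self) -> bool:
        return (
            self.dg_ok
            and self.stem_coverage_ok
            and self.bulge_ok
            and self.length_ok
            and self.loop_ok
            and self.mismatch_ok
        )


# ---------------------------------------------------------------------------
# identity scanning (shared by homology and contaminant annotation)
# ---------------------------------------------------------------------------

def _window_matches(query: str, reference: str) -> np.ndarray:
    """Matching-position count of ``query`` at every reference offset."""
    L = len(query)
    if len(reference) < L:
        return np.zeros(0, dtype=np.int64)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(reference.encode(), dtype=np.uint8)
    return (sliding_window_view(r, L) == q).sum(axis=1)


def dedup_matures(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Exact-sequence deduplication; first-seen name kept, aliases recorded."""
    unique: list[SequenceRecord] = []
    by_seq: dict[str, str] = {}
    aliases: dict[str, list[str]] = {}
    for rec in records:
        keeper = by_seq.get(rec.sequence)
        if keeper is None:
            by_seq[rec.sequence] = rec.id
            aliases[rec.id] = []
            unique.append(rec)
        else:
            aliases[keeper].append(rec.id)
    return unique, aliases


def align_mirna(
    query: SequenceRecord | str,
    references: Sequence[SequenceRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    query_id: str = "query",
) -> list[HomologyHit]:
    """Scan the full query against both strands of every reference.

    Identity is matching positions / query length in a gap-free semi-global
    placement. Overlapping placements on one reference strand are reduced
    greedily to the best ones; hits are sorted by identity, then position.
    """
    if isinstance(query, SequenceRecord):
        qseq, qid = query.sequence, query.id
    else:
        qseq, qid = to_rna(query), query_id
    if len(qseq) < MIN_QUERY_LEN:
        raise ValueError(f"query {qid!r} shorter than {MIN_QUERY_LEN} nt")
    L = len(qseq)
    raw: list[HomologyHit] = []
    for ref in references:
        for strand, q in (("+", qseq), ("-", reverse_complement(qseq))):
            matches = _window_matches(q, ref.sequence)
            for off in np.nonzero(matches >= min_identity * L - 1e-9)[0]:
                raw.append(
                    HomologyHit(
                        query_id=qid,
                        reference_id=ref.id,
                        start=int(off) + 1,
                        end=int(off) + L,
                        strand=strand,
                        identity=float(matches[off]) / L,
                    )
                )
    # greedy non-overlap reduction per reference strand
    raw.sort(key=lambda h: (-h.identity, h.reference_id, h.start, h.strand))
    kept: list[HomologyHit] = []
    for hit in raw:
        if any(
            k.reference_id == hit.reference_id
            and k.strand == hit.strand
            and not (hit.end < k.start or hit.start > k.end)
            for k in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (-h.identity, h.reference_id, h.start, h.strand))
    return kept


@dataclass(frozen=True)
class CandidatePrecursor:
    sequence: str  # excised strand (reverse-complemented for minus hits)
    location: GenomicLocation  # forward-strand coordinates
    mature_span: tuple[int, int]  # 1-based on the excised sequence


def extract_candidate(
    reference: SequenceRecord,
    hit: HomologyHit,
    flank: int = DEFAULT_FLANK,
) -> CandidatePrecursor:
    """Excise the hit plus bilateral flanks, truncated at reference ends."""
    n = len(reference.sequence)
    if not (1 <= hit.start <= hit.end <= n):
        raise ValueError(f"hit {hit.start}-{hit.end} outside reference {reference.id}")
    ws, we = max(1, hit.start - flank), min(n, hit.end + flank)
    if ws > hit.start - flank or we < hit.end + flank:
        logger.info("candidate at %s:%d-%d truncated at reference end", reference.id, ws, we)
    window = reference.sequence[ws - 1 : we]
    if hit.strand == "+":
        seq = window
        mature = (hit.start - ws + 1, hit.end - ws + 1)
    else:
        seq = reverse_complement(window)
        mature = (we - hit.end + 1, we - hit.start + 1)
    return CandidatePrecursor(
        sequence=seq,
        location=GenomicLocation(reference.id, ws, we, hit.strand),
        mature_span=mature,
    )


# ---------------------------------------------------------------------------
# hairpin criteria
# ---------------------------------------------------------------------------

def check_hairpin_criteria(
    candidate: str,
    mature_span: tuple[int, int],
    structure: SecondaryStructure,
    dg: float,
) -> SixCriteriaReport:
    """Evaluate the six precursor criteria on a folded candidate."""
    n = len(candidate)
    ms, me = mature_span
    if not (1 <= ms <= me <= n):
        raise ValueError(f"mature span {mature_span} outside candidate 1..{n}")

    dg_ok = dg <= -15.0
    length_ok = n > 53

    if structure.is_open:
        return SixCriteriaReport(
            dg_ok=dg_ok,
            stem_coverage_ok=False,
            bulge_ok=False,
            length_ok=length_ok,
            loop_ok=False,
            mismatch_ok=False,
            dg=dg,
            hairpin_length=n,
        )

    ann = annotate_regions(structure, mature_span=mature_span)
    loop_len = ann.loop_span[1] - ann.loop_span[0] + 1

    paired = sum(1 for p in range(ms, me + 1) if structure.pair_table[p] != 0)
    coverage = paired / (me - ms + 1)
    mismatches = (me - ms + 1) - paired

    pairs = structure.pairs
    max_bulge = 0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        a, b = i2 - i1 - 1, j1 - j2 - 1
        if a + b > 0:
            max_bulge = max(max_bulge, a + b)

    return SixCriteriaReport(
        dg_ok=dg_ok,
        stem_coverage_ok=coverage >= 0.80,
        bulge_ok=max_bulge <= 18,
        length_ok=length_ok,
        loop_ok=loop_len < 22,
        mismatch_ok=mismatches <= 6,
        dg=dg,
        stem_coverage=coverage,
        max_bulge=max_bulge,
        hairpin_length=n,
        loop_length=loop_len,
        mismatches=mismatches,
    )


# ---------------------------------------------------------------------------
# read cleaning and contaminant annotation
# ---------------------------------------------------------------------------

def _find_adapter(seq: str, adapter: str, min_overlap: int = 6) -> Optional[int]:
    """Leftmost 3'-adapter match start, allowing 1 mismatch per 10 aligned nt."""
    n = len(seq)
    for p in range(0, n - min_overlap + 1):
        k = min(len(adapter), n - p)
        if k < min_overlap:
            break
        allowed = k // 10
        mism = sum(1 for a, b in zip(seq[p : p + k], adapter[:k]) if a != b)
        if mism <= allowed:
            return p
    return None


def _is_poly_a(seq: str) -> bool:
    return "A" * 8 in seq or (len(seq) > 0 and seq.count("A") / len(seq) > 0.80)


def clean_reads(
    reads: Sequence[SequenceRecord],
    adapter_3p: str,
    adapter_5p: Optional[str] = None,
    min_len: int = MIN_QUERY_LEN,
    min_mean_quality: float = 20.0,
) -> tuple[list[CleanedRead], ReadAccounting]:
    """Adapter/quality/length cleaning with collapsed output and accounting.

    Reads containing the 5' adapter are discarded; the 3' adapter is
    trimmed at its leftmost match (>= 6 nt overlap, <= 1 mismatch per 10
    aligned nt); poly(A) reads (>= 8 consecutive A, or > 80% A after
    trimming), reads of mean Phred < 20, and reads shorter than ``min_len``
    after trimming are discarded. Identical survivors are collapsed.
    """
    if not adapter_3p:
        raise ValueError("3' adapter must be non-empty")
    a3 = to_rna(adapter_3p)
    a5 = to_rna(adapter_5p) if adapter_5p else None
    counts: dict[str, int] = {}
    reasons = {"adapter5": 0, "poly_a": 0, "quality": 0, "short": 0}
    for read in reads:
        seq = read.sequence
        if a5 and a5 in seq:
            reasons["adapter5"] += 1
            continue
        cut = _find_adapter(seq, a3)
        if cut is not None:
            seq = seq[:cut]
        if _is_poly_a(seq):
            reasons["poly_a"] += 1
            continue
        if read.quality is not None and len(seq) > 0:
            if float(np.mean(read.quality[: len(seq)])) < min_mean_quality:
                reasons["quality"] += 1
                continue
        if len(seq) < min_len:
            reasons["short"] += 1
            continue
        counts[seq] = counts.get(seq, 0) + 1
    cleaned = [
        CleanedRead(sequence=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    accounting = ReadAccounting(
        raw_count=len(reads),
        cleaned_count=sum(counts.values()),
    )
    logger.info("clean_reads: %s discarded %s", accounting.as_dict(), reasons)
    return cleaned, accounting


def annotate_contaminants(
    cleaned: Sequence[CleanedRead],
    contaminant_sets: dict[str, Sequence[SequenceRecord]],
    accounting: Optional[ReadAccounting] = None,
) -> tuple[list[CleanedRead], ReadAccounting]:
    """Classify reads matching a contaminant sequence full-length with
    <= 1 mismatch (either strand); priority rRNA > tRNA > snRNA > repeat.

    Returns newly-labeled reads plus an accounting whose per-class counts
    are collapsed-read multiplicities.
    """
    for cls in contaminant_sets:
        if cls not in CONTAMINANT_CLASSES:
            raise ValueError(f"unknown contaminant class {cls!r}")
    out: list[CleanedRead] = []
    class_counts = {cls: 0 for cls in CONTAMINANT_CLASSES if cls in contaminant_sets}
    for read in cleaned:
        label = "unannotated"
        for cls in CONTAMINANT_CLASSES:
            refs = contaminant_sets.get(cls)
            if not refs:
                continue
            hit = any(
                m.size and m.max() >= len(q) - 1
                for ref in refs
                for q in (read.sequence, reverse_complement(read.sequence))
                for m in (_window_matches(q, ref.sequence),)
            )
            if hit:
                label = cls
                class_counts[cls] = class_counts.get(cls, 0) + read.count
                break
        out.append(replace(read, annotation_class=label))
    cleaned_total = sum(r.count for r in cleaned)
    acc = ReadAccounting(
        raw_count=accounting.raw_count if accounting else cleaned_total,
        cleaned_count=accounting.cleaned_count if accounting else cleaned_total,
        contaminant_counts=class_counts,
    )
    return out, acc


# ---------------------------------------------------------------------------
# read-based discovery
# ---------------------------------------------------------------------------

def _exact_matches(read_seq: str, references: Sequence[SequenceRecord]):
    """All exact placements of a read: (ref_index, strand, start, end) 1-based."""
    for ri, ref in enumerate(references):
        for strand, q in (("+", read_seq), ("-", reverse_complement(read_seq))):
            off = ref.sequence.find(q)
            while off != -1:
                yield ri, strand, off + 1, off + len(q)
                off = ref.sequence.find(q, off + 1)


def _span_within_arm(ann: HairpinAnnotation, span: tuple[int, int]) -> Optional[str]:
    labels = {ann.labels[p - 1] for p in range(span[0], span[1] + 1)}
    if labels == {"stem5"}:
        return "stem5"
    if labels == {"stem3"}:
        return "stem3"
    return None


def discover_from_reads(
    unannotated: Sequence[CleanedRead],
    references: Sequence[SequenceRecord],
    min_locus_reads: int = DEFAULT_MIN_LOCUS_READS,
    flank: int = DEFAULT_FLANK,
    locus_merge_gap: int = 30,
) -> list[CatalogEntry]:
    """Stack exact-matching reads into loci, fold, and validate hairpins.

    Read stacks separated by at most ``locus_merge_gap`` nt chain into one
    locus, so mature- and star-arm stacks of one hairpin (separated by the
    terminal loop) are evaluated together. A locus is kept iff its
    dominant read lies entirely within one arm of the folded candidate,
    the six criteria pass with that read as the mature, and the locus
    holds at least ``min_locus_reads`` reads.
    """
    unannot = [r for r in unannotated if r.annotation_class == "unannotated"]
    placements: dict[tuple[int, str], list[tuple[int, int, CleanedRead]]] = {}
    for read in unannot:
        for ri, strand, s, e in _exact_matches(read.sequence, references):
            placements.setdefault((ri, strand), []).append((s, e, read))

    entries: list[CatalogEntry] = []
    counter = 0
    for (ri, strand) in sorted(placements):
        ref = references[ri]
        stack = sorted(placements[(ri, strand)], key=lambda t: (t[0], t[1]))
        # single-linkage merge of overlapping/near-adjacent stacks into loci
        loci: list[list[tuple[int, int, CleanedRead]]] = []
        cur_end = -(locus_merge_gap + 2)
        for s, e, read in stack:
            if loci and s - cur_end - 1 <= locus_merge_gap:
                loci[-1].append((s, e, read))
                cur_end = max(cur_end, e)
            else:
                loci.append([(s, e, read)])
                cur_end = e
        for locus in loci:
            total = sum(r.count for _s, _e, r in locus)
            if total < min_locus_reads:
                logger.info("locus on %s rejected: %d read(s)", ref.id, total)
                continue
            ls, le = min(s for s, _e, _r in locus), max(e for _s, e, _r in locus)
            dominant = min(locus, key=lambda t: (-t[2].count, t[0], t[2].sequence))
            ws, we = max(1, ls - flank), min(len(ref.sequence), le + flank)
            window = ref.sequence[ws - 1 : we]
            mature_span = _project_span(dominant[0], dominant[1], ws, we, strand)
            assert mature_span is not None
            cand = CandidatePrecursor(
                sequence=window if strand == "+" else reverse_complement(window),
                location=GenomicLocation(ref.id, ws, we, strand),
                mature_span=mature_span,
            )
            structure, dg = fold_hairpin(cand.sequence)
            report = check_hairpin_criteria(cand.sequence, cand.mature_span, structure, dg)
            if structure.is_open:
                logger.info("locus on %s rejected: no stable fold", ref.id)
                continue
            ann = annotate_regions(structure, mature_span=cand.mature_span)
            arm = _span_within_arm(ann, cand.mature_span)
            if arm is None:
                logger.info("locus on %s rejected: mature straddles the loop", ref.id)
                continue
            if not report.overall:
                logger.info("locus on %s rejected: criteria %s", ref.id, report)
                continue
            counter += 1
            pre_id = f"srna-pre-{counter}"
            # star: most abundant read entirely on the opposite arm
            cs, ce = cand.location.start, cand.location.end
            star_span = None
            star_candidates = []
            for s, e, read in locus:
                span = _project_span(s, e, cs, ce, strand)
                if span and _span_within_arm(ann, span) not in (None, arm):
                    star_candidates.append((read.count, span))
            if star_candidates:
                star_span = max(star_candidates, key=lambda t: (t[0], -t[1][0]))[1]
            expression = sum(
                r.count
                for s, e, r in locus
                for span in (_project_span(s, e, cs, ce, strand),)
                if span and not (span[1] < cand.mature_span[0] or span[0] > cand.mature_span[1])
            )
            precursor = PrecursorHairpin(
                id=pre_id,
                sequence=cand.sequence,
                structure=structure,
                dg=dg,
                location=cand.location,
                mature_span=cand.mature_span,
                star_span=star_span,
                annotation=ann,
            )
            mature_seq = cand.sequence[cand.mature_span[0] - 1 : cand.mature_span[1]]
            mature = MatureMiRNA(
                name=f"srna-mir-{counter}",
                sequence=mature_seq,
                precursor_id=pre_id,
                location=GenomicLocation(ref.id, dominant[0], dominant[1], strand),
                conservation="specific",
                expression_count=expression,
            )
            entries.append(CatalogEntry(mature=mature, precursor=precursor, provenance="sequencing"))
    return entries


def _project_span(
    s: int, e: int, cand_start: int, cand_end: int, strand: str
) -> Optional[tuple[int, int]]:
    """Map a forward-strand interval into excised-candidate coordinates."""
    if s < cand_start or e > cand_end:
        return None
    if strand == "+":
        return (s - cand_start + 1, e - cand_start + 1)
    return (cand_end - e + 1, cand_end - s + 1)


# ---------------------------------------------------------------------------
# homology-arm driver
# ---------------------------------------------------------------------------

def discover_from_homology(
    known_matures: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    flank: int = DEFAULT_FLANK,
) -> list[CatalogEntry]:
    """Homology arm: dedup known matures, align, excise, fold, validate."""
    unique, _aliases = dedup_matures(known_matures)
    entries: list[CatalogEntry] = []
    counter = 0
    for query in unique:
        for hit in align_mirna(query, references, min_identity=min_identity):
            ref = next(r for r in references if r.id == hit.reference_id)
            cand = extract_candidate(ref, hit, flank=flank)
            structure, dg = fold_hairpin(cand.sequence)
            if structure.is_open:
                continue
            report = check_hairpin_criteria(cand.sequence, cand.mature_span, structure, dg)
            if not report.overall:
                continue
            ann = annotate_regions(structure, mature_span=cand.mature_span)
            if _span_within_arm(ann, cand.mature_span) is None:
                continue
            counter += 1
            pre_id = f"hom-pre-{counter}"
            mature_seq = cand.sequence[cand.mature_span[0] - 1 : cand.mature_span[1]]
            precursor = PrecursorHairpin(
                id=pre_id,
                sequence=cand.sequence,
                structure=structure,
                dg=dg,
                location=cand.location,
                mature_span=cand.mature_span,
                annotation=ann,
            )
            mature = MatureMiRNA(
                name=f"{query.id}-like-{counter}",
                sequence=mature_seq,
                precursor_id=pre_id,
                location=GenomicLocation(ref.id, hit.start, hit.end, hit.strand),
                conservation="conserved",
            )
            entries.append(CatalogEntry(mature=mature, precursor=precursor, provenance="homology"))
    return entries


# ---------------------------------------------------------------------------
# catalog merging
# ---------------------------------------------------------------------------

def _same_locus(a: GenomicLocation, b: GenomicLocation) -> bool:
    return (
        a.reference_id == b.reference_id
        and a.strand == b.strand
        and not (a.end < b.start or a.start > b.end)
    )


def merge_catalogs(
    homology: Sequence[CatalogEntry],
    sequencing: Sequence[CatalogEntry],
    known_matures: Sequence[SequenceRecord] = (),
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[CatalogEntry]:
    """Merge both discovery arms into a non-redundant catalog.

    Entries merge when mature sequences are identical, or one mature is a
    subsequence of the other at the same precursor locus. Merged or
    homology-found entries are conserved; sequencing-only entries are
    conserved if homologous (>= ``min_identity``) to a known mature, else
    specific. Conflicting mature assignments at one locus are kept
    separate and flagged for manual review.
    """
    merged: list[CatalogEntry] = []
    for origin, entries in (("homology", homology), ("sequencing", sequencing)):
        for entry in entries:
            partner = None
            for cand in merged:
                same_seq = entry.mature.sequence == cand.mature.sequence
                contained = (
                    entry.mature.sequence in cand.mature.sequence
                    or cand.mature.sequence in entry.mature.sequence
                ) and _same_locus(entry.precursor.location, cand.precursor.location)
                if same_seq or contained:
                    partner = cand
                    break
            if partner is not None:
                if partner.provenance != origin:
                    partner.provenance = "both"
                    partner.mature.conservation = "conserved"
                partner.mature.expression_count = max(
                    partner.mature.expression_count, entry.mature.expression_count
                )
                continue
            # conflicting mature at an already-claimed locus
            clash = any(
                _same_locus(entry.precursor.location, c.precursor.location)
                and not (
                    entry.mature.sequence in c.mature.sequence
                    or c.mature.sequence in entry.mature.sequence
                )
                and not (entry.mature.location.end < c.mature.location.start
                         or entry.mature.location.start > c.mature.location.end)
                for c in merged
            )
            new = CatalogEntry(
                mature=replace(entry.mature),
                precursor=entry.precursor,
                provenance=origin,
            )
            if clash:
                new.conflict = True
                logger.warning("locus conflict at %s; kept separate", entry.precursor.location)
            if origin == "sequencing" and known_matures:
                try:
                    hits = align_mirna(
                        entry.mature.sequence,
                        list(known_matures),
                        min_identity=min_identity,
                        query_id=entry.mature.name,
                    )
                except ValueError:
                    hits = []
                if hits:
                    new.mature.conservation = "conserved"
            merged.append(new)
    return merged


def catalog_summary(catalog: Sequence[CatalogEntry]) -> dict[str, int]:
    return {
        "total": len(catalog),
        "conserved": sum(1 for e in catalog if e.mature.conservation == "conserved"),
        "specific": sum(1 for e in catalog if e.mature.conservation == "specific"),
    }


# ---------------------------------------------------------------------------
# isomiRs and moRNAs
# ---------------------------------------------------------------------------

def detect_isomiRs(
    cleaned: Sequence[CleanedRead],
    catalog: Sequence[CatalogEntry],
    max_shift: int = 3,
) -> dict[str, list[CleanedRead]]:
    """Reads matching a precursor whose span overlaps the mature span with
    both ends within ``max_shift`` nt of the mature ends; the
    reference-identical read is excluded."""
    out: dict[str, list[CleanedRead]] = {e.mature.name: [] for e in catalog}
    for entry in catalog:
        pre = entry.precursor
        ms, me = pre.mature_span
        for read in cleaned:
            off = pre.sequence.find(read.sequence)
            while off != -1:
                s, e = off + 1, off + len(read.sequence)
                if (
                    (s, e) != (ms, me)
                    and not (e < ms or s > me)
                    and abs(s - ms) <= max_shift
                    and abs(e - me) <= max_shift
                ):
                    out[entry.mature.name].append(read)
                    break
                off = pre.sequence.find(read.sequence, off + 1)
    return out


def detect_moRNAs(
    cleaned: Sequence[CleanedRead],
    precursor: PrecursorHairpin,
    max_gap: int = 2,
) -> list[tuple[CleanedRead, tuple[int, int]]]:
    """Reads matching the precursor exactly, entirely outside the mature
    and star spans, starting or ending within ``max_gap`` nt of a
    mature/star boundary."""
    spans = [precursor.mature_span]
    if precursor.star_span is not None:
        spans.append(precursor.star_span)
    out: list[tuple[CleanedRead, tuple[int, int]]] = []
    for read in cleaned:
        off = precursor.sequence.find(read.sequence)
        while off != -1:
            s, e = off + 1, off + len(read.sequence)
            outside = all(e < a or s > b for a, b in spans)
            adjacent = any(
                (e < a and a - e - 1 <= max_gap) or (s > b and s - b - 1 <= max_gap)
                for a, b in spans
            )
            if outside and adjacent:
                out.append((read, (s, e)))
                break
            off = precursor.sequence.find(read.sequence, off + 1)
    return out


# ---------------------------------------------------------------------------
# identity-threshold calibration
# ---------------------------------------------------------------------------

def calibrate_identity_threshold(families: dict[str, Sequence[str]]) -> float:
    """Minimum within-family pairwise identity over all families.

    Identity of a pair is the best gap-free placement of the shorter
    sequence on the longer one, matching positions / shorter length — the
    same measure :func:`align_mirna` thresholds on.
    """
    minimum = None
    for _family, members in sorted(families.items()):
        seqs = [to_rna(m) for m in members]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                a, b = seqs[i], seqs[j]
                if len(a) > len(b):
                    a, b = b, a
                matches = _window_matches(a, b)
                ident = float(matches.max()) / len(a) if matches.size else 0.0
                minimum = ident if minimum is None else min(minimum, ident)
    if minimum is None:
        raise ValueError("no family with at least two members")
    return minimum
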