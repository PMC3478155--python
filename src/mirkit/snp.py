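"""SNP effects on precursor energetics and on miRNA target repertoires.

A precursor SNP is classified by the region it falls in (mature, stem,
loop, anti-stem, using the wild-type structure), and its folding-energy
change ddG = dG(mutant) - dG(wild) is interpreted against the 0.3
kcal/mol threshold below which the change is treated as negligible for
biogenesis. Because loop penalties are sequence-independent, a loop SNP
that leaves the MFE structure unchanged has ddG exactly 0.

The published direction rule is applied literally: an energy decrease is
read as reduced mature-miRNA production and an increase as increased
production. That mapping is thermodynamically counterintuitive (a more
stable hairpin is usually processed at least as well), so
``interpret_biogenesis(..., rule="inverted")`` provides the opposite
mapping.

A 3'UTR SNP yields a target *loss* for a miRNA when the wild-type UTR
carries a consensus site (both predictors, overlapping) and neither
predictor fires on the mutant UTR; a *gain* is the symmetric case. Every
other firing pattern is *unchanged*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .fold import HairpinAnnotation, annotate_regions, fold_hairpin
from .io import SequenceRecord, SNPRecord
from .targets import (
    MAX_SITE_LEN,
    TargetSite,
    UTRRecord,
    consensus,
    predict_energy,
    predict_seedtype,
)

BIOGENESIS_THRESHOLD = 0.3  # kcal/mol, minimum |ddG| that alters production

REGIONS = ("mature", "stem", "loop", "anti-stem")


@dataclass(frozen=True)
class EnergyChange:
    """Folding-energy change of a precursor SNP (mutant minus wild)."""

    ddg: float
    region: str
    interpretation: str  # increase_production | decrease_production | negligible
    dg_wild: float
    dg_mutant: float


@dataclass(frozen=True)
class GainLossCall:
    """Wild-type vs SNP-type consensus comparison for one miRNA/UTR pair."""

    mirna_id: str
    mrna_id: str
    snp: SNPRecord
    verdict: str  # gain | loss | unchanged
    wild_sites: dict
    mutant_sites: dict


def classify_snp(snp: SNPRecord, annotation: HairpinAnnotation) -> str:
    """Region of a precursor SNP: mature (overrides all), loop, anti-stem
    (the arm opposite the mature), else stem."""
    n = len(annotation.labels)
    pos = snp.position
    if not 1 <= pos <= n:
        raise ValueError(f"SNP position {pos} outside precursor 1..{n}")
    if annotation.mature_span is None:
        raise ValueError("annotation lacks a mature span")
    ms, me = annotation.mature_span
    if ms <= pos <= me:
        return "mature"
    label = annotation.labels[pos - 1]
    if label == "loop":
        return "loop"
    if label == annotation.anti_stem_side:
        return "anti-stem"
    return "stem"


def apply_snp(sequence: str, snp: SNPRecord) -> str:
    """Apply a single-base substitution, verifying the reference allele."""
    if snp.position > len(sequence):
        raise ValueError(f"SNP position {snp.position} beyond sequence end {len(sequence)}")
    found = sequence[snp.position - 1]
    if found != snp.ref_allele:
        raise ValueError(
            f"reference mismatch at {snp.reference_id}:{snp.position}: "
            f"sequence has {found}, SNP table says {snp.ref_allele}"
        )
    return sequence[: snp.position - 1] + snp.alt_allele + sequence[snp.position :]


def interpret_biogenesis(
    ddg: float,
    threshold: float = BIOGENESIS_THRESHOLD,
    rule: str = "as_published",
) -> str:
    """Map a ddG to its biogenesis interpretation.

    |ddG| < threshold is negligible. Under the published rule a decrease
    in hairpin energy maps to decreased mature production and an increase
    to increased production; ``rule="inverted"`` swaps the directions.
    """
    if abs(ddg) < threshold:
        return "negligible"
    decreased = ddg <= -threshold
    if rule == "inverted":
        decreased = not decreased
    return "decrease_production" if decreased else "increase_production"


FoldEngine = Callable[[str], tuple]


def _default_engine(seq: str):
    structure, dg = fold_hairpin(seq)
    return structure, dg


def ddg(
    precursor: str,
    snp: SNPRecord,
    mature_span: tuple[int, int],
    engine: Optional[FoldEngine] = None,
    threshold: float = BIOGENESIS_THRESHOLD,
    rule: str = "as_published",
) -> EnergyChange:
    """Fold wild and mutant precursors with the same engine and compare.

    ddG = dG(mutant) - dG(wild); the region is classified on the
    wild-type structure.
    """
    engine = engine or _default_engine
    mutant = apply_snp(precursor, snp)
    wild_structure, dg_wild = engine(precursor)
    _mut_structure, dg_mut = engine(mutant)
    annotation = annotate_regions(wild_structure, mature_span=mature_span)
    region = classify_snp(snp, annotation)
    delta = round(dg_mut - dg_wild, 6)
    return EnergyChange(
        ddg=delta,
        region=region,
        interpretation=interpret_biogenesis(delta, threshold=threshold, rule=rule),
        dg_wild=dg_wild,
        dg_mutant=dg_mut,
    )


# ---------------------------------------------------------------------------
# target gain/loss
# ---------------------------------------------------------------------------

def gain_loss_verdict(
    a_wild: bool,
    b_wild: bool,
    a_mut: bool,
    b_mut: bool,
    consensus_wild: Optional[bool] = None,
    consensus_mut: Optional[bool] = None,
) -> str:
    """Verdict from the four predictor firing flags.

    loss: consensus on wild type and neither predictor fires on the SNP
    type; gain: the symmetric pattern; everything else: unchanged. Of the
    16 boolean firing patterns exactly one is loss and one is gain.
    """
    if consensus_wild is None:
        consensus_wild = a_wild and b_wild
    if consensus_mut is None:
        consensus_mut = a_mut and b_mut
    if consensus_wild and not a_mut and not b_mut:
        return "loss"
    if consensus_mut and not a_wild and not b_wild:
        return "gain"
    return "unchanged"


def call_gain_loss(
    mirnas: Sequence[SequenceRecord],
    utr: UTRRecord,
    snp: SNPRecord,
    ddg_cutoff: float = -9.0,
) -> list[GainLossCall]:
    """Compare wild vs SNP-type target predictions around a 3'UTR SNP.

    Both predictors run on both alleles, restricted to sites overlapping
    the SNP position +/- (max site length - 1). One call is produced per
    miRNA with any site in that window on either allele.
    """
    if snp.position > len(utr.sequence):
        raise ValueError(f"SNP position {snp.position} outside the {utr.mrna_id} 3'UTR")
    mutant = UTRRecord(
        mrna_id=utr.mrna_id,
        sequence=apply_snp(utr.sequence, snp),
        offset=utr.offset,
        mrna_length=utr.mrna_length,
    )
    lo = snp.position - (MAX_SITE_LEN - 1)
    hi = snp.position + (MAX_SITE_LEN - 1)

    def windowed(sites: Sequence[TargetSite]) -> list[TargetSite]:
        return [s for s in sites if not (s.end < lo or s.start > hi)]

    calls: list[GainLossCall] = []
    for mi in mirnas:
        a_wild = windowed(predict_seedtype(mi, utr))
        b_wild = windowed(predict_energy(mi, utr, ddg_cutoff=ddg_cutoff))
        a_mut = windowed(predict_seedtype(mi, mutant))
        b_mut = windowed(predict_energy(mi, mutant, ddg_cutoff=ddg_cutoff))
        if not (a_wild or b_wild or a_mut or b_mut):
            continue
        verdict = gain_loss_verdict(
            bool(a_wild),
            bool(b_wild),
            bool(a_mut),
            bool(b_mut),
            consensus_wild=len(consensus(a_wild, b_wild)) > 0,
            consensus_mut=len(consensus(a_mut, b_mut)) > 0,
        )
        calls.append(
            GainLossCall(
                mirna_id=mi.id,
                mrna_id=utr.mrna_id,
                snp=snp,
                verdict=verdict,
                wild_sites={"A_seedtype": a_wild, "B_energy": b_wild},
                mutant_sites={"A_seedtype": a_mut, "B_energy": b_mut},
            )
        )
    return calls
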