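"""Seed-based miRNA target prediction with two predictors and a consensus.

Predictor A (``seedtype``) reports canonical Watson–Crick seed sites —
6mer (miRNA positions 2–7), 7mer-m8 (2–8), 7mer-A1 (2–7 plus an A on the
UTR opposite position 1), and 8mer (2–8 plus A1) — with no wobbles and no
mismatches, collapsing overlapping matches to the strongest type.

Predictor B (``energy``) accepts 6–8-nt seed duplexes starting at miRNA
position 2 with zero mismatches and at most one G:U wobble (none in
6mers), then scores the full miRNA:UTR duplex with the nearest-neighbor
stacking table in duplex mode (bimolecular initiation, no hairpin) and
keeps sites whose duplex dG is at or below the cutoff (default
-9 kcal/mol).

A miRNA–mRNA pair is a consensus target when both predictors report
overlapping sites for it; the consensus false-positive rate on a labeled
pair set is never above either single predictor's.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

from .fold import DEFAULT_MODEL, EnergyModel
from .io import SequenceRecord, reverse_complement, to_rna

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_TYPE_RANK = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1, "6mer": 0}
MAX_SITE_LEN = 8

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class UTRRecord:
    """A 3'UTR with its 1-based offset inside the parent mRNA."""

    mrna_id: str
    sequence: str
    offset: int = 1
    mrna_length: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.mrna_id}: empty 3'UTR")
        if self.offset < 1:
            raise ValueError(f"{self.mrna_id}: UTR offset must be >= 1 (1-based)")
        if self.mrna_length is not None and self.offset + len(self.sequence) - 1 > self.mrna_length:
            raise ValueError(f"{self.mrna_id}: UTR extends past the mRNA end")


@dataclass(frozen=True)
class TargetSite:
    """A predicted miRNA binding site on a 3'UTR (1-based inclusive)."""

    mirna_id: str
    mrna_id: str
    start: int
    end: int
    site_type: str
    gu_count: int = 0
    duplex_dg: Optional[float] = None
    predictor: str = "A_seedtype"

    def overlaps(self, other: "TargetSite") -> bool:
        return not (self.end < other.start or self.start > other.end)


@dataclass(frozen=True)
class LabeledPair:
    mirna: SequenceRecord
    utr: UTRRecord
    label: str  # positive | negative


def _mirna(mirna: SequenceRecord | str, mirna_id: str) -> tuple[str, str]:
    if isinstance(mirna, SequenceRecord):
        return mirna.sequence, mirna.id
    return to_rna(mirna), mirna_id


def _complement(base: str) -> str:
    return {"A": "U", "U": "A", "G": "C", "C": "G"}.get(base, "N")


# ---------------------------------------------------------------------------
# predictor A: canonical seed types
# ---------------------------------------------------------------------------

def predict_seedtype(
    mirna: SequenceRecord | str,
    utr: UTRRecord,
    mirna_id: str = "mirna",
) -> list[TargetSite]:
    """Canonical seed-match scan, one site per match at its strongest type."""
    mi, mid = _mirna(mirna, mirna_id)
    if len(mi) < 8:
        raise ValueError(f"{mid}: miRNA must be >= 8 nt for seed matching")
    seq = utr.sequence
    seed6 = reverse_complement(mi[1:7])  # complement of positions 2-7
    m8 = _complement(mi[7])  # UTR base pairing miRNA position 8 (5' of site)
    sites: list[TargetSite] = []
    for o in range(len(seq) - 5):
        if seq[o : o + 6] != seed6:
            continue
        has_m8 = o >= 1 and seq[o - 1] == m8
        has_a1 = o + 6 < len(seq) and seq[o + 6] == "A"
        if has_m8 and has_a1:
            stype, s, e = "8mer", o - 1, o + 6
        elif has_m8:
            stype, s, e = "7mer-m8", o - 1, o + 5
        elif has_a1:
            stype, s, e = "7mer-A1", o, o + 6
        else:
            stype, s, e = "6mer", o, o + 5
        sites.append(
            TargetSite(
                mirna_id=mid,
                mrna_id=utr.mrna_id,
                start=s + 1,
                end=e + 1,
                site_type=stype,
                predictor="A_seedtype",
            )
        )
    return sites


# ---------------------------------------------------------------------------
# predictor B: seed duplex + energy cutoff
# ---------------------------------------------------------------------------

def _duplex_energy(
    mi: str,
    seq: str,
    o: int,
    k: int,
    model: EnergyModel,
) -> float:
    """Full miRNA:UTR duplex dG anchored on a seed of length k at offset o.

    Pairing is antiparallel: miRNA position 2 pairs the 3'-most seed base.
    The helix is extended outward from the seed in both directions while
    bases remain complementary (WC or G:U), then scored as bimolecular
    initiation plus nearest-neighbor stacks.
    """
    # pair list along the miRNA, 5'->3': (mi index, utr index), 0-based
    pairs = [(1 + t, o + k - 1 - t) for t in range(k)]
    # extend toward miRNA position 1 (UTR 3' side)
    mi_i, utr_j = 0, o + k
    while mi_i >= 0 and utr_j < len(seq):
        duo = (mi[mi_i], seq[utr_j])
        if duo in _WC or duo in _GU:
            pairs.insert(0, (mi_i, utr_j))
            mi_i -= 1
            utr_j += 1
        else:
            break
    # extend toward the miRNA 3' end (UTR 5' side)
    mi_i, utr_j = 1 + k, o - 1
    while mi_i < len(mi) and utr_j >= 0:
        duo = (mi[mi_i], seq[utr_j])
        if duo in _WC or duo in _GU:
            pairs.append((mi_i, utr_j))
            mi_i += 1
            utr_j -= 1
        else:
            break
    cents = model.duplex_init
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        cents += model.stack_energy(mi[i1] + seq[j1], mi[i2] + seq[j2])
    return cents / 100.0


def predict_energy(
    mirna: SequenceRecord | str,
    utr: UTRRecord,
    ddg_cutoff: float = -9.0,
    mirna_id: str = "mirna",
    model: EnergyModel = DEFAULT_MODEL,
) -> list[TargetSite]:
    """Energy predictor: perfect 6–8-nt seeds (<= 1 G:U in 7/8-mers, none
    in 6mers) kept when the full duplex dG is at or below ``ddg_cutoff``."""
    mi, mid = _mirna(mirna, mirna_id)
    if len(mi) < 8:
        raise ValueError(f"{mid}: miRNA must be >= 8 nt")
    seq = utr.sequence
    best_at_anchor: dict[int, TargetSite] = {}
    for k in (6, 7, 8):
        seed = mi[1 : 1 + k]
        max_gu = 0 if k == 6 else 1
        for o in range(len(seq) - k + 1):
            gu = 0
            ok = True
            for t in range(k):
                duo = (seed[t], seq[o + k - 1 - t])
                if duo in _WC:
                    continue
                if duo in _GU:
                    gu += 1
                    if gu > max_gu:
                        ok = False
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            dg = _duplex_energy(mi, seq, o, k, model)
            if dg > ddg_cutoff:
                continue
            anchor = o + k - 1  # UTR base pairing miRNA position 2
            site = TargetSite(
                mirna_id=mid,
                mrna_id=utr.mrna_id,
                start=o + 1,
                end=o + k,
                site_type={6: "6mer", 7: "7mer-m8", 8: "8mer"}[k],
                gu_count=gu,
                duplex_dg=dg,
                predictor="B_energy",
            )
            prev = best_at_anchor.get(anchor)
            if prev is None or (prev.end - prev.start) < (site.end - site.start):
                best_at_anchor[anchor] = site
    return [best_at_anchor[a] for a in sorted(best_at_anchor)]


# ---------------------------------------------------------------------------
# consensus and false-positive rate
# ---------------------------------------------------------------------------

def consensus(
    sites_a: Sequence[TargetSite],
    sites_b: Sequence[TargetSite],
    require_overlap: bool = True,
) -> list[TargetSite]:
    """Consensus sites: A-sites whose miRNA–mRNA pair is also reported by
    predictor B with an overlapping interval (or merely the same pair when
    ``require_overlap`` is off)."""
    by_pair_b: dict[tuple[str, str], list[TargetSite]] = {}
    for s in sites_b:
        by_pair_b.setdefault((s.mirna_id, s.mrna_id), []).append(s)
    out: list[TargetSite] = []
    for a in sites_a:
        partners = by_pair_b.get((a.mirna_id, a.mrna_id), [])
        if not partners:
            continue
        if require_overlap and not any(a.overlaps(b) for b in partners):
            continue
        out.append(replace(a, predictor="consensus"))
    return out


Predictor = Callable[[SequenceRecord, UTRRecord], Sequence[TargetSite]]


def estimate_fpr(predict: Predictor, pairs: Sequence[LabeledPair]) -> float:
    """Fraction of negative pairs for which the predictor reports a site."""
    negatives = [p for p in pairs if p.label == "negative"]
    if not negatives:
        raise ValueError("no negative pairs: FPR undefined")
    flagged = sum(1 for p in negatives if len(predict(p.mirna, p.utr)) > 0)
    return flagged / len(negatives)


def fpr_report(
    pairs: Sequence[LabeledPair],
    ddg_cutoff: float = -9.0,
) -> dict[str, float]:
    """FPR of predictor A, predictor B, and their consensus on one set."""
    def _a(mi, utr):
        return predict_seedtype(mi, utr)

    def _b(mi, utr):
        return predict_energy(mi, utr, ddg_cutoff=ddg_cutoff)

    def _c(mi, utr):
        return consensus(_a(mi, utr), _b(mi, utr))

    return {
        "A_seedtype": estimate_fpr(_a, pairs),
        "B_energy": estimate_fpr(_b, pairs),
        "consensus": estimate_fpr(_c, pairs),
    }


# ---------------------------------------------------------------------------
# antisense miRNAs
# ---------------------------------------------------------------------------

def find_antisense_mirnas(
    matures: Sequence[SequenceRecord],
    mrnas: Sequence[SequenceRecord],
) -> list[tuple[str, str, int, int]]:
    """(miRNA id, mRNA id, start, end) for every exact occurrence of the
    reverse complement of a full mature miRNA inside a sense mRNA."""
    out: list[tuple[str, str, int, int]] = []
    for mi in matures:
        probe = reverse_complement(mi.sequence)
        for mrna in mrnas:
            off = mrna.sequence.find(probe)
            while off != -1:
                out.append((mi.id, mrna.id, off + 1, off + len(probe)))
                off = mrna.sequence.find(probe, off + 1)
    return out
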