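"""Single-hairpin RNA secondary-structure prediction and energy evaluation.

The model is deliberately restricted to the shapes this package scores:
pseudoknot-free structures with exactly one hairpin loop and no multiloops
(a single helix chain interrupted by bulges and internal loops). The
minimum free energy over that space is found by a dynamic program over
closing pairs with interior extensions capped at ``max_interior`` unpaired
nucleotides, using a nearest-neighbor stacking table and size-only
(Jacobson–Stockmayer style) loop penalties.

Energies are handled internally as integer centi-kcal/mol so that ties are
exact and tie-breaking is deterministic: among equal-energy structures the
5'-most, then longest, closing helix wins.

Any external folding engine can be substituted anywhere a fold is
consumed: an engine is simply a callable ``sequence -> (dot_bracket, dG)``.
:func:`viennarna_engine` builds one from a local ``RNAfold`` executable for
users who want Turner-parameter energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterator, Optional

import numpy as np

from .io import RNA_ALPHABET

__all__ = [
    "SecondaryStructure",
    "EnergyModel",
    "HairpinAnnotation",
    "DEFAULT_MODEL",
    "fold_hairpin",
    "energy_of",
    "annotate_regions",
    "parse_structure",
    "exhaustive_fold",
    "enumerate_hairpin_chains",
    "viennarna_engine",
]

MIN_HAIRPIN_LOOP = 3
DEFAULT_MAX_INTERIOR = 30

_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")


class StructureError(ValueError):
    """Invalid secondary structure (shape, balance, or disallowed pair)."""


class AlphabetError(ValueError):
    """Sequence contains non-RNA characters."""


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

def _reverse_pair(p: str) -> str:
    return p[::-1]


# Nearest-neighbor stack free energies, kcal/mol, keyed (outer, inner) where
# the outer pair (i,j) closes the inner pair (i+1,j-1). Values are
# Turner-like magnitudes constrained to the model's invariants (all
# stabilizing) and to thermodynamic symmetry E[p,q] == E[rev(q),rev(p)].
_STACK_CLASSES = {
    ("AU", "AU"): -0.9,
    ("AU", "UA"): -1.1,
    ("UA", "AU"): -1.3,
    ("AU", "GC"): -2.2,
    ("AU", "CG"): -2.1,
    ("UA", "GC"): -2.4,
    ("UA", "CG"): -2.1,
    ("GC", "GC"): -3.3,
    ("GC", "CG"): -3.4,
    ("CG", "GC"): -2.9,
    ("AU", "GU"): -0.6,
    ("AU", "UG"): -1.4,
    ("UA", "GU"): -1.0,
    ("UA", "UG"): -1.3,
    ("GC", "GU"): -1.5,
    ("GC", "UG"): -2.5,
    ("CG", "GU"): -1.4,
    ("CG", "UG"): -2.1,
    ("GU", "GU"): -0.5,
    ("GU", "UG"): -0.4,
    ("UG", "GU"): -0.3,
}


def _build_stack_table() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {}
    for (p, q), e in _STACK_CLASSES.items():
        cents = round(e * 100)
        table[(p, q)] = cents
        table[(_reverse_pair(q), _reverse_pair(p))] = cents
    assert len(table) == 36
    return table


_LN_COEF = 108  # 1.75 * RT at 37 degC, centi-kcal/mol
# large bulges/internal loops are penalized beyond the Jacobson-Stockmayer
# log term (0.45 kcal/mol per unpaired nt past 6), keeping wide interior
# excursions realistically expensive; penalties remain size-only
_LINEAR_COEF = 45


@dataclass(frozen=True)
class EnergyModel:
    """Additive nearest-neighbor model with size-only loop penalties.

    Loop penalties depend on loop length only, never on sequence; as a
    consequence a substitution at an unpaired loop position leaves the
    energy of a fixed structure unchanged.
    """

    stack: dict[tuple[str, str], int]  # centi-kcal/mol, all < 0
    duplex_init: int = 410  # bimolecular initiation, centi-kcal/mol

    def stack_energy(self, outer: str, inner: str) -> int:
        try:
            return self.stack[(outer, inner)]
        except KeyError:
            raise StructureError(f"disallowed pair stack {outer}/{inner}") from None

    @staticmethod
    def hairpin_penalty(n: int) -> int:
        if n < MIN_HAIRPIN_LOOP:
            raise StructureError(f"hairpin loop of {n} < {MIN_HAIRPIN_LOOP} nt")
        return 540 + round(_LN_COEF * math.log(n / 3))

    @staticmethod
    def bulge_penalty(n: int) -> int:
        if n < 1:
            raise ValueError("bulge size must be >= 1")
        return 380 + round(_LN_COEF * math.log(n)) + _LINEAR_COEF * max(0, n - 6)

    @staticmethod
    def internal_penalty(n: int) -> int:
        if n < 2:
            raise ValueError("internal loop size must be >= 2")
        return 410 + round(_LN_COEF * math.log(n / 2)) + _LINEAR_COEF * max(0, n - 6)

    def interior_penalty(self, a: int, b: int) -> int:
        """Cost of an interior extension leaving a/b unpaired nt per side."""
        if a == 0 and b == 0:
            raise ValueError("a stack is not an interior loop")
        if a == 0 or b == 0:
            return self.bulge_penalty(a + b)
        return self.internal_penalty(a + b)


DEFAULT_MODEL = EnergyModel(stack=_build_stack_table())


def pair_allowed(a: str, b: str) -> bool:
    return a + b in _PAIRS


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecondaryStructure:
    """Dot-bracket string plus a 1-based pair table (0 = unpaired)."""

    dot_bracket: str
    pair_table: tuple[int, ...]  # length n+1; index 0 unused

    def __len__(self) -> int:
        return len(self.dot_bracket)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """(i, j) pairs with i < j, 1-based, sorted by i."""
        return [
            (i, self.pair_table[i])
            for i in range(1, len(self.dot_bracket) + 1)
            if self.pair_table[i] > i
        ]

    @property
    def is_open(self) -> bool:
        return all(p == 0 for p in self.pair_table[1:])


def parse_structure(dot_bracket: str) -> SecondaryStructure:
    """Parse a dot-bracket string; rejects unbalanced brackets."""
    n = len(dot_bracket)
    table = [0] * (n + 1)
    stack: list[int] = []
    for pos, ch in enumerate(dot_bracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            table[i], table[pos] = pos, i
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[-1]}")
    return SecondaryStructure(dot_bracket, tuple(table))


def _chain_of(structure: SecondaryStructure) -> list[tuple[int, int]]:
    """The helix chain of a single-hairpin structure, outermost first.

    Raises :class:`StructureError` for open structures, sibling helices
    (multiloops) or hairpin loops shorter than the minimum.
    """
    pairs = structure.pairs
    if not pairs:
        raise StructureError("open structure contains no hairpin loop")
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 < j2 < j1):
            raise StructureError(
                f"pairs ({i1},{j1}) and ({i2},{j2}) are not nested in one helix chain"
            )
    pi, pj = pairs[-1]
    if pj - pi - 1 < MIN_HAIRPIN_LOOP:
        raise StructureError(f"hairpin loop of {pj - pi - 1} nt below minimum")
    return pairs


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-RNA characters {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# energy evaluation of a given structure
# ---------------------------------------------------------------------------

def energy_of(
    sequence: str,
    structure: SecondaryStructure | str,
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Free energy (kcal/mol) of ``structure`` on ``sequence``.

    The structure must be open or a valid single-hairpin shape with all
    pairs drawn from {AU, UA, GC, CG, GU, UG}.
    """
    seq = _check_sequence(sequence)
    if isinstance(structure, str):
        structure = parse_structure(structure)
    if len(structure) != len(seq):
        raise StructureError("structure length != sequence length")
    if structure.is_open:
        return 0.0
    chain = _chain_of(structure)
    for i, j in chain:
        if not pair_allowed(seq[i - 1], seq[j - 1]):
            raise StructureError(f"non-complementary pair {seq[i - 1]}{seq[j - 1]} at ({i},{j})")
    cents = 0
    for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
        a, b = i2 - i1 - 1, j1 - j2 - 1
        if a == 0 and b == 0:
            cents += model.stack_energy(seq[i1 - 1] + seq[j1 - 1], seq[i2 - 1] + seq[j2 - 1])
        else:
            cents += model.interior_penalty(a, b)
    pi, pj = chain[-1]
    cents += model.hairpin_penalty(pj - pi - 1)
    return cents / 100.0


# ---------------------------------------------------------------------------
# MFE fold (restricted dynamic program)
# ---------------------------------------------------------------------------

_INF = np.iinfo(np.int64).max // 4


@lru_cache(maxsize=8)
def _interior_cost_matrix(w: int) -> np.ndarray:
    """pen[a, b] for interior extensions, INF where a + b > w or a = b = 0."""
    pen = np.full((w + 1, w + 1), _INF, dtype=np.int64)
    model = DEFAULT_MODEL
    for a in range(w + 1):
        for b in range(w + 1):
            if a == 0 and b == 0:
                continue  # stack; sequence-dependent, filled per closing pair
            if a + b <= w:
                pen[a, b] = model.interior_penalty(a, b)
    return pen


def fold_hairpin(
    sequence: str,
    model: EnergyModel = DEFAULT_MODEL,
    max_interior: int = DEFAULT_MAX_INTERIOR,
) -> tuple[SecondaryStructure, float]:
    """Minimum-free-energy single-hairpin structure of ``sequence``.

    Returns the optimal structure among all pseudoknot-free structures with
    exactly one hairpin loop and no multiloops; if no structure has energy
    below zero, the open structure with dG = 0 is returned.
    """
    seq = _check_sequence(sequence)
    n = len(seq)
    if n < 10:
        raise ValueError(f"sequence of {n} nt is too short to fold (minimum 10)")
    w = max_interior

    can_pair = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            can_pair[i, j] = pair_allowed(seq[i], seq[j])

    if model is DEFAULT_MODEL:
        pen = _interior_cost_matrix(w)
    else:
        pen = np.full((w + 1, w + 1), _INF, dtype=np.int64)
        for a in range(w + 1):
            for b in range(w + 1):
                if (a, b) != (0, 0) and a + b <= w:
                    pen[a, b] = model.interior_penalty(a, b)

    hairpin_pen = [0] * (n + 1)
    for ln in range(MIN_HAIRPIN_LOOP, n + 1):
        hairpin_pen[ln] = model.hairpin_penalty(ln)

    V = np.full((n, n), _INF, dtype=np.int64)
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not can_pair[i, j]:
                continue
            best = hairpin_pen[span - 1]
            # interior extensions to an inner closing pair (k, l)
            kmax = min(i + 1 + w, j - MIN_HAIRPIN_LOOP - 2)
            if kmax >= i + 1:
                lmin = max(j - 1 - w, i + 2)
                A = kmax - i  # rows: k = i+1 .. kmax
                B = j - lmin  # cols: l = j-1 down to lmin
                block = V[i + 1 : i + 1 + A, lmin : j][:, ::-1]
                cost = pen[:A, :B].copy()
                if can_pair[i + 1, j - 1]:
                    cost[0, 0] = model.stack_energy(seq[i] + seq[j], seq[i + 1] + seq[j - 1])
                total = cost + block
                inner = total.min() if total.size else _INF
                if inner < best:
                    best = int(inner)
            V[i, j] = best

    finite = V < _INF
    if not finite.any() or V[finite].min() >= 0:
        open_struct = SecondaryStructure("." * n, tuple([0] * (n + 1)))
        return open_struct, 0.0
    vmin = int(V[finite].min())

    # closing pair: 5'-most, then longest helix (smallest i, then largest j)
    close = None
    for i in range(n):
        js = np.nonzero(V[i] == vmin)[0]
        if js.size:
            close = (i, int(js[-1]))
            break
    assert close is not None

    # traceback, re-applying the same tie-break at every step
    table = [0] * (n + 1)
    i, j = close
    while True:
        table[i + 1], table[j + 1] = j + 1, i + 1
        target = int(V[i, j])
        if target == hairpin_pen[j - i - 1]:
            break
        found = False
        for k in range(i + 1, min(i + 1 + w, j - MIN_HAIRPIN_LOOP - 2) + 1):
            a = k - i - 1
            for l in range(j - 1, k + MIN_HAIRPIN_LOOP, -1):
                b = j - l - 1
                if a + b > w or V[k, l] >= _INF:
                    continue
                if a == 0 and b == 0:
                    if not can_pair[k, l]:
                        continue
                    cost = model.stack_energy(seq[i] + seq[j], seq[k] + seq[l])
                else:
                    cost = int(pen[a, b])
                    if cost >= _INF:
                        continue
                if cost + int(V[k, l]) == target:
                    i, j = k, l
                    found = True
                    break
            if found:
                break
        assert found, "traceback failed to reproduce the DP optimum"

    db = "".join(
        "(" if table[p] > p else (")" if 0 < table[p] < p else ".")
        for p in range(1, n + 1)
    )
    return SecondaryStructure(db, tuple(table)), vmin / 100.0


# ---------------------------------------------------------------------------
# exhaustive reference (independent of the DP; for validation at small n)
# ---------------------------------------------------------------------------

def enumerate_hairpin_chains(
    sequence: str,
) -> Iterator[tuple[tuple[tuple[int, int], ...], int]]:
    """Yield every single-hairpin helix chain with its energy (centi-kcal).

    A chain is a maximal-to-innermost tuple of nested 1-based pairs; every
    valid single-hairpin structure of the sequence is produced exactly
    once. Exponential in sequence length; intended for n <= ~20.
    """
    seq = _check_sequence(sequence)
    n = len(seq)
    model = DEFAULT_MODEL

    def rec(i: int, j: int, chain: list[tuple[int, int]], acc: int):
        # close with a hairpin loop here
        if j - i - 1 >= MIN_HAIRPIN_LOOP:
            yield tuple(chain), acc + model.hairpin_penalty(j - i - 1)
        for k in range(i + 1, j - MIN_HAIRPIN_LOOP):
            for l in range(j - 1, k + MIN_HAIRPIN_LOOP, -1):
                if not pair_allowed(seq[k - 1], seq[l - 1]):
                    continue
                a, b = k - i - 1, j - l - 1
                if a == 0 and b == 0:
                    cost = model.stack_energy(seq[i - 1] + seq[j - 1], seq[k - 1] + seq[l - 1])
                else:
                    cost = model.interior_penalty(a, b)
                chain.append((k, l))
                yield from rec(k, l, chain, acc + cost)
                chain.pop()

    for i in range(1, n + 1):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n + 1):
            if pair_allowed(seq[i - 1], seq[j - 1]):
                yield from rec(i, j, [(i, j)], 0)


def exhaustive_fold(sequence: str) -> float:
    """MFE (kcal/mol) by brute-force enumeration of all single-hairpin
    structures, with the open structure (0) as fallback. No interior-size
    cap is applied, so for n <= 20 this is the exact optimum the DP must
    reproduce."""
    best = 0
    for _chain, cents in enumerate_hairpin_chains(sequence):
        if cents < best:
            best = cents
    return best / 100.0


# ---------------------------------------------------------------------------
# region annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinAnnotation:
    """Per-position region labels of a single-hairpin structure.

    ``labels[p-1]`` is the region of 1-based position p, one of
    ``stem5`` / ``loop`` / ``stem3``. The loop is the unpaired interval
    enclosed by the innermost pair; everything 5' of it is the 5' arm and
    everything 3' of it the 3' arm (internal-loop and bulge nucleotides are
    labeled by their arm, not as loop).
    """

    labels: tuple[str, ...]
    loop_span: tuple[int, int]
    stem5_span: tuple[int, int]
    stem3_span: tuple[int, int]
    mature_span: Optional[tuple[int, int]] = None
    star_span: Optional[tuple[int, int]] = None
    anti_stem_side: Optional[str] = None

    def region_of(self, position: int) -> str:
        if not 1 <= position <= len(self.labels):
            raise ValueError(f"position {position} outside precursor 1..{len(self.labels)}")
        return self.labels[position - 1]


def annotate_regions(
    structure: SecondaryStructure | str,
    mature_span: Optional[tuple[int, int]] = None,
    star_span: Optional[tuple[int, int]] = None,
) -> HairpinAnnotation:
    """Partition a single-hairpin structure into 5' arm, loop and 3' arm.

    With a ``mature_span`` the arm opposite the mature is recorded as the
    anti-stem side. A mature straddling the loop is assigned the arm
    holding the majority of its positions.
    """
    if isinstance(structure, str):
        structure = parse_structure(structure)
    chain = _chain_of(structure)  # validates single-hairpin shape
    n = len(structure)
    pi, pj = chain[-1]  # innermost pair
    loop = (pi + 1, pj - 1)
    labels = tuple(
        "stem5" if p <= pi else ("loop" if p < pj else "stem3") for p in range(1, n + 1)
    )
    anti = None
    if mature_span is not None:
        ms, me = mature_span
        if not (1 <= ms <= me <= n):
            raise ValueError(f"mature span {mature_span} outside precursor 1..{n}")
        in5 = sum(1 for p in range(ms, me + 1) if labels[p - 1] == "stem5")
        in3 = sum(1 for p in range(ms, me + 1) if labels[p - 1] == "stem3")
        anti = "stem3" if in5 >= in3 else "stem5"
    return HairpinAnnotation(
        labels=labels,
        loop_span=loop,
        stem5_span=(1, pi),
        stem3_span=(pj, n),
        mature_span=mature_span,
        star_span=star_span,
        anti_stem_side=anti,
    )


# ---------------------------------------------------------------------------
# external engine adapter
# ---------------------------------------------------------------------------

FoldEngine = Callable[[str], tuple[str, float]]


def viennarna_engine(executable: str = "RNAfold") -> FoldEngine:
    """Adapter wrapping a local RNAfold binary as a fold engine.

    The returned callable maps sequence -> (dot_bracket, dG kcal/mol),
    matching the signature of the internal engine, so Turner-parameter
    energies can be plugged into any consumer (e.g. SNP ddG).
    """
    import re
    import subprocess

    def engine(sequence: str) -> tuple[str, float]:
        out = subprocess.run(
            [executable, "--noPS"],
            input=sequence + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout
        line = out.splitlines()[1]
        m = re.match(r"([().]+)\s+\(\s*(-?\d+\.?\d*)\)", line)
        if not m:
            raise RuntimeError(f"unexpected {executable} output: {line!r}")
        return m.group(1), float(m.group(2))

    return engine
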