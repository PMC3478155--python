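"""Post-discovery characterization.

Genomic clustering of precursors, phylogenetic grouping of conserved
families from a species presence/absence matrix, conserved-vs-specific
expression comparison (Mann–Whitney), relative expression by the
2^-ddCt method, miRNA–target correlation, and hierarchical clustering of
log2 expression matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import Annotation, GenomicLocation

DEFAULT_CLUSTER_GAP = 10_000

PROTOSTOMES = frozenset({"dme", "cel"})
FISH = frozenset({"dre", "fru", "tni", "cca", "pma", "ola"})
VERTEBRATES = FISH | frozenset({"hsa", "mmu", "gga", "xtr"})
DEUTEROSTOMES = VERTEBRATES | frozenset({"bfl", "cin", "spu"})


@dataclass(frozen=True)
class MiRNACluster:
    """Two or more precursors close together on one strand of one contig."""

    members: tuple[str, ...]
    reference_id: str
    strand: str
    span: GenomicLocation

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least two members")

    @property
    def length(self) -> int:
        return self.span.span


def find_clusters(
    annotations: Sequence[Annotation],
    max_gap: int = DEFAULT_CLUSTER_GAP,
) -> list[MiRNACluster]:
    """Single-linkage chaining of same-reference, same-strand precursors.

    Two precursors chain when the gap between them (nucleotides strictly
    between the intervals) is at most ``max_gap``; singletons are dropped.
    The cluster span runs from the smallest member start to the largest
    member end, 1-based inclusive.
    """
    groups: dict[tuple[str, str], list[Annotation]] = {}
    for a in annotations:
        groups.setdefault((a.location.reference_id, a.location.strand), []).append(a)
    clusters: list[MiRNACluster] = []
    for (ref, strand), anns in sorted(groups.items()):
        anns = sorted(anns, key=lambda a: (a.location.start, a.location.end))
        chain: list[Annotation] = []
        chain_end = None
        for a in anns + [None]:  # sentinel flushes the last chain
            if a is not None and (chain_end is None or a.location.start - chain_end - 1 <= max_gap):
                chain.append(a)
                chain_end = max(chain_end or 0, a.location.end)
                continue
            if len(chain) >= 2:
                start = min(c.location.start for c in chain)
                end = max(c.location.end for c in chain)
                clusters.append(
                    MiRNACluster(
                        members=tuple(c.feature_id for c in chain),
                        reference_id=ref,
                        strand=strand,
                        span=GenomicLocation(ref, start, end, strand),
                    )
                )
            if a is not None:
                chain = [a]
                chain_end = a.location.end
    return clusters


# ---------------------------------------------------------------------------
# phylogenetic grouping
# ---------------------------------------------------------------------------

def assign_phylo_group(
    presence: dict[str, bool] | pd.Series,
    protostomes: frozenset[str] = PROTOSTOMES,
    deuterostomes: frozenset[str] = DEUTEROSTOMES,
    vertebrates: frozenset[str] = VERTEBRATES,
    fish: frozenset[str] = FISH,
) -> str:
    """Group a family's species-presence row.

    ``shared``: present in at least one protostome and one deuterostome;
    ``fish-only``: present only in fish species; ``vertebrate-only``:
    present only in vertebrates but not exclusively fish.
    """
    if isinstance(presence, pd.Series):
        presence = {sp: bool(v) for sp, v in presence.items()}
    species = {sp for sp, present in presence.items() if present}
    if not species:
        raise ValueError("family absent from every species: group undefined")
    if species & protostomes and species & deuterostomes:
        return "shared"
    if species <= fish:
        return "fish-only"
    if species <= vertebrates:
        return "vertebrate-only"
    # deuterostome-but-not-vertebrate presence without protostomes: treat as
    # shared-deuterostome depth is not distinguished by the three-group scheme
    return "vertebrate-only"


def read_presence_matrix(path) -> pd.DataFrame:
    """TSV with family rows, species columns, entries +/- (or 1/0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.map(lambda v: str(v).strip() in ("+", "1", "present", "True"))


def group_families(matrix: pd.DataFrame) -> pd.Series:
    return pd.Series(
        {fam: assign_phylo_group(matrix.loc[fam]) for fam in matrix.index},
        name="group",
    )


# ---------------------------------------------------------------------------
# Mann–Whitney comparison
# ---------------------------------------------------------------------------

def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided exact Mann–Whitney by full enumeration of label
    arrangements; correct under ties. Returns (U of x, p)."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    center = n * m / 2.0
    dev = abs(u_obs - center)
    total = 0
    extreme = 0
    for idx in combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in set(idx)]
        u = _u_statistic(xs, ys)
        total += 1
        if abs(u - center) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def compare_expression(
    conserved: Sequence[float],
    specific: Sequence[float],
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U comparing two expression-count groups.

    Exact enumeration for combined n <= ``exact_max_n``; the
    tie-corrected normal approximation otherwise. Returns (U, p).
    """
    if len(conserved) == 0 or len(specific) == 0:
        raise ValueError("both groups must be non-empty")
    if len(conserved) + len(specific) <= exact_max_n:
        return mann_whitney_exact(conserved, specific)
    res = stats.mannwhitneyu(conserved, specific, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# 2^-ddCt relative expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfile:
    """Relative expression of one gene across samples by 2^-ddCt.

    ``relative`` is 2^-ddCt per sample (the calibrator is exactly 1);
    ``log2`` equals -ddCt exactly.
    """

    gene: str
    reference_gene: str
    calibrator: str
    samples: list[str]
    delta_ct: dict[str, float]
    delta_delta_ct: dict[str, float]
    relative: dict[str, float]

    @property
    def log2(self) -> dict[str, float]:
        return {s: -ddct for s, ddct in self.delta_delta_ct.items()}


def ddct_expression(
    ct_table: pd.DataFrame,
    gene: str,
    reference_gene: str,
    calibrator: str,
) -> ExpressionProfile:
    """Relative expression from a Ct table (rows = genes, columns = samples).

    dCt = Ct_gene - Ct_reference per sample; ddCt = dCt_sample -
    dCt_calibrator; relative = 2^-ddCt.
    """
    for g in (gene, reference_gene):
        if g not in ct_table.index:
            raise KeyError(f"gene {g!r} missing from Ct table")
    if calibrator not in ct_table.columns:
        raise KeyError(f"calibrator sample {calibrator!r} missing from Ct table")
    for g in (gene, reference_gene):
        missing = [s for s in ct_table.columns if pd.isna(ct_table.loc[g, s])]
        if missing:
            raise ValueError(f"missing Ct for {g!r} in sample(s) {missing}")
    samples = list(ct_table.columns)
    dct = {s: float(ct_table.loc[gene, s] - ct_table.loc[reference_gene, s]) for s in samples}
    ddct = {s: dct[s] - dct[calibrator] for s in samples}
    rel = {s: 2.0 ** (-ddct[s]) for s in samples}
    return ExpressionProfile(
        gene=gene,
        reference_gene=reference_gene,
        calibrator=calibrator,
        samples=samples,
        delta_ct=dct,
        delta_delta_ct=ddct,
        relative=rel,
    )


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# miRNA–target correlation
# ---------------------------------------------------------------------------

def mirna_target_correlation(
    mirna_log2: Sequence[float],
    target_log2: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Pearson r and two-sided p on two log2 expression series.

    Returns (r, p, reciprocal) where ``reciprocal`` flags a significant
    negative correlation (r < 0 and p <= alpha), the expected signature of
    a miRNA repressing its target.
    """
    x = np.asarray(mirna_log2, dtype=float)
    y = np.asarray(target_log2, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("profiles must be equal-length with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), bool(r < 0 and p <= alpha)


# ---------------------------------------------------------------------------
# hierarchical clustering of expression matrices
# ---------------------------------------------------------------------------

def hierarchical_cluster(
    matrix: pd.DataFrame,
    n_groups: int = 2,
) -> tuple[list[str], np.ndarray, dict[str, int]]:
    """Agglomerative clustering (Euclidean distance, complete linkage).

    Returns (leaf order, linkage matrix, row -> flat group id). Leaf order
    is deterministic; ties resolve by row index. A single row yields a
    trivial tree.
    """
    if matrix.isna().any().any():
        bad = matrix.index[matrix.isna().any(axis=1)].tolist()
        raise ValueError(f"rows with missing values: {bad}")
    rows = list(matrix.index)
    if len(rows) == 1:
        return rows, np.zeros((0, 4)), {rows[0]: 1}
    dist = pdist(matrix.to_numpy(dtype=float), metric="euclidean")
    link = hierarchy.linkage(dist, method="complete")
    order = [rows[i] for i in hierarchy.leaves_list(link)]
    flat = hierarchy.fcluster(link, t=min(n_groups, len(rows)), criterion="maxclust")
    return order, link, {rows[i]: int(flat[i]) for i in range(len(rows))}
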