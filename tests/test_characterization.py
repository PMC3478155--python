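import itertools
import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirkit.characterization import (
    assign_phylo_group,
    compare_expression,
    ddct_expression,
    find_clusters,
    group_families,
    hierarchical_cluster,
    mann_whitney_exact,
    mirna_target_correlation,
)
from mirkit.io import Annotation, GenomicLocation

# the five published cluster layouts: (reference, strand, cluster span)
PRINTED_CLUSTERS = [
    ("CYC023A01I23/2", "-", 200, 591, 392),
    ("CYC084B02N10/1", "-", 362, 723, 362),
    ("utg7180000000224", "+", 174, 688, 515),
    ("utg7180000000234", "+", 306, 1206, 901),
    ("utg7180000001602", "-", 502, 775, 274),
]


def _members(ref, strand, start, end, n=2):
    """Subdivide a cluster span into n members with 9-nt gaps."""
    bounds = np.linspace(start, end, n + 1).astype(int)
    anns = []
    for i in range(n):
        s = bounds[i] if i == 0 else bounds[i] + 5
        e = bounds[i + 1] if i == n - 1 else bounds[i + 1] - 5
        anns.append(
            Annotation(f"{ref}-m{i}", "pre_miRNA", GenomicLocation(ref, int(s), int(e), strand))
        )
    return anns


class TestClusters:
    def test_printed_cluster_lengths_reproduced(self):
        anns = []
        for ref, strand, start, end, _length in PRINTED_CLUSTERS:
            anns.extend(_members(ref, strand, start, end))
        clusters = find_clusters(anns, max_gap=10_000)
        assert sorted(c.length for c in clusters) == [274, 362, 392, 515, 901]

    def test_two_members_gap_nine(self):
        anns = [
            Annotation("miR-212", "pre_miRNA", GenomicLocation("c", 200, 420, "-")),
            Annotation("mir-132", "pre_miRNA", GenomicLocation("c", 430, 591, "-")),
        ]
        (cluster,) = find_clusters(anns, max_gap=10)
        assert cluster.length == 392 and cluster.members == ("miR-212", "mir-132")

    def test_opposite_strands_never_cluster(self):
        anns = [
            Annotation("a", "pre_miRNA", GenomicLocation("c", 200, 420, "+")),
            Annotation("b", "pre_miRNA", GenomicLocation("c", 430, 591, "-")),
        ]
        assert find_clusters(anns, max_gap=10_000) == []

    def test_three_members_chain_matches_exhaustive_grouping(self):
        rng = random.Random(11)
        for _ in range(30):
            starts = sorted(rng.sample(range(1, 2000), 5))
            anns = [
                Annotation(f"p{i}", "pre_miRNA", GenomicLocation("c", s, s + 60, "+"))
                for i, s in enumerate(starts)
            ]
            max_gap = rng.choice([10, 50, 200])
            clusters = find_clusters(anns, max_gap=max_gap)
            # exhaustive single-linkage oracle: iterate merging until fixpoint
            groups = [{a.feature_id: a} for a in anns]
            changed = True
            while changed:
                changed = False
                for i, j in itertools.combinations(range(len(groups)), 2):
                    if any(
                        0 <= b.location.start - a.location.end - 1 <= max_gap
                        or 0 <= a.location.start - b.location.end - 1 <= max_gap
                        or not (a.location.end < b.location.start or b.location.end < a.location.start)
                        for a in groups[i].values()
                        for b in groups[j].values()
                    ):
                        groups[i].update(groups[j])
                        del groups[j]
                        changed = True
                        break
            expected = sorted(
                tuple(sorted(g)) for g in groups if len(g) >= 2
            )
            assert sorted(tuple(sorted(c.members)) for c in clusters) == expected

    def test_singletons_excluded(self):
        anns = [Annotation("a", "pre_miRNA", GenomicLocation("c", 1, 60, "+"))]
        assert find_clusters(anns) == []


class TestPhyloGroups:
    def test_shared_between_protostomes_and_deuterostomes(self):
        assert assign_phylo_group({"dme": 1, "cel": 1, "hsa": 1, "dre": 1}) == "shared"

    def test_fish_only(self):
        assert assign_phylo_group({"dre": 1, "fru": 1, "cca": 1}) == "fish-only"

    def test_vertebrate_only(self):
        assert assign_phylo_group({"hsa": 1, "dre": 1}) == "vertebrate-only"

    def test_all_absent_is_undefined(self):
        with pytest.raises(ValueError):
            assign_phylo_group({"hsa": 0, "dre": 0})

    def test_partition_property_every_family_gets_one_group(self):
        rng = random.Random(2)
        species = ["hsa", "mmu", "gga", "xtr", "dre", "fru", "tni", "cca", "dme", "cel", "spu"]
        rows = {}
        for f in range(40):
            row = {sp: rng.random() < 0.4 for sp in species}
            if not any(row.values()):
                row["dre"] = True
            rows[f"fam{f}"] = row
        matrix = pd.DataFrame(rows).T
        groups = group_families(matrix)
        assert set(groups) <= {"shared", "vertebrate-only", "fish-only"}
        assert len(groups) == 40


class TestMannWhitney:
    def test_separated_triples_exact_p(self):
        u, p = compare_expression([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_complete_ties_p_one(self):
        _u, p = compare_expression([5, 5], [5, 5])
        assert p == 1.0

    def test_exact_matches_scipy_enumeration_small_n(self):
        rng = random.Random(8)
        for _ in range(25):
            n, m = rng.randint(2, 5), rng.randint(2, 5)
            x = rng.sample(range(1000), n)
            y = rng.sample(range(1000, 2000), m) if rng.random() < 0.3 else rng.sample(range(500, 1500), m)
            _u, p = mann_whitney_exact(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(float(ref), abs=1e-12)

    def test_approximation_close_to_exact_at_ten_per_group(self):
        rng = random.Random(9)
        x = [rng.random() for _ in range(10)]
        y = [rng.random() * 1.4 for _ in range(10)]
        _u, p_exact = mann_whitney_exact(x, y)
        _u, p_approx = compare_expression(x, y, exact_max_n=0)
        assert abs(p_exact - p_approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_expression([], [1.0])


class TestDdct:
    def _table(self):
        return pd.DataFrame(
            {"t0": [20.0, 15.0], "t1": [19.0, 15.0], "t2": [22.0, 15.0]},
            index=["mir", "U6"],
        )

    def test_calibrator_relative_is_exactly_one(self):
        prof = ddct_expression(self._table(), "mir", "U6", "t0")
        assert prof.relative["t0"] == 1.0

    @pytest.mark.parametrize("sample,expect", [("t1", 2.0), ("t2", 0.25)])
    def test_closed_form_doubling(self, sample, expect):
        prof = ddct_expression(self._table(), "mir", "U6", "t0")
        assert prof.relative[sample] == pytest.approx(expect)

    def test_log2_equals_negative_ddct(self):
        prof = ddct_expression(self._table(), "mir", "U6", "t0")
        for s in prof.samples:
            assert prof.log2[s] == -prof.delta_delta_ct[s]

    def test_missing_ct_names_sample(self):
        tab = self._table()
        tab.loc["mir", "t1"] = float("nan")
        with pytest.raises(ValueError, match="t1"):
            ddct_expression(tab, "mir", "U6", "t0")


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        r, p, reciprocal = mirna_target_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r == pytest.approx(-1.0) and reciprocal

    def test_self_correlation(self):
        r, _p, reciprocal = mirna_target_correlation([1, 2, 3, 5], [1, 2, 3, 5])
        assert r == pytest.approx(1.0) and not reciprocal

    def test_matches_direct_covariance_formula(self):
        rng = random.Random(4)
        x = [rng.random() for _ in range(5)]
        y = [rng.random() for _ in range(5)]
        r, _p, _ = mirna_target_correlation(x, y)
        xa, ya = np.array(x), np.array(y)
        manual = float(
            np.sum((xa - xa.mean()) * (ya - ya.mean()))
            / np.sqrt(np.sum((xa - xa.mean()) ** 2) * np.sum((ya - ya.mean()) ** 2))
        )
        assert r == pytest.approx(manual)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mirna_target_correlation([1, 1, 1], [1, 2, 3])


class TestHierarchicalClustering:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"])
        _order, link, _groups = hierarchical_cluster(df)
        assert link[0, 2] == 0.0  # first merge distance

    def test_recovers_planted_two_group_partition(self):
        rng = np.random.default_rng(12)
        hi = rng.normal(5.0, 0.1, size=(4, 6))
        lo = rng.normal(0.0, 0.1, size=(4, 6))
        df = pd.DataFrame(
            np.vstack([hi, lo]), index=[f"h{i}" for i in range(4)] + [f"l{i}" for i in range(4)]
        )
        _order, _link, groups = hierarchical_cluster(df, n_groups=2)
        assert len({groups[f"h{i}"] for i in range(4)}) == 1
        assert len({groups[f"l{i}"] for i in range(4)}) == 1
        assert groups["h0"] != groups["l0"]

    def test_single_row_trivial_tree(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["only"])
        order, link, groups = hierarchical_cluster(df)
        assert order == ["only"] and link.shape == (0, 4) and groups == {"only": 1}

    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0, np.nan]], index=["a"])
        with pytest.raises(ValueError):
            hierarchical_cluster(df)
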