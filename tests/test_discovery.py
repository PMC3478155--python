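import random

import pytest

from conftest import random_rna
from mirkit.discovery import (
    CleanedRead,
    align_mirna,
    annotate_contaminants,
    calibrate_identity_threshold,
    catalog_summary,
    check_hairpin_criteria,
    clean_reads,
    dedup_matures,
    detect_isomiRs,
    detect_moRNAs,
    discover_from_homology,
    discover_from_reads,
    extract_candidate,
    merge_catalogs,
)
from mirkit.fold import parse_structure
from mirkit.io import SequenceRecord, reverse_complement
from mirkit.simulate import (
    GeneratorConfig,
    make_decoy_references,
    make_hairpin,
    make_reference_with_mirnas,
    mutate_homolog,
    simulate_sreads,
)

ADAPTER3 = "UCGUAUGCCGUCUUCUGCUUG"


def _records(seqs):
    return [SequenceRecord(id=f"s{i}", sequence=s) for i, s in enumerate(seqs)]


class TestDedup:
    def test_exact_dedup_keeps_first_name(self):
        recs = [
            SequenceRecord(id="a", sequence="UGAGGUAGUAGGUUGUAUAGUU"),
            SequenceRecord(id="b", sequence="UGAGGUAGUAGGUUGUAUAGUU"),
            SequenceRecord(id="c", sequence="UGAGGUAGUAGGUUGUAUAGUC"),
        ]
        unique, aliases = dedup_matures(recs)
        assert [r.id for r in unique] == ["a", "c"]
        assert aliases["a"] == ["b"]

    def test_empty_input(self):
        assert dedup_matures([]) == ([], {})

    def test_planted_duplicate_count(self, rng):
        base = [random_rna(rng, 22) for _ in range(60)]
        dups = [rng.choice(base) for _ in range(40)]
        recs = _records(base + dups)
        unique, _ = dedup_matures(recs)
        assert len(unique) == 60


class TestAlign:
    def test_exact_hit_identity_one(self, rng, let7):
        bg = random_rna(rng, 200)
        ref = SequenceRecord(id="c", sequence=bg[:100] + let7.sequence + bg[100:])
        hits = align_mirna(let7, [ref])
        assert hits and hits[0].identity == 1.0
        assert (hits[0].start, hits[0].end) == (101, 122)

    def test_two_mismatches_retained_three_excluded(self, rng, let7):
        # 20/22 = 0.909 passes the 0.90 threshold; 19/22 = 0.864 does not
        for n_mm, expect in ((2, True), (3, False)):
            variant, _ = mutate_homolog(let7.sequence, 1 - n_mm / 22, seed=5)
            ref = SequenceRecord(id="c", sequence=random_rna(rng, 80) + variant + random_rna(rng, 80))
            hits = align_mirna(let7, [ref])
            assert bool(hits) is expect

    def test_minus_strand_hit_reported(self, rng, let7):
        ref = SequenceRecord(
            id="c",
            sequence=random_rna(rng, 50) + reverse_complement(let7.sequence) + random_rna(rng, 50),
        )
        hits = align_mirna(let7, [ref])
        assert hits[0].strand == "-" and (hits[0].start, hits[0].end) == (51, 72)

    def test_short_query_refused(self):
        with pytest.raises(ValueError):
            align_mirna("ACGUACGUACGU", [SequenceRecord(id="c", sequence="ACGU" * 30)])


class TestExtractCandidate:
    def _hit(self, start, end, strand="+"):
        from mirkit.discovery import HomologyHit

        return HomologyHit("q", "c", start, end, strand, 1.0)

    def test_interior_hit_gets_both_flanks(self, rng):
        ref = SequenceRecord(id="c", sequence=random_rna(rng, 1000))
        cand = extract_candidate(ref, self._hit(100, 121), flank=60)
        assert (cand.location.start, cand.location.end) == (40, 181)
        assert len(cand.sequence) == 142
        assert cand.mature_span == (61, 82)

    def test_left_truncation(self, rng):
        ref = SequenceRecord(id="c", sequence=random_rna(rng, 1000))
        cand = extract_candidate(ref, self._hit(10, 31), flank=60)
        assert (cand.location.start, cand.location.end) == (1, 91)

    def test_minus_strand_round_trip(self, rng):
        ref = SequenceRecord(id="c", sequence=random_rna(rng, 400))
        cand = extract_candidate(ref, self._hit(150, 171, "-"), flank=60)
        ms, me = cand.mature_span
        excised_mature = cand.sequence[ms - 1 : me]
        assert excised_mature == reverse_complement(ref.sequence[149:171])


class TestSixCriteria:
    def _clean(self, stem=20, loop=5, seed=0):
        seq, db, span = make_hairpin(stem, loop, seed=seed)
        return seq, parse_structure(db), span

    def test_dg_boundary_minus_15(self):
        seq, structure, span = self._clean()
        assert check_hairpin_criteria(seq, span, structure, -15.0).dg_ok
        assert not check_hairpin_criteria(seq, span, structure, -14.99).dg_ok

    @pytest.mark.parametrize("loop,ok", [(21, True), (22, False)])
    def test_loop_boundary_22(self, loop, ok):
        seq, structure, span = self._clean(stem=20, loop=loop)
        assert check_hairpin_criteria(seq, span, structure, -30.0).loop_ok is ok

    @pytest.mark.parametrize("extra,ok", [(0, False), (1, True)])
    def test_length_boundary_53(self, extra, ok):
        # stem 24 + loop 5 = 53 nt exactly; one more loop base passes
        seq, structure, span = self._clean(stem=24, loop=5 + extra)
        assert len(seq) == 53 + extra
        assert check_hairpin_criteria(seq, span, structure, -30.0).length_ok is ok

    @pytest.mark.parametrize("gap,ok", [(18, True), (19, False)])
    def test_bulge_boundary_18(self, gap, ok):
        db = "(" * 5 + "." * gap + "(" * 5 + "...." + ")" * 5 + ")" * 5
        seq = "A" * len(db)
        report = check_hairpin_criteria(seq, (1, 5), parse_structure(db), -30.0)
        assert report.max_bulge == gap and report.bulge_ok is ok

    def test_stem_coverage_boundary_80(self):
        # mature of 20 nt: 16 paired (0.80) passes, 15 (0.75) fails
        for unpaired, ok in ((4, True), (5, False)):
            paired = 20 - unpaired
            db = "(" * paired + "." * unpaired + "...." + "." * unpaired + ")" * paired
            report = check_hairpin_criteria(
                "A" * len(db), (1, 20), parse_structure(db), -30.0
            )
            assert report.stem_coverage == pytest.approx(paired / 20)
            assert report.stem_coverage_ok is ok

    @pytest.mark.parametrize("unpaired,ok", [(6, True), (7, False)])
    def test_mismatch_boundary_6(self, unpaired, ok):
        paired = 18
        db = "(" * paired + "." * unpaired + "...." + "." * unpaired + ")" * paired
        span = (1, paired + unpaired)
        report = check_hairpin_criteria("A" * len(db), span, parse_structure(db), -30.0)
        assert report.mismatches == unpaired and report.mismatch_ok is ok

    def test_overall_is_conjunction(self):
        seq, structure, span = self._clean(stem=30, loop=6)
        good = check_hairpin_criteria(seq, span, structure, -30.0)
        assert good.overall
        bad = check_hairpin_criteria(seq, span, structure, -3.0)
        assert not bad.overall and not bad.dg_ok


class TestCleanReads:
    def _read(self, seq, q=40):
        self._n = getattr(self, "_n", 0) + 1
        return SequenceRecord(id=f"r{self._n}", sequence=seq, quality=[q] * len(seq))

    def test_generator_known_composition(self, rng):
        insert = random_rna(rng, 22)
        reads = (
            [self._read(insert + ADAPTER3[:14]) for _ in range(650)]
            + [self._read(ADAPTER3 + random_rna(rng, 10)) for _ in range(200)]  # adapter at 5' end
            + [self._read("A" * 30) for _ in range(100)]
            + [self._read(random_rna(rng, 12) + ADAPTER3[:18]) for _ in range(50)]
        )
        cleaned, acc = clean_reads(reads, ADAPTER3)
        assert acc.raw_count == 1000
        assert acc.cleaned_count == 650
        assert sum(r.count for r in cleaned) == 650

    def test_seventeen_nt_insert_discarded(self, rng):
        short = self._read(random_rna(rng, 17) + ADAPTER3)
        keep = self._read(random_rna(rng, 18) + ADAPTER3)
        cleaned, acc = clean_reads([short, keep], ADAPTER3)
        assert acc.cleaned_count == 1 and len(cleaned[0].sequence) == 18

    def test_low_quality_discarded(self, rng):
        bad = self._read(random_rna(rng, 22) + ADAPTER3, q=10)
        cleaned, acc = clean_reads([bad], ADAPTER3)
        assert acc.cleaned_count == 0

    def test_trimming_tolerates_one_mismatch_per_ten(self, rng):
        insert = random_rna(rng, 22)
        adapter14 = ADAPTER3[:14]
        mutated = "G" if adapter14[4] != "G" else "C"
        read = self._read(insert + adapter14[:4] + mutated + adapter14[5:])
        cleaned, acc = clean_reads([read], ADAPTER3)
        assert acc.cleaned_count == 1 and cleaned[0].sequence == insert

    def test_collapse_counts(self, rng):
        insert = random_rna(rng, 22)
        reads = [self._read(insert + ADAPTER3) for _ in range(5)]
        cleaned, _ = clean_reads(reads, ADAPTER3)
        assert len(cleaned) == 1 and cleaned[0].count == 5


class TestContaminants:
    def test_priority_rrna_over_repeat(self, rng):
        shared = random_rna(rng, 22)
        sets = {
            "rRNA": [SequenceRecord(id="rr", sequence=random_rna(rng, 30) + shared)],
            "repeat": [SequenceRecord(id="rep", sequence=shared + random_rna(rng, 30))],
        }
        reads = [CleanedRead(sequence=shared, count=3)]
        out, acc = annotate_contaminants(reads, sets)
        assert out[0].annotation_class == "rRNA"
        assert acc.contaminant_counts == {"rRNA": 3, "repeat": 0}

    def test_one_mismatch_still_annotated_two_not(self, rng):
        ref = random_rna(rng, 60)
        read0 = ref[10:32]
        read1 = read0[:5] + ("A" if read0[5] != "A" else "C") + read0[6:]
        read2 = read1[:15] + ("A" if read1[15] != "A" else "C") + read1[16:]
        sets = {"tRNA": [SequenceRecord(id="t", sequence=ref)]}
        out, _ = annotate_contaminants(
            [CleanedRead(s, 1) for s in (read0, read1, read2)], sets
        )
        assert [r.annotation_class for r in out] == ["tRNA", "tRNA", "unannotated"]

    def test_accounting_identity_holds(self, rng):
        reads = [CleanedRead(random_rna(rng, 20), c) for c in (4, 2, 1)]
        out, acc = annotate_contaminants(reads, {"rRNA": []})
        assert acc.remaining_count == acc.cleaned_count - sum(acc.contaminant_counts.values())
        assert acc.remaining_count == 7


class TestDiscoverFromReads:
    def _setup(self, seed=3, n=6):
        cfg = GeneratorConfig(seed=seed, n_precursors=n, depth_range=(5, 15))
        contigs, truth = make_reference_with_mirnas(cfg)
        reads, _ = simulate_sreads(truth.precursors, cfg)
        cleaned, _ = clean_reads(reads, cfg.adapter_3p, cfg.adapter_5p)
        return cfg, contigs, truth, cleaned

    def test_planted_precursors_recovered_with_correct_matures(self):
        cfg, contigs, truth, cleaned = self._setup()
        catalog = discover_from_reads(cleaned, contigs)
        found = {e.mature.sequence for e in catalog}
        for t in truth.precursors.values():
            assert t["mature_sequence"] in found

    def test_single_read_locus_rejected_at_threshold_two(self, rng):
        seq, _db, span = make_hairpin(28, 6, seed=9)
        contig = SequenceRecord(
            id="c", sequence=random_rna(rng, 150) + seq + random_rna(rng, 150)
        )
        mature = seq[span[0] - 1 : span[1]]
        one = [CleanedRead(mature, 1)]
        two = [CleanedRead(mature, 2)]
        assert discover_from_reads(one, [contig], min_locus_reads=2) == []
        assert len(discover_from_reads(two, [contig], min_locus_reads=2)) >= 1

    def test_read_straddling_loop_rejected(self, rng):
        seq, db, _span = make_hairpin(28, 6, seed=10)
        contig = SequenceRecord(
            id="c", sequence=random_rna(rng, 150) + seq + random_rna(rng, 150)
        )
        straddler = seq[18:40]  # covers stem/loop junction
        catalog = discover_from_reads([CleanedRead(straddler, 5)], [contig])
        assert catalog == []

    def test_decoy_loci_yield_no_candidates(self, rng):
        cfg = GeneratorConfig(seed=21)
        decoy_contigs, decoy_matures = make_decoy_references(cfg, n_decoys=8)
        reads = [CleanedRead(m.sequence, 5) for m in decoy_matures]
        assert discover_from_reads(reads, decoy_contigs) == []


class TestHomologyArm:
    def test_high_identity_homologs_recovered_low_never(self):
        cfg = GeneratorConfig(seed=13, n_precursors=6)
        contigs, truth = make_reference_with_mirnas(cfg)
        for ident, expect_all in ((0.95, True), (0.80, False)):
            known = [
                SequenceRecord(
                    id=f"k-{pid}",
                    sequence=mutate_homolog(t["mature_sequence"], ident, seed=4)[0],
                )
                for pid, t in truth.precursors.items()
            ]
            catalog = discover_from_homology(known, contigs)
            recovered = {e.mature.sequence for e in catalog}
            hits = sum(
                1 for t in truth.precursors.values() if t["mature_sequence"] in recovered
            )
            if expect_all:
                assert hits == len(truth.precursors)
            else:
                assert hits == 0

    def test_mature_is_substring_of_precursor_at_offset(self):
        cfg = GeneratorConfig(seed=13, n_precursors=6)
        contigs, truth = make_reference_with_mirnas(cfg)
        known = [
            SequenceRecord(id=f"k-{p}", sequence=t["mature_sequence"])
            for p, t in truth.precursors.items()
        ]
        for entry in discover_from_homology(known, contigs):
            ms, me = entry.precursor.mature_span
            assert entry.precursor.sequence[ms - 1 : me] == entry.mature.sequence


class TestMergeCatalogs:
    def test_disjoint_sets_sum(self):
        cfg = GeneratorConfig(seed=3, n_precursors=6, depth_range=(5, 15))
        contigs, truth = make_reference_with_mirnas(cfg)
        known = [
            SequenceRecord(id=f"k-{p}", sequence=t["mature_sequence"])
            for p, t in truth.precursors.items()
        ]
        hom = discover_from_homology(known[:3], contigs)
        reads, _ = simulate_sreads(
            {p: truth.precursors[p] for p in sorted(truth.precursors)[3:]}, cfg
        )
        cleaned, _ = clean_reads(reads, cfg.adapter_3p, cfg.adapter_5p)
        seq_cat = discover_from_reads(cleaned, contigs)
        merged = merge_catalogs(hom, seq_cat)
        mature_seqs = {e.mature.sequence for e in merged}
        assert len(mature_seqs) == len(merged) == 6
        summary = catalog_summary(merged)
        assert summary["conserved"] == 3 and summary["specific"] == 3

    def test_same_mirna_found_by_both_arms_single_entry(self):
        cfg = GeneratorConfig(seed=3, n_precursors=4, depth_range=(10, 20))
        contigs, truth = make_reference_with_mirnas(cfg)
        known = [
            SequenceRecord(id=f"k-{p}", sequence=t["mature_sequence"])
            for p, t in truth.precursors.items()
        ]
        hom = discover_from_homology(known, contigs)
        reads, _ = simulate_sreads(truth.precursors, cfg)
        cleaned, _ = clean_reads(reads, cfg.adapter_3p, cfg.adapter_5p)
        seq_cat = discover_from_reads(cleaned, contigs)
        merged = merge_catalogs(hom, seq_cat)
        assert len(merged) == 4
        assert all(e.provenance == "both" for e in merged)

    def test_empty_sequencing_set_is_identity(self):
        cfg = GeneratorConfig(seed=13, n_precursors=4)
        contigs, truth = make_reference_with_mirnas(cfg)
        known = [
            SequenceRecord(id=f"k-{p}", sequence=t["mature_sequence"])
            for p, t in truth.precursors.items()
        ]
        hom = discover_from_homology(known, contigs)
        merged = merge_catalogs(hom, [])
        assert {e.mature.sequence for e in merged} == {e.mature.sequence for e in hom}


class TestIsomiRsAndMoRNAs:
    def _entry(self, seed=17):
        cfg = GeneratorConfig(seed=seed, n_precursors=1)
        contigs, truth = make_reference_with_mirnas(cfg)
        known = [
            SequenceRecord(id="k", sequence=next(iter(truth.precursors.values()))["mature_sequence"])
        ]
        return merge_catalogs(discover_from_homology(known, contigs), [])[0]

    def test_templated_end_variants_detected_exactly(self):
        entry = self._entry()
        pre = entry.precursor
        ms, me = pre.mature_span
        mature = pre.sequence[ms - 1 : me]
        variants = [
            pre.sequence[ms - 1 : me + 1],  # +1 nt 3'
            pre.sequence[ms - 2 : me],  # +1 nt 5'
            pre.sequence[ms - 1 : me - 2],  # -2 nt 3'
        ]
        reads = [CleanedRead(v, 1) for v in variants if len(v) >= 18]
        reads.append(CleanedRead(mature, 10))  # reference-identical: excluded
        iso = detect_isomiRs(reads, [entry])
        assert len(iso[entry.mature.name]) == len(reads) - 1

    def test_morna_adjacency_rules(self):
        entry = self._entry(seed=23)
        pre = entry.precursor
        ms, me = pre.mature_span
        n = len(pre.sequence)
        picks = []
        # immediately 3' of the mature span (gap 0)
        if me + 18 <= n:
            picks.append((pre.sequence[me : me + 18], True))
        # overlapping the mature by 1 nt: isomiR territory, not moRNA
        picks.append((pre.sequence[me - 1 : me + 17], False))
        # far from both arms (if the precursor is long enough)
        if me + 5 + 18 <= n:
            picks.append((pre.sequence[me + 4 : me + 4 + 18], False))
        for seq, expect in picks:
            got = detect_moRNAs([CleanedRead(seq, 1)], pre)
            assert bool(got) is expect, (seq, expect)


class TestCalibration:
    def test_identical_family_identity_one(self):
        fams = {"let-7": ["UGAGGUAGUAGGUUGUAUAGUU"] * 3}
        assert calibrate_identity_threshold(fams) == 1.0

    def test_planted_identity_floor_recovered(self):
        rng = random.Random(5)
        fams = {}
        for f in range(4):
            base = random_rna(rng, 20)
            variant, realized = mutate_homolog(base, 0.9, seed=f)
            fams[f"fam{f}"] = [base, variant]
        floor = calibrate_identity_threshold(fams)
        assert floor == pytest.approx(0.9, abs=0.05)

    def test_singletons_error(self):
        with pytest.raises(ValueError):
            calibrate_identity_threshold({"a": ["ACGUACGUACGUACGUACGU"]})
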