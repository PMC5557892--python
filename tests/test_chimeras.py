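"""Chimera calling: miRNA detection tolerance, segment extraction,
mapping/dedup rules, interaction clusters, profiling, novel arms."""

import numpy as np
import pytest

from chimeramap.annotation import AnnotationIndex
from chimeramap.catalog import MiRNA, MiRNACatalog
from chimeramap.chimeras import (
    GenomeMapper,
    Read,
    build_interaction_clusters,
    detect_novel_arm_candidates,
    extract_target_segments,
    find_mirna_in_read,
    map_and_dedup,
    profile_ago_mirnas,
)
from chimeramap.intervals import GenomicInterval
from chimeramap.simulate import Hairpin
from conftest import MIR17, MIR224


def _read(seq, rid="r1", bc="ACGTA", rep="rep1"):
    return Read(rid, seq, bc, rep)


def _rand(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


RNG = np.random.default_rng(42)
TAIL25 = _rand(RNG, 25)


class TestFindMirnaInRead:
    def test_exact_match_found(self, small_catalog):
        hits = find_mirna_in_read(_read(MIR224 + TAIL25), small_catalog)
        assert [h.mirna_name for h in hits] == ["bta-miR-224-3p"]
        assert hits[0].read_offset == 0 and hits[0].total_mismatches == 0

    def test_one_mismatch_at_position_10_tolerated(self, small_catalog):
        mutated = MIR224[:9] + ("A" if MIR224[9] != "A" else "C") + MIR224[10:]
        hits = find_mirna_in_read(_read(mutated + TAIL25), small_catalog)
        assert [h.mirna_name for h in hits] == ["bta-miR-224-3p"]
        assert hits[0].mismatches_first18 == 1

    def test_two_mismatches_in_first_18_rejected(self, small_catalog):
        s = list(MIR224)
        for pos in (4, 8):  # positions 5 and 9
            s[pos] = "A" if s[pos] != "A" else "C"
        hits = find_mirna_in_read(_read("".join(s) + TAIL25), small_catalog)
        assert hits == []

    def test_two_mismatches_split_across_18_boundary_tolerated(self, small_catalog):
        s = list(MIR17)  # 24 nt: second mismatch beyond the first 18
        s[4] = "A" if s[4] != "A" else "C"
        s[20] = "A" if s[20] != "A" else "C"
        hits = find_mirna_in_read(_read("".join(s) + TAIL25), small_catalog)
        assert [h.mirna_name for h in hits] == ["bta-miR-17-5p"]
        assert hits[0].total_mismatches == 2 and hits[0].mismatches_first18 == 1

    def test_truncated_variants_detected(self, small_catalog):
        for trunc, s in (("5p-1nt", MIR224[1:]), ("3p-1nt", MIR224[:-1])):
            hits = find_mirna_in_read(_read(s + TAIL25), small_catalog)
            assert hits and hits[0].truncation == trunc

    def test_first_alphanumeric_wins_within_4nt(self):
        # same 18-nt prefix makes 15a and 15b match at the same offset
        shared = "TAGCAGCACATAATGGTT"
        catalog = MiRNACatalog(
            [MiRNA("bta-miR-15b", shared + "TACA"), MiRNA("bta-miR-15a", shared + "TGTG")]
        )
        hits = find_mirna_in_read(_read(shared + "TGTG" + TAIL25), catalog)
        assert [h.mirna_name for h in hits] == ["bta-miR-15a"]

    def test_distant_loci_coexist(self, small_catalog):
        gap = TAIL25[:6]
        read = _read(MIR224 + gap + MIR17 + TAIL25)
        hits = find_mirna_in_read(read, small_catalog)
        assert {h.mirna_name for h in hits} == {"bta-miR-224-3p", "bta-miR-17-5p"}

    def test_no_match_returns_empty(self, small_catalog):
        assert find_mirna_in_read(_read(_rand(RNG, 50)), small_catalog) == []


class TestExtractTargetSegments:
    def test_downstream_is_mirfirst(self, small_catalog):
        read = _read(MIR224 + TAIL25)
        hit = find_mirna_in_read(read, small_catalog)[0]
        segs = extract_target_segments(read, hit)
        assert [(s.chimera_type, s.sequence) for s in segs] == [("miRfirst", TAIL25)]

    def test_18nt_segment_dropped(self, small_catalog):
        read = _read(MIR224 + TAIL25[:18])
        hit = find_mirna_in_read(read, small_catalog)[0]
        assert extract_target_segments(read, hit) == []

    def test_both_sides_emitted(self, small_catalog):
        up, down = TAIL25[:20], _rand(RNG, 30)
        read = _read(up + MIR224 + down)
        hit = find_mirna_in_read(read, small_catalog)[0]
        segs = extract_target_segments(read, hit)
        assert {(s.chimera_type, s.sequence) for s in segs} == {
            ("miRlast", up),
            ("miRfirst", down),
        }


@pytest.fixture(scope="module")
def toy_mapper():
    rng = np.random.default_rng(7)
    chrom = _rand(rng, 5000)
    return GenomeMapper({"chr1": chrom}), chrom


class TestGenomeMapper:
    def test_unique_exact_hit(self, toy_mapper):
        mapper, chrom = toy_mapper
        iv, mm, status = mapper.map_segment(chrom[1000:1025])
        assert status == "unique" and (iv.start, iv.end, iv.strand) == (1000, 1025, "+")

    def test_minus_strand_hit(self, toy_mapper):
        from chimeramap import seq

        mapper, chrom = toy_mapper
        iv, mm, status = mapper.map_segment(seq.revcomp(chrom[2000:2024]))
        assert status == "unique" and iv.strand == "-" and iv.start == 2000

    def test_two_mismatches_recovered(self, toy_mapper):
        mapper, chrom = toy_mapper
        s = list(chrom[3000:3030])
        s[5] = "A" if s[5] != "A" else "C"
        s[25] = "A" if s[25] != "A" else "C"
        iv, mm, status = mapper.map_segment("".join(s))
        assert status == "unique" and mm == 2 and iv.start == 3000

    def test_multimapper_dropped(self):
        seg = "ACGTACGTACGTACGTACGTACG"
        mapper = GenomeMapper({"chr1": seg + "TTTTTTTTTT" + seg})
        _, _, status = mapper.map_segment(seg)
        assert status == "multi"

    def test_unmapped_dropped(self, toy_mapper):
        mapper, _ = toy_mapper
        _, _, status = mapper.map_segment("A" * 25)
        assert status in ("unmapped", "multi")


def _segments_for(mapper_genome, catalog, reads):
    from chimeramap.chimeras import MiRNAReadMatcher

    matcher = MiRNAReadMatcher(catalog)
    segs = []
    for read in reads:
        for hit in matcher.find(read):
            segs.extend(extract_target_segments(read, hit))
    return segs


@pytest.fixture(scope="module")
def setting():
    rng = np.random.default_rng(9)
    chrom = _rand(rng, 4000)
    target = chrom[500:530]
    return GenomeMapper({"chr1": chrom}), target


class TestMapAndDedup:

    def test_same_coords_same_barcode_collapse(self, setting, small_catalog):
        mapper, target = setting
        reads = [
            _read(MIR224 + target, "a", bc="AAAAA"),
            _read(MIR224 + target, "b", bc="AAAAA"),
        ]
        counters = {}
        out = map_and_dedup(
            _segments_for(None, small_catalog, reads), mapper, counters=counters
        )
        assert len(out) == 1 and counters.get("duplicate") == 1

    def test_distinct_barcodes_kept(self, setting, small_catalog):
        mapper, target = setting
        reads = [
            _read(MIR224 + target, "a", bc="AAAAA"),
            _read(MIR224 + target, "b", bc="CCCCC"),
        ]
        out = map_and_dedup(_segments_for(None, small_catalog, reads), mapper)
        assert len(out) == 2

    def test_precursor_targets_removed(self, setting, small_catalog):
        mapper, target = setting
        reads = [_read(MIR224 + target, "a")]
        out = map_and_dedup(
            _segments_for(None, small_catalog, reads),
            mapper,
            precursor_loci=[GenomicInterval("chr1", 490, 540, "+")],
        )
        assert out == []

    def test_idempotent(self, setting, small_catalog):
        mapper, target = setting
        reads = [
            _read(MIR224 + target, "a", bc="AAAAA"),
            _read(MIR224 + target, "b", bc="AAAAA"),
            _read(MIR224 + target, "c", bc="CCCCC"),
        ]
        segs = _segments_for(None, small_catalog, reads)
        once = map_and_dedup(segs, mapper)
        # feed the deduplicated events back through as pseudo-segments
        twice = map_and_dedup(segs + segs, mapper)
        assert {(c.barcode, c.target_interval) for c in once} == {
            (c.barcode, c.target_interval) for c in twice
        }


class TestInteractionClusters:
    def _chim(self, mirna, fam, start, end, rep, strand="+"):
        from chimeramap.chimeras import MappedChimera

        return MappedChimera(
            mirna, fam, "miRfirst",
            GenomicInterval("chr1", start, end, strand), "N" * (end - start),
            rep, "AAAAA",
        )

    def test_counts_and_bc(self):
        chims = [
            self._chim("miR-a", "F", 100, 130, "rep1"),
            self._chim("miR-a", "F", 110, 140, "rep1"),
            self._chim("miR-a", "F", 120, 150, "rep2"),
        ]
        (cluster,) = build_interaction_clusters(chims, "miRNA")
        assert cluster.chimera_count == 3 and cluster.bc == 2
        assert (cluster.span.start, cluster.span.end) == (100, 150)

    def test_family_level_merges_members(self):
        chims = [
            self._chim("miR-29a", "FAM", 100, 130, "rep1"),
            self._chim("miR-29b", "FAM", 110, 140, "rep1"),
        ]
        assert len(build_interaction_clusters(chims, "miRNA")) == 2
        assert len(build_interaction_clusters(chims, "family")) == 1

    def test_partition_of_chimeras(self, sim_called):
        called, *_ = sim_called
        clusters = build_interaction_clusters(called, "miRNA")
        assert sum(c.chimera_count for c in clusters) == len(called)
        for c in clusters:
            assert 1 <= c.bc <= 3 and c.chimera_count >= c.bc


class TestProfileAgoMirnas:
    def test_exact_full_length_counts(self, small_catalog):
        counts, unmatched = profile_ago_mirnas([MIR224], small_catalog)
        assert counts["bta-miR-224-3p"] == 1 and unmatched == []

    def test_one_mismatch_not_counted(self, small_catalog):
        s = "A" + MIR224[1:] if MIR224[0] != "A" else "C" + MIR224[1:]
        counts, unmatched = profile_ago_mirnas([s], small_catalog)
        assert sum(counts.values()) == 0 and unmatched == [s]

    def test_prefix_substring_counts(self, small_catalog):
        counts, _ = profile_ago_mirnas([MIR17[:19]], small_catalog)
        assert counts["bta-miR-17-5p"] == 1

    def test_multi_match_goes_to_first_alphanumeric(self):
        catalog = MiRNACatalog(
            [MiRNA("miR-zz", MIR17), MiRNA("miR-aa", MIR17[:22])]
        )
        counts, _ = profile_ago_mirnas([MIR17[:20]], catalog)
        assert counts == {"miR-aa": 1, "miR-zz": 0}

    def test_out_of_range_lengths_unmatched(self, small_catalog):
        counts, unmatched = profile_ago_mirnas([MIR17[:16], MIR17 + "AAA"], small_catalog)
        assert sum(counts.values()) == 0 and len(unmatched) == 2


@pytest.fixture(scope="module")
def hairpin_setting():
    rng = np.random.default_rng(13)
    chrom = _rand(rng, 3000)
    locus = GenomicInterval("chr1", 1000, 1060, "+")
    arm3 = GenomicInterval("chr1", 1038, 1060, "+")
    hp = Hairpin("mir-340", locus, {"3p": arm3}, "5p", chrom[1000:1020])
    return GenomeMapper({"chr1": chrom}), hp, chrom


class TestNovelArms:

    def test_candidate_on_free_arm(self, hairpin_setting):
        mapper, hp, chrom = hairpin_setting
        seqs = [chrom[1000:1020]] * 120
        (cand,) = detect_novel_arm_candidates(seqs, [hp], mapper)
        assert cand.proposed_name == "mir-340-5p" and cand.count == 120

    def test_min_count_threshold(self, hairpin_setting):
        mapper, hp, chrom = hairpin_setting
        assert detect_novel_arm_candidates([chrom[1000:1020]] * 99, [hp], mapper) == []

    def test_length_window_enforced(self, hairpin_setting):
        mapper, hp, chrom = hairpin_setting
        assert detect_novel_arm_candidates([chrom[1000:1016]] * 200, [hp], mapper) == []

    def test_outside_hairpin_excluded(self, hairpin_setting):
        mapper, hp, chrom = hairpin_setting
        assert detect_novel_arm_candidates([chrom[2000:2020]] * 200, [hp], mapper) == []

    def test_annotated_arm_not_a_candidate(self, hairpin_setting):
        mapper, hp, chrom = hairpin_setting
        assert detect_novel_arm_candidates([chrom[1038:1058]] * 200, [hp], mapper) == []
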