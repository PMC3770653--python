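"""Microhomology, leftmost normalization, mechanism rules, nomenclature."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rearrangemap import (
    RearrangementCall,
    RepeatElement,
    UnresolvedBreakpointError,
    annotate_call,
    classify_mechanism,
    compute_microhomology,
    deletion_size,
    format_deletion,
    format_duplication,
    format_nomenclature,
    generate_reference,
    iscn_string,
    leftmost_normalize,
    overlap_repeats,
    repeat_content,
)
from rearrangemap.junction_annotator import mlpa_bounded_notation
from rearrangemap.synthetic_locus import plant_nahr_deletion
from rearrangemap.types import Junction

from conftest import junction_shift_oracle


class TestMicrohomology:
    def test_unrelated_flanks_zero(self, plain_locus):
        # find a junction with no chance homology
        for bp5 in range(500, 600):
            length, seq, interval = compute_microhomology(plain_locus, bp5, bp5 + 3000)
            if length == 0:
                assert seq == "" and interval == (bp5, bp5)
                return
        pytest.fail("no zero-homology junction found in 100 tries")

    def test_planted_24_bp_recovered(self):
        locus, track = generate_reference(12000, 10, 0.08, seed=17)
        pairs = [
            (a, b)
            for i, a in enumerate(track)
            for b in track[i + 1 :]
            if a.strand == b.strand and b.start - a.end > 1000 and a.start > 100
        ]
        _allele, truth = plant_nahr_deletion(locus, *pairs[0], 24)
        length, _seq, _iv = compute_microhomology(locus, truth.bp5, truth.bp3)
        assert length == 24

    def test_agrees_with_exhaustive_shift_oracle(self, plain_locus):
        rng = np.random.default_rng(5)
        for _ in range(300):
            bp5 = int(rng.integers(300, 4000))
            bp3 = int(rng.integers(bp5 + 300, 9500))
            length, _seq, (lo, _hi) = compute_microhomology(plain_locus, bp5, bp3)
            o_len, o_left = junction_shift_oracle(plain_locus, bp5, bp3)
            assert (length, lo) == (o_len, o_left)

    def test_coordinates_outside_locus_rejected(self, plain_locus):
        with pytest.raises(ValueError, match="outside"):
            compute_microhomology(plain_locus, 100, 10**7)

    @settings(deadline=None, max_examples=60)
    @given(
        bp5=st.integers(min_value=300, max_value=4000),
        delta=st.integers(min_value=300, max_value=5000),
    )
    def test_leftmost_normalization_idempotent_and_allele_preserving(
        self, plain_locus, bp5, delta
    ):
        bp3 = bp5 + delta
        n5, n3, ins = leftmost_normalize(plain_locus, bp5, bp3)
        assert ins == ""
        assert (n5, n3, "") == leftmost_normalize(plain_locus, n5, n3)
        before = plain_locus.fetch(plain_locus.start, bp5) + plain_locus.fetch(
            bp3, plain_locus.end
        )
        after = plain_locus.fetch(plain_locus.start, n5) + plain_locus.fetch(
            n3, plain_locus.end
        )
        assert before == after


class TestDeletionSize:
    @pytest.mark.parametrize(
        "start, end, size",
        [
            (47654696, 47659152, 4457),
            (47696844, 47715548, 18705),
            (47649352, 47726190, 76839),
            (47672050, 47680329, 8280),
            (47694636, 47697106, 2471),
            (5, 5, 1),
        ],
    )
    def test_inclusive_arithmetic(self, start, end, size):
        assert deletion_size(start, end) == size

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            deletion_size(10, 9)


class TestOverlapRepeats:
    def test_containing_element_and_unique_sequence(self, repeat_locus):
        locus, track = repeat_locus
        r = track[0]
        mid = (r.start + r.end) // 2
        assert overlap_repeats(mid, track) == r
        assert overlap_repeats(r.start, track) == r  # endpoints inclusive
        assert overlap_repeats(r.end, track) == r
        gaps = [p for p in range(locus.start, locus.end) if all(not e.contains(p) for e in track)]
        assert overlap_repeats(gaps[0], track) is None

    def test_nahr_breakpoints_hit_same_strand_pair(self):
        locus, track = generate_reference(12000, 10, 0.08, seed=19)
        pairs = [
            (a, b)
            for i, a in enumerate(track)
            for b in track[i + 1 :]
            if a.strand == b.strand and b.start - a.end > 1000 and a.start > 100
        ]
        _allele, truth = plant_nahr_deletion(locus, *pairs[0], 30)
        r5 = overlap_repeats(truth.bp5, track)
        r3 = overlap_repeats(truth.bp3, track)
        assert r5 is not None and r3 is not None
        assert r5.strand == r3.strand and r5.family_group == r3.family_group == "Alu"


def _junction(mh):
    seq = "A" * mh
    return Junction(1000, 5000, mh, seq, "", (1000, 1000 + mh))


def _repeat(family, strand, start=900):
    return RepeatElement(family, start, start + 299, strand, "SINE")


class TestClassifyMechanism:
    def test_published_junction_rows_reproduced(self, table3_rows):
        for mh, fam5, fam3, (s5, s3), expected in table3_rows:
            r5 = _repeat(fam5, s5) if fam5 else None
            r3 = _repeat(fam3, s3, 4900) if fam3 else None
            assert classify_mechanism(_junction(mh), r5, r3) == expected

    def test_intermediate_homology_unclassified(self):
        assert classify_mechanism(_junction(7), _repeat("AluY", "+"),
                                  _repeat("AluSx", "+", 4900)) == "unclassified"

    def test_long_homology_without_repeats_unclassified(self):
        assert classify_mechanism(_junction(30), None, None) == "unclassified"

    def test_opposite_strand_repeats_do_not_qualify(self):
        assert classify_mechanism(_junction(30), _repeat("AluY", "+"),
                                  _repeat("AluY", "-", 4900)) == "unclassified"

    def test_insertion_junction_is_end_joining(self):
        j = Junction(1000, 5000, 0, "", "AAACAAT", (1000, 1000))
        assert classify_mechanism(j, _repeat("AluSx", "+"), None) == "NHEJ"


class TestNomenclature:
    def test_deletion_report_and_hgvs_styles(self):
        report, hgvs = format_deletion(47654696, 47659152)
        assert report == "g.47654696-47659152del4457"
        assert hgvs == "g.47654696_47659152del"

    def test_duplication_with_insertion_allele_string(self):
        for dup_start in (47662877, 47662878):
            report, _h = format_duplication(dup_start, 47694485, "AAACAAT")
            assert report == (
                "g.[47694485_86insAAACAAT;"
                f"47694485_86insENSG00000095002:g.{dup_start}_47694485]"
            )

    def test_single_base_deletion(self):
        report, hgvs = format_deletion(12345, 12345)
        assert report == "g.12345-12345del1" and hgvs == "g.12345del"

    def test_unresolved_breakpoints_direct_to_bounded_notation(self):
        unresolved = RearrangementCall("deletion", -1, -1, 1)
        with pytest.raises(UnresolvedBreakpointError, match="c.212"):
            format_nomenclature(unresolved)

    def test_bounded_and_iscn_helpers(self):
        assert mlpa_bounded_notation(212, 366) == "c.212-?_366+?del"
        assert iscn_string(47705272, 47705637, 3) == "arr 2p21 (47705272-47705637)×3"


class TestRepeatContent:
    def test_empty_track(self, plain_locus):
        frac, counts = repeat_content([], plain_locus)
        assert frac == 0.0 and all(v == 0 for v in counts.values())

    def test_overlapping_elements_counted_once(self, plain_locus):
        a = RepeatElement("AluY", 1000, 1299, "+", "SINE")
        b = RepeatElement("AluSx", 1200, 1499, "+", "SINE")
        frac, counts = repeat_content([a, b], plain_locus)
        assert frac == pytest.approx(500 / len(plain_locus))
        assert counts["SINE"] == 2

    def test_matches_bruteforce_mask(self, repeat_locus):
        locus, track = repeat_locus
        frac, _counts = repeat_content(track, locus)
        mask = np.zeros(len(locus), dtype=bool)
        for r in track:
            mask[r.start - locus.offset : r.end - locus.offset + 1] = True
        assert frac == pytest.approx(mask.mean())


class TestAnnotateCall:
    def test_full_annotation_of_planted_nahr(self):
        locus, track = generate_reference(12000, 10, 0.08, seed=23)
        pairs = [
            (a, b)
            for i, a in enumerate(track)
            for b in track[i + 1 :]
            if a.strand == b.strand and b.start - a.end > 1000 and a.start > 100
        ]
        _allele, truth = plant_nahr_deletion(locus, *pairs[0], 40)
        call = annotate_call(locus, track, truth.bp5, truth.bp3)
        assert call.mechanism == "NAHR"
        assert call.size == truth.bp3 - truth.bp5 - 1
        assert call.nomenclature_report_style.startswith("g.")
        assert call.junction.microhomology_len == 40

    def test_exonic_vs_intronic_pathogenicity_metadata(self, plain_locus):
        exons = [(4000, 4200)]
        exonic = annotate_call(plain_locus, [], 3900, 4500, exon_regions=exons)
        intronic = annotate_call(plain_locus, [], 5000, 5600, exon_regions=exons,
                                 co_occurring_pathogenic=True)
        assert exonic.pathogenic_flag and "exon" in exonic.pathogenic_rationale
        assert not intronic.pathogenic_flag
        assert "co-occurs" in intronic.pathogenic_rationale
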