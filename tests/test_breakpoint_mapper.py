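"""Chimeric-read detection, clustering and junction consensus."""

from __future__ import annotations

import numpy as np
import pytest

from rearrangemap import (
    cluster_chimeras,
    generate_reference,
    reconstruct_junction,
    revcomp,
    simulate_reads,
    split_align,
)
from rearrangemap.synthetic_locus import plant_nhej_deletion, plant_tandem_duplication

from conftest import junction_shift_oracle


@pytest.fixture(scope="module")
def deletion_case():
    """Locus + planted 2470 bp end-joining deletion + error-free reads."""
    locus, track = generate_reference(12000, 8, 0.08, seed=33)
    rng = np.random.default_rng(0)
    while True:
        bp5 = int(rng.integers(3000, 5000))
        try:
            allele, truth = plant_nhej_deletion(locus, bp5, bp5 + 2470)
            break
        except ValueError:
            continue
    reads = simulate_reads(allele, 400, 30, 0.0, seed=2)
    return locus, track, allele, truth, reads


class TestSplitAlign:
    def test_exact_substring_is_non_chimeric(self, deletion_case):
        locus, _t, _a, _truth, _r = deletion_case
        read = ("r", locus.fetch(2000, 2399))
        aln = split_align(read, locus)
        assert aln is not None and not aln.is_chimeric
        assert aln.seg1.ref_start == 2000

    def test_junction_read_is_chimeric_with_oracle_breakpoints(self, deletion_case):
        locus, _t, allele, truth, _r = deletion_case
        # synthesize a read centered on the junction
        j = truth.bp5 - locus.offset  # 0-based index of last 5' base in allele
        read = ("jr", allele[j - 199 : j + 201])
        aln = split_align(read, locus)
        assert aln is not None and aln.is_chimeric and aln.orientation == "del"
        o_len, o_left = junction_shift_oracle(locus, truth.bp5, truth.bp3)
        assert aln.bp5 == o_left == truth.bp5
        assert aln.bp3 - aln.bp5 == truth.bp3 - truth.bp5

    def test_read_too_short_for_anchors_rejected(self, deletion_case):
        locus, *_ = deletion_case
        with pytest.raises(ValueError, match="min_anchor"):
            split_align(("r", "ACGT" * 9), locus)

    def test_duplication_read_maps_suffix_upstream(self):
        locus, _track = generate_reference(10000, 6, 0.08, seed=35)
        allele, truth = plant_tandem_duplication(locus, 4000, 6500)
        j = truth.bp5 - locus.offset
        read = ("dr", allele[j - 199 : j + 201])
        aln = split_align(read, locus)
        assert aln is not None and aln.is_chimeric and aln.orientation == "dup"
        assert aln.bp3 < aln.bp5  # suffix anchor upstream of prefix anchor
        assert (aln.bp5, aln.bp3) == (truth.bp5, truth.bp3)


class TestClustering:
    def test_concordant_reads_one_cluster_full_support(self, deletion_case):
        locus, _t, _a, truth, reads = deletion_case
        alns = [a for a in (split_align(r, locus) for r in reads) if a]
        chim = [a for a in alns if a.is_chimeric]
        [cluster] = cluster_chimeras(alns)
        assert cluster.support == len(chim) >= 20
        assert (cluster.bp5, cluster.bp3) == (truth.bp5, truth.bp3)

    def test_support_below_minimum_discarded(self, deletion_case):
        locus, _t, allele, truth, _r = deletion_case
        j = truth.bp5 - locus.offset
        reads = [("a", allele[j - 150 : j + 250]), ("b", allele[j - 220 : j + 180])]
        alns = [split_align(r, locus) for r in reads]
        assert cluster_chimeras(alns, min_support=3) == []
        assert len(cluster_chimeras(alns, min_support=2)) == 1

    def test_empty_input_empty_output(self):
        assert cluster_chimeras([]) == []

    def test_deletion_and_duplication_on_one_allele_two_clusters(self):
        locus, _track = generate_reference(14000, 8, 0.08, seed=37)
        # one allele carrying a deletion and, downstream, a tandem duplication
        del5, del3 = 2000, 3600
        dup_s, dup_e = 8000, 11000
        allele = (
            locus.fetch(locus.start, del5)
            + locus.fetch(del3, dup_e)
            + locus.fetch(dup_s, locus.end)
        )
        reads = simulate_reads(allele, 400, 30, 0.0, seed=4)
        alns = [a for a in (split_align(r, locus) for r in reads) if a]
        clusters = cluster_chimeras(alns)
        assert sorted(c.orientation for c in clusters) == ["del", "dup"]

    def test_no_read_in_more_than_one_cluster(self, deletion_case):
        locus, _t, _a, _truth, reads = deletion_case
        alns = [a for a in (split_align(r, locus) for r in reads) if a]
        clusters = cluster_chimeras(alns)
        seen: set[str] = set()
        for c in clusters:
            assert not (set(c.read_ids) & seen)
            seen |= set(c.read_ids)

    def test_strand_symmetry(self, deletion_case):
        locus, _t, _a, _truth, reads = deletion_case
        fwd = [a for a in (split_align(r, locus) for r in reads) if a]
        rc = [(rid, revcomp(s)) for rid, s in reads]
        rev = [a for a in (split_align(r, locus) for r in rc) if a]
        key = lambda cs: [(c.bp5, c.bp3, c.orientation) for c in cs]
        assert key(cluster_chimeras(fwd)) == key(cluster_chimeras(rev))


class TestConsensus:
    def test_error_free_consensus_equals_true_junction(self, deletion_case):
        locus, _t, _a, truth, reads = deletion_case
        alns = [a for a in (split_align(r, locus) for r in reads) if a]
        [cluster] = cluster_chimeras(alns)
        cons = reconstruct_junction(locus, cluster, alns, reads)
        expected = locus.fetch(truth.bp5 - 149, truth.bp5) + locus.fetch(
            truth.bp3, truth.bp3 + 149
        )
        assert cons == expected

    def test_noisy_consensus_recovers_truth_with_support(self, deletion_case):
        locus, _t, allele, truth, _r = deletion_case
        reads = simulate_reads(allele, 400, 30, 0.01, seed=6)
        alns = [a for a in (split_align(r, locus) for r in reads) if a]
        [cluster] = cluster_chimeras(alns)
        assert cluster.support >= 10
        cons = reconstruct_junction(locus, cluster, alns, reads)
        expected = locus.fetch(truth.bp5 - 149, truth.bp5) + locus.fetch(
            truth.bp3, truth.bp3 + 149
        )
        assert cons == expected

    def test_duplication_consensus_contains_insertion_between_copies(self):
        locus, _track = generate_reference(10000, 6, 0.08, seed=39)
        for start in range(3500, 3600):
            try:
                allele, truth = plant_tandem_duplication(locus, start, start + 3300,
                                                         "AAACAAT")
                break
            except ValueError:  # insertion boundary clash: slide the interval
                continue
        reads = simulate_reads(allele, 400, 30, 0.0, seed=8)
        alns = [a for a in (split_align(r, locus) for r in reads) if a]
        [cluster] = cluster_chimeras(alns)
        cons = reconstruct_junction(locus, cluster, alns, reads)
        end_of_copy = locus.fetch(truth.bp5 - 20, truth.bp5)
        start_of_copy = locus.fetch(truth.bp3, truth.bp3 + 20)
        assert end_of_copy + "AAACAAT" + start_of_copy in cons
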