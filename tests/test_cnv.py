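import numpy as np
import pytest

from genomesurvey.cnv import (
    CNVSegment,
    MappingHit,
    ReadPairRecord,
    annotate_genes,
    call_everted_tandem,
    call_wssd,
    classify_zygosity,
    filter_deletions,
    map_region,
    read_pair_table,
    shared_duplications,
)
from genomesurvey.depthmodel import DepthCalibration, DepthWindow
from genomesurvey.seqio import GenomeSequence, GenomicInterval, IntervalSet, revcomp
from tests.conftest import make_depth_windows

CALIB = DepthCalibration(mean=100.0, sd=10.0)  # cutoffs 130 / 80


def brute_force_wssd(depths, calib, width=500, scaffold="s1"):
    """Independent oracle: test every heptad, union the covered windows, trim
    each run to its outermost marked window."""
    out = []
    n = len(depths)
    for kind in ("duplication", "deletion"):
        marks = [
            (d > calib.dup_cutoff) if kind == "duplication" else (d < calib.del_cutoff)
            for d in depths
        ]
        covered = [False] * n
        for i in range(n - 6):
            if sum(marks[i : i + 7]) >= 6:
                for j in range(i, i + 7):
                    covered[j] = True
        i = 0
        while i < n:
            if not covered[i]:
                i += 1
                continue
            j = i
            while j < n and covered[j]:
                j += 1
            idx = [k for k in range(i, j) if marks[k]]
            if idx:
                out.append((scaffold, kind, idx[0] * width, (idx[-1] + 1) * width, len(idx)))
            i = j
    return sorted(out)


class TestCallWssd:
    def test_six_of_seven_duplication(self):
        wins = make_depth_windows([135, 140, 128, 150, 133, 138, 141])
        (seg,) = call_wssd(wins, CALIB)
        assert (seg.type, seg.start, seg.end, seg.n_windows) == (
            "duplication",
            0,
            3500,
            6,
        )

    def test_flat_depth_no_calls(self):
        wins = make_depth_windows([100.0] * 50)
        assert call_wssd(wins, CALIB) == []

    def test_marks_pattern_without_qualifying_heptad(self):
        pattern = [1, 1, 1, 1, 1, 0, 0, 0, 1, 1]
        wins = make_depth_windows([150 if m else 100 for m in pattern])
        assert call_wssd(wins, CALIB) == []
        assert brute_force_wssd([150 if m else 100 for m in pattern], CALIB) == []

    def test_flagged_windows_break_runs_and_never_enter_calls(self):
        # a flagged window splits the run, so neither 3+3 side qualifies
        wins = make_depth_windows([150.0] * 7)
        wins[3].n_fraction = 0.9  # gap-dominated
        assert call_wssd(wins, CALIB) == []
        # with seven marked windows on one side the call forms there and
        # stops short of the flagged window
        wins2 = make_depth_windows([150.0] * 10)
        wins2[7].n_fraction = 0.9
        (seg,) = call_wssd(wins2, CALIB)
        assert (seg.start, seg.end, seg.n_windows) == (0, 3500, 7)
        flagged = wins2[7]
        assert not (seg.start < flagged.end and flagged.start < seg.end)

    def test_unordered_windows_rejected(self):
        wins = make_depth_windows([100.0] * 10)
        with pytest.raises(ValueError, match="ordered"):
            call_wssd(list(reversed(wins)), CALIB)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            depths = rng.normal(100, 25, 1000)
            wins = make_depth_windows(depths)
            got = sorted(
                (s.scaffold, s.type, s.start, s.end, s.n_windows)
                for s in call_wssd(wins, CALIB)
            )
            assert got == brute_force_wssd(depths, CALIB)

    def test_call_symmetry_under_mirrored_anomalies(self, rng):
        # mirroring depths around the mean with swapped multipliers swaps
        # duplication and deletion calls on the same coordinates
        depths = rng.normal(100, 30, 600)
        calib = DepthCalibration(mean=100.0, sd=10.0, dup_multiplier=2.0, del_multiplier=2.0)
        wins = make_depth_windows(depths)
        mirrored = make_depth_windows(200.0 - depths)
        flip = {"duplication": "deletion", "deletion": "duplication"}
        got = sorted((s.start, s.end, flip[s.type]) for s in call_wssd(wins, calib))
        exp = sorted((s.start, s.end, s.type) for s in call_wssd(mirrored, calib))
        assert got == exp


class TestFilterDeletions:
    def _deletion_segment(self, n=8):
        wins = make_depth_windows([50.0] * n)
        (seg,) = call_wssd(wins, CALIB)
        assert seg.type == "deletion" and seg.n_windows == n
        return seg

    def test_masked_windows_unmarked_and_rule_reapplied(self):
        seg = self._deletion_segment(8)
        mask = IntervalSet(
            [GenomicInterval("s1", w.start, w.end) for w in seg.windows[:3]]
        )
        out = filter_deletions([seg], mask, IntervalSet())
        assert out == []  # 5 surviving marks cannot satisfy 6-of-7

    def test_empty_mask_is_identity(self):
        seg = self._deletion_segment(8)
        (out,) = filter_deletions([seg], IntervalSet(), IntervalSet())
        assert (out.start, out.end, out.n_windows) == (seg.start, seg.end, 8)

    def test_segment_inside_gap_removed(self):
        seg = self._deletion_segment(8)
        gaps = IntervalSet([GenomicInterval("s1", 0, seg.end)])
        assert filter_deletions([seg], IntervalSet(), gaps) == []

    def test_duplications_untouched(self):
        wins = make_depth_windows([150.0] * 8)
        (dup,) = call_wssd(wins, CALIB)
        mask = IntervalSet([GenomicInterval("s1", 0, 10_000)])
        (out,) = filter_deletions([dup], mask, mask)
        assert out is dup


class TestClassifyZygosity:
    def _deletion(self, depths):
        wins = make_depth_windows(depths)
        (seg,) = call_wssd(wins, CALIB)
        return seg

    def test_heterozygous_when_no_window_below_floor(self):
        seg = self._deletion([45, 50, 48, 45, 50, 48, 45])
        assert classify_zygosity(seg, floor=5.0) == "heterozygous"

    def test_homozygous_near_zero_depth(self):
        seg = self._deletion([0, 1, 0, 1, 0, 1, 0])
        assert classify_zygosity(seg, floor=5.0) == "homozygous"

    def test_floor_zero_makes_every_deletion_heterozygous(self):
        seg = self._deletion([0, 0, 0, 0, 0, 0, 0])
        assert classify_zygosity(seg, floor=0.0) == "heterozygous"

    def test_duplication_rejected(self):
        wins = make_depth_windows([150.0] * 7)
        (dup,) = call_wssd(wins, CALIB)
        with pytest.raises(ValueError):
            classify_zygosity(dup)


class TestAnnotateGenes:
    def test_overlap_attaches_label(self):
        seg = CNVSegment("s1", 1000, 5000, "duplication", 8, 150.0)
        genes = IntervalSet([GenomicInterval("s1", 4000, 8000, "geneA")])
        _, summary = annotate_genes([seg], genes)
        assert seg.genes == ["geneA"]
        assert summary == {"segments_with_genes": 1, "unique_genes": 1}

    def test_two_segments_one_gene_counting_semantics(self):
        segs = [
            CNVSegment("s1", 0, 2000, "duplication", 8, 150.0),
            CNVSegment("s1", 3000, 5000, "duplication", 8, 150.0),
        ]
        genes = IntervalSet([GenomicInterval("s1", 1000, 4000, "geneA")])
        _, summary = annotate_genes(segs, genes)
        assert summary == {"segments_with_genes": 2, "unique_genes": 1}

    def test_no_genes(self):
        seg = CNVSegment("s1", 0, 2000, "duplication", 8, 150.0)
        _, summary = annotate_genes([seg], IntervalSet())
        assert seg.genes == []
        assert summary == {"segments_with_genes": 0, "unique_genes": 0}


def everted(scaffold, lo, hi):
    return ReadPairRecord(scaffold, lo, hi, "reverse", "forward", insert=hi - lo)


def concordant(scaffold, lo, hi):
    return ReadPairRecord(scaffold, lo, hi, "forward", "reverse", insert=hi - lo)


class TestEvertedTandem:
    def test_single_cluster(self):
        pairs = [everted("s1", 10_000, 12_000) for _ in range(5)]
        (cand,) = call_everted_tandem(pairs, min_support=3)
        assert (cand.scaffold, cand.start, cand.end) == ("s1", 10_000, 12_000)
        assert cand.provenance == "everted_pair"

    def test_below_support_no_candidate(self):
        pairs = [everted("s1", 10_000, 12_000)] * 2
        assert call_everted_tandem(pairs, min_support=3) == []

    def test_concordant_only_is_empty(self):
        pairs = [concordant("s1", i * 1000, i * 1000 + 400) for i in range(20)]
        assert call_everted_tandem(pairs) == []

    def test_normalization_swaps_orientations(self):
        p = ReadPairRecord("s1", 5000, 1000, "forward", "reverse", insert=4000)
        assert (p.pos1, p.pos2) == (1000, 5000)
        assert (p.orient1, p.orient2) == ("reverse", "forward")
        assert p.everted

    def test_distant_clusters_split(self):
        a = [everted("s1", 10_000, 12_000) for _ in range(3)]
        b = [everted("s1", 50_000, 52_000) for _ in range(3)]
        cands = call_everted_tandem(a + b, min_support=3, max_cluster_gap=1000)
        assert [(c.start, c.end) for c in cands] == [(10_000, 12_000), (50_000, 52_000)]

    def test_pair_table_roundtrip(self, tmp_path):
        from genomesurvey.simdata import write_pair_table

        pairs = [everted("s1", 100, 900), concordant("s2", 0, 350)]
        p = tmp_path / "pairs.tsv"
        write_pair_table(pairs, p)
        back = read_pair_table(p)
        assert [(r.scaffold, r.pos1, r.pos2, r.everted) for r in back] == [
            ("s1", 100, 900, True),
            ("s2", 0, 350, False),
        ]


@pytest.fixture(scope="module")
def random_target():
    rng = np.random.default_rng(3)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50_000)])
    return [GenomeSequence("t1", seq)]


class TestMapRegion:
    def test_exact_substring(self, random_target):
        q = random_target[0].seq[10_000:12_000]
        (hit,) = map_region(q, random_target)
        assert (hit.start, hit.end, hit.strand, hit.identity) == (10_000, 12_000, "+", 1.0)

    def test_reverse_complement_hits_minus_strand(self, random_target):
        q = revcomp(random_target[0].seq[10_000:12_000])
        (hit,) = map_region(q, random_target)
        assert (hit.start, hit.end, hit.strand) == (10_000, 12_000, "-")

    def test_mutated_query_identity(self, random_target):
        rng = np.random.default_rng(11)
        q = list(random_target[0].seq[20_000:22_000])
        for p in rng.choice(2000, 200, replace=False):
            q[p] = "ACGT"[("ACGT".index(q[p]) + 1 + rng.integers(3)) % 4]
        (hit,) = map_region("".join(q), random_target)
        assert 0.88 <= hit.identity <= 0.92
        assert hit.aligned_len >= 1000

    def test_query_shorter_than_seed(self, random_target):
        with pytest.raises(ValueError):
            map_region("ACGT", random_target)


class TestSharedDuplications:
    def test_identical_assemblies_share_everything(self, random_target):
        segs = [
            CNVSegment("t1", 5000, 9000, "duplication", 8, 150.0),
            CNVSegment("t1", 20_000, 24_000, "duplication", 8, 150.0),
        ]
        part = shared_duplications(segs, random_target, list(segs), random_target)
        assert len(part["shared_a"]) == len(part["shared_b"]) == 2
        assert part["a_only"] == [] and part["b_only"] == []

    def test_mapping_without_reciprocal_call_is_private(self, random_target):
        segs_a = [CNVSegment("t1", 5000, 9000, "duplication", 8, 150.0)]
        part = shared_duplications(segs_a, random_target, [], random_target)
        assert part["a_only"] == segs_a
        assert part["shared_a"] == []

    def test_three_event_synthetic_pair_partition(self):
        from genomesurvey.simdata import shared_duplication_pair

        A, sa, B, sb = shared_duplication_pair(seed=9)
        part = shared_duplications(sa, A, sb, B)
        counts = {k: len(v) for k, v in part.items()}
        assert counts == {"shared_a": 1, "shared_b": 1, "a_only": 1, "b_only": 1}
        assert part["shared_a"][0].start == 30_000
        assert part["shared_b"][0].start == 60_000
        # symmetry: swapping assemblies swaps the labels
        swapped = shared_duplications(sb, B, sa, A)
        assert {k: len(v) for k, v in swapped.items()} == counts
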