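"""Read mapping, coverage statistics, and the non-specific read fraction."""
import numpy as np
import pytest

from markergeo import cluster as clu
from markergeo import recruit as rr

from conftest import mutate_dna, random_dna


def brute_force_best(read, refs, match=2, mismatch=-3):
    """Score every full-containment placement on both strands; return the
    primary under the mapper's tie-break and the best remaining score."""
    L = len(read)
    placements = {}
    for strand, s in (("+", read), ("-", rr.reverse_complement(read))):
        for rid in sorted(refs):
            ref = refs[rid]
            for start in range(0, len(ref) - L + 1):
                m = sum(1 for x, y in zip(ref[start : start + L], s) if x == y)
                placements[(rid, start, strand)] = (match - mismatch) * m + mismatch * L
    ranked = sorted(placements.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1], kv[0][2]))
    (rid, start, strand), best = ranked[0]
    secondary = ranked[1][1] if len(ranked) > 1 else None
    return rid, start, strand, best, secondary


class TestMapReads:
    def test_exact_substring_maps_with_maximal_score(self):
        rng = np.random.default_rng(0)
        ref = random_dna(rng, 300)
        read = ref[100:170]
        (aln,) = rr.map_reads([("r1", read)], {"ref1": ref})
        assert aln.is_mapped and aln.ref_id == "ref1"
        assert (aln.ref_start, aln.ref_end) == (100, 170)
        assert aln.score == 2 * 70
        assert aln.secondary_best_score is None or aln.secondary_best_score < aln.score

    def test_reverse_complement_read_reported_on_forward_coordinates(self):
        rng = np.random.default_rng(1)
        ref = random_dna(rng, 300)
        read = rr.reverse_complement(ref[50:120])
        (aln,) = rr.map_reads([("r1", read)], {"ref1": ref})
        assert aln.is_mapped and aln.strand == "-"
        assert (aln.ref_start, aln.ref_end) == (50, 120)

    def test_foreign_read_with_no_shared_kmer_is_unmapped(self):
        ref = "A" * 200
        (aln,) = rr.map_reads([("r1", "CGTT" * 20)], {"ref1": ref})
        assert not aln.is_mapped

    def test_read_from_duplicated_region_is_multimapped(self):
        rng = np.random.default_rng(2)
        core = random_dna(rng, 150)
        refs = {"refA": core + random_dna(rng, 100), "refB": core + random_dna(rng, 100)}
        read = core[10:110]
        (aln,) = rr.map_reads([("r1", read)], refs)
        assert aln.is_mapped and aln.is_multimapped
        assert aln.score == aln.secondary_best_score
        # brute force confirms both placements are co-optimal
        rid, start, strand, best, secondary = brute_force_best(read, refs)
        assert (aln.ref_id, aln.ref_start, aln.strand) == (rid, start, strand)
        assert (aln.score, aln.secondary_best_score) == (best, secondary)

    def test_primary_placement_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(3)
        refs = {f"ref{i}": random_dna(rng, 250) for i in range(5)}
        names = sorted(refs)
        for trial in range(60):
            rid = names[int(rng.integers(len(names)))]
            start = int(rng.integers(0, 151))
            read = refs[rid][start : start + 100]
            read = mutate_dna(rng, read, int(rng.integers(0, 2)))
            if rng.random() < 0.5:
                read = rr.reverse_complement(read)
            (aln,) = rr.map_reads([("r", read)], refs)
            b_rid, b_start, b_strand, b_score, _ = brute_force_best(read, refs)
            assert aln.is_mapped
            assert (aln.ref_id, aln.ref_start, aln.strand, aln.score) == (
                b_rid, b_start, b_strand, b_score)

    def test_k_larger_than_every_read_is_config_error(self):
        with pytest.raises(ValueError, match="k=50"):
            rr.map_reads([("r1", "ACGTACGT")], {"ref1": "A" * 100}, k=50)


class TestProfiles:
    def test_no_alignments_gives_zero_profile(self):
        p = rr.build_profile([], "ref1", "s1", 300)
        assert p.detection == 0.0 and p.q2q3_mean == 0.0 and p.mapped_reads == 0

    def test_tiling_reads_give_full_detection(self):
        alns = [
            rr.ReadAlignment(f"r{i}", "ref1", i * 50, (i + 1) * 50, 100, None, True)
            for i in range(6)
        ]
        p = rr.build_profile(alns, "ref1", "s1", 300)
        assert p.detection == 1.0 and p.q2q3_mean == 1.0 and p.mapped_reads == 6

    def test_half_covered_reference(self):
        alns = [rr.ReadAlignment("r1", "ref1", 0, 50, 100, None, True)]
        p = rr.build_profile(alns, "ref1", "s1", 100)
        assert p.detection == 0.5

    def test_out_of_bounds_alignment_raises(self):
        alns = [rr.ReadAlignment("r1", "ref1", 250, 350, 100, None, True)]
        with pytest.raises(ValueError, match="bounds"):
            rr.build_profile(alns, "ref1", "s1", 300)

    def test_depth_conservation_and_detection_monotonicity(self):
        rng = np.random.default_rng(4)
        alns = []
        prev_detection = 0.0
        total_len = 0
        for i in range(30):
            start = int(rng.integers(0, 200))
            end = start + int(rng.integers(10, 100))
            alns.append(rr.ReadAlignment(f"r{i}", "ref1", start, min(end, 300), 10, None, True))
            total_len += min(end, 300) - start
            p = rr.build_profile(alns, "ref1", "s1", 300)
            assert p.detection >= prev_detection
            prev_detection = p.detection
            assert int(p.depth.sum()) == total_len


class TestQ2Q3:
    @pytest.mark.parametrize(
        "depth, expected",
        [
            ([5] * 10, 5.0),                      # uniform vector
            ([0, 0, 0, 0, 10, 10, 10, 10], 5.0),  # middle-half ranks 3..6
            ([7], 7.0),                           # degenerate n < 4
            ([1, 2, 3], 2.0),
        ],
    )
    def test_rank_rule(self, depth, expected):
        assert rr.q2q3_mean(depth) == pytest.approx(expected)

    def test_never_exceeds_max_depth(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            d = rng.integers(0, 100, size=int(rng.integers(1, 40)))
            assert rr.q2q3_mean(d) <= d.max()


class TestNonspecificFraction:
    def _aln(self, i, score, secondary):
        return rr.ReadAlignment(f"r{i}", "ref1", 0, 50, score, secondary, True)

    def test_all_unique_is_zero(self):
        alns = [self._aln(i, 100, 90) for i in range(4)]
        assert rr.nonspecific_fraction(alns) == 0.0

    def test_half_tied_is_half(self):
        alns = [self._aln(0, 100, 100), self._aln(1, 100, 100),
                self._aln(2, 100, 80), self._aln(3, 100, None)]
        assert rr.nonspecific_fraction(alns) == 0.5

    def test_no_mapped_reads_is_zero(self):
        alns = [rr.ReadAlignment("r0", None, 0, 0, 0, None, False)]
        assert rr.nonspecific_fraction(alns) == 0.0

    def test_sister_pair_merging_removes_nonspecific_recruitment(self):
        """Two references above 98% identity recruit ambiguously when both
        are kept (clustering at 0.99) and unambiguously after 97% merging."""
        rng = np.random.default_rng(6)
        base = random_dna(rng, 400)
        sister = mutate_dna(rng, base, 6)  # 98.5% identity
        ident, _ = clu.pairwise_identity(base, sister)
        assert ident == pytest.approx(0.985)
        fine = clu.cluster_greedy({"a": base, "b": sister}, identity=0.99, min_target_coverage=0.8)
        assert len(fine) == 2  # both retained at the fine threshold
        coarse = clu.cluster_greedy({"a": base, "b": sister}, identity=0.97, min_target_coverage=0.8)
        assert len(coarse) == 1  # merged at the recommended threshold
        reads = [(f"r{i}", base[s : s + 100]) for i, s in enumerate(rng.integers(0, 301, size=150))]
        both = rr.nonspecific_fraction(rr.map_reads(reads, {"a": base, "b": sister}))
        merged = rr.nonspecific_fraction(
            rr.map_reads(reads, {coarse[0].representative_id: base})
        )
        assert both > 0.0
        assert merged == 0.0


class TestSamRoundTrip:
    def test_write_then_ingest_preserves_alignments(self, tmp_path):
        rng = np.random.default_rng(7)
        refs = {"refA": random_dna(rng, 300), "refB": random_dna(rng, 280)}
        reads = [("r1", refs["refA"][10:110]),
                 ("r2", rr.reverse_complement(refs["refB"][50:150])),
                 ("r3", refs["refA"][200:300])]
        alns = rr.map_reads(reads, refs)
        sam = tmp_path / "out.sam"
        rr.write_sam(sam, alns, refs)
        back = rr.ingest_sam(sam, refs)
        assert len(back) == len([a for a in alns if a.is_mapped])
        by_id = {a.read_id: a for a in back}
        for a in alns:
            if a.is_mapped:
                b = by_id[a.read_id]
                assert (b.ref_id, b.ref_start, b.ref_end, b.score, b.secondary_best_score,
                        b.strand) == (a.ref_id, a.ref_start, a.ref_end, a.score,
                                      a.secondary_best_score, a.strand)

    def test_tied_as_xs_scores_mark_multimapped(self, tmp_path):
        sam = tmp_path / "multi.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:refA\tLN:300\n"
            "r1\t0\trefA\t11\t255\t100M\t*\t0\t0\t*\t*\tAS:i:140\tXS:i:140\n"
            "r2\t0\trefA\t51\t255\t100M\t*\t0\t0\t*\t*\tAS:i:180\n"
        )
        refs = {"refA": "A" * 300}
        a1, a2 = rr.ingest_sam(sam, refs)
        assert a1.is_multimapped
        assert a2.secondary_best_score is None and not a2.is_multimapped

    def test_header_only_sam_is_empty(self, tmp_path):
        sam = tmp_path / "empty.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:refA\tLN:300\n")
        assert rr.ingest_sam(sam, {"refA": "A" * 300}) == []

    def test_unknown_reference_raises(self, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:refX\tLN:300\n"
            "r1\t0\trefX\t1\t255\t50M\t*\t0\t0\t*\t*\tAS:i:100\n"
        )
        with pytest.raises(KeyError, match="refX"):
            rr.ingest_sam(sam, {"refA": "A" * 300})
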