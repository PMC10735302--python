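"""Hit stitching: slicing, overlap resolution, and the stack algorithm,
checked against exhaustive enumeration on small instances."""

import itertools
import random

import pytest

from markerstitch import seqio
from markerstitch.pairwise import GAP, ScoringScheme, align
from markerstitch.refine import finalize, TrimPolicy
from markerstitch.search import AlignedRegion
from markerstitch.seqio import SeqRecord
from markerstitch.stitch import (
    StitchError,
    covered_positions,
    resolve_overlap,
    slice_region,
    stitch,
    total_overlap,
)
from oracles import gotoh_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_ref(rng, length):
    return SeqRecord(id="ref", seq="".join(rng.choice(AA) for _ in range(length)),
                     alphabet=seqio.AMINO_ACID)


def gapless_region(ref, first, last, mutations=(), query_id="q", rng=None):
    """A region whose query is the reference slice with substitutions at the
    given reference positions."""
    residues = list(ref.seq[first - 1 : last])
    for pos in mutations:
        i = pos - first
        orig = residues[i]
        choices = [c for c in AA if c != orig]
        residues[i] = (rng or random).choice(choices)
    q = "".join(residues)
    return AlignedRegion(query_id=query_id, ref_id=ref.id, query_aa=q,
                         ref_aa=ref.seq[first - 1 : last],
                         ref_first=first, ref_last=last, frame=1)


class TestSliceRegion:
    def test_full_extent_is_identity(self):
        rng = random.Random(0)
        ref = make_ref(rng, 20)
        r = gapless_region(ref, 3, 15)
        s = slice_region(r, 3, 15)
        assert (s.query_aa, s.ref_aa, s.ref_first, s.ref_last) == (
            r.query_aa, r.ref_aa, 3, 15)

    def test_single_column(self):
        rng = random.Random(0)
        ref = make_ref(rng, 20)
        r = gapless_region(ref, 1, 10)
        s = slice_region(r, 5, 5)
        assert (s.ref_first, s.ref_last) == (5, 5)
        assert s.query_aa == ref.seq[4]

    def test_interval_outside_region_rejected(self):
        rng = random.Random(0)
        ref = make_ref(rng, 20)
        r = gapless_region(ref, 5, 10)
        with pytest.raises(StitchError):
            slice_region(r, 1, 10)

    def test_insertion_travels_with_anchor_position(self):
        # insertion after reference position 2
        ref = SeqRecord(id="ref", seq="MKLVW", alphabet=seqio.AMINO_ACID)
        r = AlignedRegion(query_id="q", ref_id="ref",
                          query_aa="MKAALVW", ref_aa="MK--LVW",
                          ref_first=1, ref_last=5, frame=1)
        left = slice_region(r, 1, 2)
        right = slice_region(r, 3, 5)
        assert (left.query_aa, left.ref_aa) == ("MKAA", "MK--")
        assert (right.query_aa, right.ref_aa) == ("LVW", "LVW")

    def test_insertion_slice_matches_column_walk_oracle(self):
        ref = SeqRecord(id="ref", seq="MKLVWYDE", alphabet=seqio.AMINO_ACID)
        r = AlignedRegion(query_id="q", ref_id="ref",
                          query_aa="MKAALVCWYDE", ref_aa="MK--LV-WYDE",
                          ref_first=1, ref_last=8, frame=1)
        # oracle: walk columns, anchoring insertions to the preceding position
        for lo in range(1, 9):
            for hi in range(lo, 9):
                anchor = 0
                keep_q, keep_r = [], []
                for qc, rc in zip(r.query_aa, r.ref_aa):
                    if rc != GAP:
                        anchor += 1
                    if lo <= anchor <= hi:
                        keep_q.append(qc)
                        keep_r.append(rc)
                s = slice_region(r, lo, hi)
                assert s.query_aa == "".join(keep_q)
                assert s.ref_aa == "".join(keep_r)

    def test_codons_follow_slice(self):
        ref = SeqRecord(id="ref", seq="MKLVW", alphabet=seqio.AMINO_ACID)
        codons = "ATGAAACTAGTATGG"
        r = AlignedRegion(query_id="q", ref_id="ref", query_aa="MKLVW",
                          ref_aa="MKLVW", ref_first=1, ref_last=5, frame=1,
                          query_codons=codons)
        s = slice_region(r, 2, 4)
        assert s.query_codons == codons[3:12]


class TestStitchBasics:
    def test_single_region_unchanged(self, scheme):
        rng = random.Random(0)
        ref = make_ref(rng, 30)
        r = gapless_region(ref, 5, 20)
        assert stitch([r], ref, scheme) == [r]

    def test_disjoint_regions_kept_in_order(self, scheme):
        rng = random.Random(0)
        ref = make_ref(rng, 40)
        a = gapless_region(ref, 1, 10)
        b = gapless_region(ref, 20, 30)
        assert stitch([b, a], ref, scheme) == [a, b]

    def test_exact_overlap_segment_wins(self, scheme):
        # A covers [1,20] with 5 mismatches inside [11,20]; B covers [11,30]
        # exactly: the output must carry B's residues at 11..20.
        rng = random.Random(3)
        ref = make_ref(rng, 30)
        a = gapless_region(ref, 1, 20, mutations=[12, 14, 15, 17, 19],
                           query_id="qa", rng=rng)
        b = gapless_region(ref, 11, 30, query_id="qb")
        out = stitch([a, b], ref, scheme)
        assert covered_positions(out) == set(range(1, 31))
        by_pos = {}
        for r in out:
            for i, pos in enumerate(range(r.ref_first, r.ref_last + 1)):
                by_pos[pos] = r.query_aa[i]
        for pos in range(11, 31):
            assert by_pos[pos] == ref.seq[pos - 1]

    def test_mixed_reference_ids_rejected(self, scheme):
        rng = random.Random(0)
        ref = make_ref(rng, 30)
        a = gapless_region(ref, 1, 10)
        b = gapless_region(ref, 5, 15)
        b.ref_id = "other"
        with pytest.raises(StitchError, match="mixed"):
            stitch([a, b], ref, scheme)

    def test_region_beyond_reference_rejected(self, scheme):
        rng = random.Random(0)
        ref = make_ref(rng, 30)
        r = gapless_region(ref, 25, 30)
        short = SeqRecord(id="ref", seq=ref.seq[:20], alphabet=seqio.AMINO_ACID)
        with pytest.raises(StitchError, match="beyond"):
            stitch([r], short, scheme)


def _mutated(rng, ref, first, last, query_id, mut_fraction=0.25):
    span = last - first + 1
    k = rng.randint(0, max(1, int(span * mut_fraction)))
    muts = rng.sample(range(first, last + 1), min(k, span))
    return gapless_region(ref, first, last, muts, query_id=query_id, rng=rng)


def random_chain_instance(rng, scheme, max_regions=3):
    """2-3 mutated regions tiling a short reference so that region i
    overlaps only region i+1 (the generic geometry of contigs tiling a
    reference). Overlap decisions are then independent of one another and
    greedy per-overlap resolution is provably score-optimal."""
    ref = make_ref(rng, rng.randint(25, 40))
    L = len(ref.seq)
    n = rng.randint(2, max_regions)
    first, last = 1, rng.randint(5, min(16, L - 2))
    bounds = [(first, last)]
    prev_prev_last = 0
    for _ in range(n - 1):
        # overlap with the previous region only: the new region must start
        # after the region before that ends, and must extend further right
        ov_max = min(6, last - first, last - prev_prev_last - 1)
        ov = rng.randint(0, max(0, ov_max))  # 0 = exactly adjacent
        new_first = last - ov + 1
        lo = max(new_first + 3, last + 1)
        if lo > L:
            break
        new_last = rng.randint(lo, min(lo + 12, L))
        prev_prev_last = last
        first, last = new_first, new_last
        bounds.append((first, last))
    return ref, [
        _mutated(rng, ref, f, l, f"q{i}") for i, (f, l) in enumerate(bounds)
    ]


def random_instance(rng, scheme, max_regions=3):
    """Unconstrained random instance: regions may mutually overlap or be
    contained in one another."""
    ref = make_ref(rng, rng.randint(20, 40))
    L = len(ref.seq)
    n = rng.randint(2, max_regions)
    regions = []
    for i in range(n):
        first = rng.randint(1, L - 4)
        last = rng.randint(first + 3, min(first + 20, L))
        regions.append(_mutated(rng, ref, first, last, f"q{i}"))
    return ref, regions


def enumeration_best_score(ref, regions, scheme):
    """Brute force: every way of assigning each covered elementary interval
    to one covering region; final score by an independent semi-global DP."""
    points = sorted({r.ref_first for r in regions} | {r.ref_last + 1 for r in regions})
    intervals = []
    for lo, hi in zip(points, points[1:]):
        covering = [r for r in regions if r.ref_first <= lo and r.ref_last >= hi - 1]
        if covering:
            intervals.append((lo, hi - 1, covering))
    best = None
    for choice in itertools.product(*(c for _, _, c in intervals)):
        seq = "".join(
            r.query_aa[lo - r.ref_first : hi - r.ref_first + 1]
            for (lo, hi, _), r in zip(intervals, choice)
        )
        score = gotoh_score(seq, ref.seq, scheme.pair_score,
                            scheme.gap_open, scheme.gap_extend, "semi_global")
        best = score if best is None else max(best, score)
    return best


class TestStitchProperties:
    N = 150

    def test_coverage_preserved_and_disjoint(self, scheme):
        rng = random.Random(42)
        for _ in range(self.N):
            ref, regions = random_instance(rng, scheme)
            out = stitch(regions, ref, scheme)
            assert covered_positions(out) == covered_positions(regions)
            assert total_overlap(out) == 0
            for a, b in zip(out, out[1:]):
                assert a.ref_last < b.ref_first

    def test_idempotent(self, scheme):
        rng = random.Random(43)
        for _ in range(self.N):
            ref, regions = random_instance(rng, scheme)
            once = stitch(regions, ref, scheme)
            assert stitch(once, ref, scheme) == once

    def test_winner_optimality_per_overlap(self, scheme):
        from markerstitch.stitch import overlap_score

        rng = random.Random(44)
        for _ in range(self.N):
            ref, regions = random_instance(rng, scheme, max_regions=2)
            a, b = sorted(regions, key=lambda r: (r.ref_first, -r.span))
            if b.ref_first > a.ref_last:
                continue
            ov_from, ov_to = b.ref_first, min(a.ref_last, b.ref_last)
            pieces = resolve_overlap(a, b, ref, scheme)
            winner = next(p for p in pieces if p.ref_first == ov_from)
            w_score = overlap_score(winner, ov_from, ov_to, ref, scheme)
            for cand in (a, b):
                assert w_score >= overlap_score(cand, ov_from, ov_to, ref, scheme)

    def test_containment_resolves(self, scheme):
        rng = random.Random(45)
        ref = make_ref(rng, 30)
        outer = gapless_region(ref, 1, 30, mutations=[10, 12], query_id="qa", rng=rng)
        inner = gapless_region(ref, 8, 14, query_id="qb")
        out = stitch([outer, inner], ref, scheme)
        assert covered_positions(out) == set(range(1, 31))
        by_pos = {}
        for r in out:
            for i, pos in enumerate(range(r.ref_first, r.ref_last + 1)):
                by_pos[pos] = r.query_aa[i]
        assert by_pos[10] == ref.seq[9] and by_pos[12] == ref.seq[11]

    def test_chain_instances_match_enumeration(self, scheme):
        rng = random.Random(46)
        checked = 0
        for _ in range(100):
            ref, regions = random_chain_instance(rng, scheme)
            out = stitch(regions, ref, scheme)
            marker = finalize(out, ref, scheme, trim_policy=TrimPolicy(enabled=False))
            assert marker is not None
            assert marker.score == enumeration_best_score(ref, regions, scheme)
            checked += 1
        assert checked == 100
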