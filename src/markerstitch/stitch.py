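"""Hit stitching: merge overlapping translated-search hits into an ordered,
non-overlapping tiling of the reference.

The procedure is a stack algorithm. Regions are sorted by where they align
on the reference and pushed one by one; whenever the incoming region
overlaps the top of the stack, the top is popped and the two regions are
realigned *only over the interval in which they overlap*. The higher-scoring
candidate keeps the overlap, and up to three sliced parts go back on the
stack: the flank preceding the overlap (from the earlier region), the
winning overlap segment, and the flank following it (from whichever region
extends further). Passes repeat until no overlaps remain — a later region
can reach past its immediate predecessor, so one pass is not always enough.

Slicing always cuts the *original* aligned strings; the overlap realignment
is used only to decide the winner, so residues (and their codon provenance)
are never rewritten by the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .pairwise import GAP, ScoringScheme, DEFAULT_SCHEME, align
from .search import AlignedRegion
from .seqio import SeqRecord

MAX_PASSES = 10_000


class StitchError(ValueError):
    pass


def sort_key(region: AlignedRegion) -> tuple:
    # ref_first ascending; ties: longer region first, then query_id
    return (region.ref_first, -region.span, region.query_id)


def covered_positions(regions: Sequence[AlignedRegion]) -> set[int]:
    pos: set[int] = set()
    for r in regions:
        pos.update(range(r.ref_first, r.ref_last + 1))
    return pos


def total_overlap(regions: Sequence[AlignedRegion]) -> int:
    """Sum of pairwise overlap lengths; zero iff the set is non-overlapping."""
    ordered = sorted(regions, key=sort_key)
    total = 0
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if b.ref_first > a.ref_last:
                break
            total += min(a.ref_last, b.ref_last) - b.ref_first + 1
    return total


def slice_region(region: AlignedRegion, ref_from: int, ref_to: int) -> AlignedRegion:
    """Restrict a region to the reference interval [ref_from, ref_to].

    Columns are walked left to right; each column is anchored to the last
    reference position consumed, so insertion columns (gap in the reference)
    travel with the reference position they follow.
    """
    if not (region.ref_first <= ref_from <= ref_to <= region.ref_last):
        raise StitchError(
            f"slice [{ref_from}, {ref_to}] outside region "
            f"[{region.ref_first}, {region.ref_last}]"
        )
    q_out: list[str] = []
    r_out: list[str] = []
    codons_out: list[str] = []
    ref_pos = region.ref_first - 1  # last consumed reference position
    codon_idx = 0
    for qc, rc in zip(region.query_aa, region.ref_aa):
        if rc != GAP:
            ref_pos += 1
        inside = ref_from <= ref_pos <= ref_to
        if inside:
            q_out.append(qc)
            r_out.append(rc)
            if region.query_codons is not None and qc != GAP:
                codons_out.append(region.query_codons[3 * codon_idx : 3 * codon_idx + 3])
        if qc != GAP:
            codon_idx += 1
    return replace(
        region,
        query_aa="".join(q_out),
        ref_aa="".join(r_out),
        ref_first=ref_from,
        ref_last=ref_to,
        query_codons="".join(codons_out) if region.query_codons is not None else None,
        raw_score=0,
        bitscore=0.0,
    )


def overlap_score(region: AlignedRegion, ref_from: int, ref_to: int,
                  reference: SeqRecord, scheme: ScoringScheme) -> int:
    """Score of a region's residues over [ref_from, ref_to], realigned
    globally against the corresponding reference slice.

    Only residues aligned to reference positions take part: insertion
    columns are invisible to the reference interval being contested (and are
    removed by masking afterwards in any case), so charging their gap cost
    here would let a mismatch-ridden candidate beat one that merely bridges
    an intron-sized insertion.
    """
    piece = slice_region(region, ref_from, ref_to)
    ref_slice = reference.seq[ref_from - 1 : ref_to]
    return align(piece.aligned_query_residues(), ref_slice, scheme, mode="global").score


def resolve_overlap(
    a: AlignedRegion,
    b: AlignedRegion,
    reference: SeqRecord,
    scheme: ScoringScheme,
) -> list[AlignedRegion]:
    """Resolve one overlapping pair into up to three disjoint sliced parts.

    ``a`` must start at or before ``b``. Ties in the overlap realignment
    score keep the earlier region's segment (determinism)."""
    if sort_key(b) < sort_key(a):
        a, b = b, a
    ov_from = b.ref_first
    ov_to = min(a.ref_last, b.ref_last)
    if ov_from > ov_to:
        raise StitchError("resolve_overlap called on disjoint regions")
    score_a = overlap_score(a, ov_from, ov_to, reference, scheme)
    score_b = overlap_score(b, ov_from, ov_to, reference, scheme)
    winner = a if score_a >= score_b else b

    pieces: list[AlignedRegion] = []
    if a.ref_first < ov_from:
        pieces.append(slice_region(a, a.ref_first, ov_from - 1))
    pieces.append(slice_region(winner, ov_from, ov_to))
    right_src = a if a.ref_last > b.ref_last else b
    if right_src.ref_last > ov_to:
        pieces.append(slice_region(right_src, ov_to + 1, right_src.ref_last))
    return pieces


def _one_pass(
    regions: Sequence[AlignedRegion],
    reference: SeqRecord,
    scheme: ScoringScheme,
) -> list[AlignedRegion]:
    stack: list[AlignedRegion] = []
    for incoming in sorted(regions, key=sort_key):
        current = incoming
        if stack and current.ref_first <= stack[-1].ref_last and current.ref_last >= stack[-1].ref_first:
            top = stack.pop()
            stack.extend(resolve_overlap(top, current, reference, scheme))
        else:
            stack.append(current)
    return stack


def stitch(
    regions: Sequence[AlignedRegion],
    reference: SeqRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[AlignedRegion]:
    """Merge a reference's hits into an ordered non-overlapping region list.

    The union of covered reference positions is preserved exactly; only the
    choice of which region supplies each overlapping stretch is decided, by
    the overlap realignment score. The result is idempotent under
    re-stitching.
    """
    if not regions:
        return []
    ref_ids = {r.ref_id for r in regions}
    if len(ref_ids) != 1:
        raise StitchError(f"stitch received mixed reference ids: {sorted(ref_ids)}")
    for r in regions:
        if r.ref_last > len(reference.seq):
            raise StitchError(
                f"region [{r.ref_first}, {r.ref_last}] extends beyond reference "
                f"{reference.id!r} (length {len(reference.seq)})"
            )

    current = list(regions)
    previous_overlap = total_overlap(current)
    passes = 0
    while previous_overlap > 0:
        passes += 1
        if passes > MAX_PASSES:
            raise StitchError("stitching did not terminate")
        current = _one_pass(current, reference, scheme)
        overlap_now = total_overlap(current)
        if overlap_now >= previous_overlap:
            raise StitchError(
                f"stitching stalled: overlap {previous_overlap} -> {overlap_now}"
            )
        previous_overlap = overlap_now
    return sorted(current, key=sort_key)
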