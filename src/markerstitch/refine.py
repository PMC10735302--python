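"""Marker refinement: residue masking, sliding-window trimming, and the
final concatenation/realignment.

Masking removes residues that carry no phylogenetic signal or betray
noncoding sequence: query residues aligned to nothing in the reference
(insertion columns), the ambiguous amino-acid characters B, J, X and Z
(B = D or N, J = I or L, X = unknown, Z = E or Q), and stop codons ('*').
Stops and ambiguous characters can be retained on request. Removed query
positions become deletion columns, so reference coordinates never shift.

Trimming scans the realigned marker with a sliding window and computes, per
window, the gap-excluded distance 1 - identical/aligned. Aligned translated
nucleotide sequences can drag in noncoding stretches — many indels broken by
occasional chance matches — and those windows sit far from the reference.
The query residues of *non-identical* aligned columns that fall inside any
window whose distance exceeds the threshold are removed; identical residues
are never cut, so a single good match inside a bad neighbourhood survives.
This removal is idempotent and monotone in the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .pairwise import (
    GAP,
    PairwiseAlignment,
    ScoringScheme,
    DEFAULT_SCHEME,
    align,
    score_columns,
)
from .search import AlignedRegion
from .seqio import AMBIGUOUS_AA, SeqRecord

STOP = "*"


@dataclass(frozen=True)
class MaskPolicy:
    """Which residue classes to strip from stitched regions."""

    retain_stops: bool = False
    retain_ambiguous: bool = False
    ambiguous_set: frozenset[str] = AMBIGUOUS_AA  # {B, J, X, Z}

    def masked(self, residue: str) -> bool:
        if residue == STOP:
            return not self.retain_stops
        if residue in self.ambiguous_set:
            return not self.retain_ambiguous
        return False


@dataclass(frozen=True)
class TrimPolicy:
    """Sliding-window trimming parameters.

    ``window_size`` is in alignment columns; ``distance_threshold`` is the
    maximum tolerated gap-excluded distance (1 - identity) per window.
    """

    window_size: int = 15
    distance_threshold: float = 0.5
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0.0 <= self.distance_threshold <= 1.0):
            raise ValueError("distance_threshold must be in [0, 1]")


@dataclass
class StitchedMarker:
    """The final product for one reference: the stitched, masked, trimmed
    marker plus its realignment to the reference."""

    ref_id: str
    regions: list[AlignedRegion]
    final_aa: str
    final_nt: str | None
    final_alignment: PairwiseAlignment
    score: int  # realignment score of the concatenated sequence, pre-trim

    @property
    def query_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.regions:
            if r.query_id not in seen:
                seen.append(r.query_id)
        return seen


def mask(region: AlignedRegion, policy: MaskPolicy = MaskPolicy()) -> AlignedRegion:
    """Apply the masking policy to one region.

    Insertion columns (reference gap) are removed outright; masked query
    residues are replaced by deletion columns. Codon provenance follows the
    surviving residues. Idempotent.
    """
    q_out: list[str] = []
    r_out: list[str] = []
    codons: list[str] = []
    codon_idx = 0
    for qc, rc in zip(region.query_aa, region.ref_aa):
        consumed = qc != GAP
        if rc == GAP:
            pass  # unaligned residue: drop the whole column
        elif consumed and policy.masked(qc):
            q_out.append(GAP)
            r_out.append(rc)
        else:
            q_out.append(qc)
            r_out.append(rc)
            if region.query_codons is not None and consumed:
                codons.append(region.query_codons[3 * codon_idx : 3 * codon_idx + 3])
        if consumed:
            codon_idx += 1
    return replace(
        region,
        query_aa="".join(q_out),
        ref_aa="".join(r_out),
        query_codons="".join(codons) if region.query_codons is not None else None,
    )


def window_distance(q: str, r: str) -> float | None:
    """Gap-excluded distance of an aligned window; None if no aligned column."""
    aligned = 0
    identical = 0
    for qc, rc in zip(q, r):
        if qc != GAP and rc != GAP:
            aligned += 1
            if qc == rc:
                identical += 1
    if aligned == 0:
        return None
    return 1.0 - identical / aligned


def _failing_columns(q: str, r: str, policy: TrimPolicy) -> set[int]:
    n = len(q)
    w = min(policy.window_size, n)
    flagged: set[int] = set()
    for start in range(0, n - w + 1):
        d = window_distance(q[start : start + w], r[start : start + w])
        if d is not None and d > policy.distance_threshold:
            flagged.update(range(start, start + w))
    # only non-identical aligned columns are actually cut
    return {
        i for i in flagged
        if q[i] != GAP and r[i] != GAP and q[i] != r[i]
    }


def trim(aln: PairwiseAlignment, policy: TrimPolicy = TrimPolicy()) -> PairwiseAlignment:
    """Sliding-window trim of a query-vs-reference alignment.

    Windows of ``window_size`` columns slide one column at a time; where the
    gap-excluded distance of a window exceeds the threshold, the mismatching
    query residues inside it are cut (they become deletion columns).
    Insertion columns whose query residue is cut disappear entirely. With
    ``enabled=False`` the input is returned unchanged.
    """
    if not policy.enabled or len(aln) == 0:
        return aln
    q, r = aln.query_gapped, aln.ref_gapped
    cut = _failing_columns(q, r, policy)
    if not cut:
        return aln
    q_out: list[str] = []
    r_out: list[str] = []
    for i, (qc, rc) in enumerate(zip(q, r)):
        if i in cut:
            if rc == GAP:
                continue  # insertion column vanishes with its residue
            q_out.append(GAP)
            r_out.append(rc)
        else:
            q_out.append(qc)
            r_out.append(rc)
    trimmed = PairwiseAlignment("".join(q_out), "".join(r_out), 0, mode=aln.mode)
    trimmed.score = score_columns(trimmed)
    return trimmed


def finalize(
    regions: Sequence[AlignedRegion],
    reference: SeqRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    trim_policy: TrimPolicy = TrimPolicy(),
    mask_policy: MaskPolicy = MaskPolicy(),
) -> StitchedMarker | None:
    """Concatenate stitched regions, realign to the reference, and trim.

    ``regions`` must already be stitched (ordered, non-overlapping); masking
    is applied here so the concatenated sequence is clean. Returns ``None``
    when nothing survives (marker absent).
    """
    masked = [mask(r, mask_policy) for r in regions]
    concat_aa: list[str] = []
    concat_codons: list[str] = []
    have_codons = all(r.query_codons is not None for r in masked) and bool(masked)
    for r in masked:
        concat_aa.append(r.query_residues())
        if have_codons:
            concat_codons.append(r.query_codons or "")
    seq = "".join(concat_aa)
    if not seq:
        return None

    realignment = align(seq, reference.seq, scheme, mode="semi_global")

    # Trim with codon bookkeeping: walk the pre-trim realignment so that the
    # codon index tracks *every* original query residue, including cut ones.
    q, r = realignment.query_gapped, realignment.ref_gapped
    cut = _failing_columns(q, r, trim_policy) if trim_policy.enabled else set()
    codon_string = "".join(concat_codons) if have_codons else None
    q_out: list[str] = []
    r_out: list[str] = []
    final_aa_chars: list[str] = []
    final_codons: list[str] = []
    res_idx = 0
    for i, (qc, rc) in enumerate(zip(q, r)):
        consumed = qc != GAP
        if i in cut:
            if rc != GAP:  # cut residue becomes a deletion column
                q_out.append(GAP)
                r_out.append(rc)
        else:
            q_out.append(qc)
            r_out.append(rc)
            if consumed:
                final_aa_chars.append(qc)
                if codon_string is not None:
                    final_codons.append(codon_string[3 * res_idx : 3 * res_idx + 3])
        if consumed:
            res_idx += 1
    trimmed = PairwiseAlignment("".join(q_out), "".join(r_out), 0, mode=realignment.mode)
    trimmed.score = score_columns(trimmed)
    final_aa = "".join(final_aa_chars)
    if not final_aa:
        return None
    return StitchedMarker(
        ref_id=reference.id,
        regions=list(masked),
        final_aa=final_aa,
        final_nt="".join(final_codons) if codon_string is not None else None,
        final_alignment=trimmed,
        score=realignment.score,
    )
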