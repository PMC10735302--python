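"""Affine-gap pairwise amino-acid alignment.

The scoring convention follows BLAST: a gap of length L costs
``gap_open + L * gap_extend``, so under the default BLOSUM62 / 11 / 1 scheme
a length-1 gap costs 12. Three modes are supported:

``local``
    Smith–Waterman; score is never negative and an empty alignment (score 0)
    is a legal result for dissimilar sequences.
``global``
    Needleman–Wunsch with end gaps penalised.
``semi_global``
    Global alignment with free terminal gaps on both sequences ("overlap"
    alignment) — used when realigning a concatenated marker to its
    reference, where uncovered reference tails should not be penalised.

The dynamic programming itself is delegated to Biopython's C
``PairwiseAligner``; traceback ties are resolved by its fixed, deterministic
preference order, so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"


class AlignmentError(ValueError):
    """Raised for invalid alignments or residues outside the matrix alphabet."""


@lru_cache(maxsize=None)
def _load_builtin(name: str):
    return substitution_matrices.load(name)


def load_matrix(name_or_path: str):
    """Load a substitution matrix by built-in name (e.g. ``BLOSUM62``) or from
    an NCBI-format matrix file."""
    try:
        return _load_builtin(name_or_path)
    except FileNotFoundError:
        pass
    path = Path(name_or_path)
    if not path.exists():
        raise FileNotFoundError(
            f"{name_or_path!r} is neither a built-in substitution matrix nor an existing file"
        )
    return substitution_matrices.read(str(path))


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open`` and ``gap_extend`` are non-negative costs; a gap of length L
    costs ``gap_open + L * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_extend < 0 or self.gap_open < self.gap_extend:
            raise ValueError("require gap_open >= gap_extend >= 0")

    @property
    def matrix(self):
        return load_matrix(self.matrix_name)

    @property
    def alphabet(self) -> str:
        return str(self.matrix.alphabet)

    def pair_score(self, a: str, b: str) -> int:
        try:
            return int(self.matrix[a, b])
        except (KeyError, IndexError) as exc:
            raise AlignmentError(f"residue pair ({a!r},{b!r}) outside matrix alphabet") from exc

    def gap_cost(self, length: int) -> int:
        if length <= 0:
            return 0
        return self.gap_open + length * self.gap_extend


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class PairwiseAlignment:
    """Two gapped strings of equal length plus the score that produced them."""

    query_gapped: str
    ref_gapped: str
    score: int
    mode: str = "global"

    def __post_init__(self) -> None:
        if len(self.query_gapped) != len(self.ref_gapped):
            raise AlignmentError("gapped strings differ in length")
        for i, (q, r) in enumerate(zip(self.query_gapped, self.ref_gapped)):
            if q == GAP and r == GAP:
                raise AlignmentError(f"gap/gap column at position {i}")

    def __len__(self) -> int:
        return len(self.query_gapped)


def _validate_residues(seq: str, scheme: ScoringScheme, label: str) -> None:
    alpha = set(scheme.alphabet)
    for i, c in enumerate(seq):
        if c not in alpha:
            raise AlignmentError(f"{label} residue {c!r} at position {i} outside matrix alphabet")


@lru_cache(maxsize=32)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int, mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = load_matrix(matrix_name)
    a.open_gap_score = -(gap_open + gap_extend)
    a.extend_gap_score = -gap_extend
    if mode == "local":
        a.mode = "local"
    elif mode == "global":
        a.mode = "global"
    elif mode == "semi_global":
        a.mode = "global"
        try:  # Biopython >= 1.88 naming
            a.end_insertion_score = 0.0
            a.end_deletion_score = 0.0
        except AttributeError:
            a.target_end_gap_score = 0.0
            a.query_end_gap_score = 0.0
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return a


def _gapped_strings(alignment) -> tuple[str, str]:
    # Biopython's Alignment string slices [0]/[1] include gaps.
    return str(alignment[0]), str(alignment[1])


def align(query: str, ref: str, scheme: ScoringScheme = DEFAULT_SCHEME, mode: str = "global") -> PairwiseAlignment:
    """Optimal affine-gap alignment of ``query`` against ``ref``.

    Local mode may return an empty alignment with score 0 when no segment
    pair scores positively. Global/semi-global mode accepts empty inputs
    (the result is an all-gap alignment of the other sequence).
    """
    _validate_residues(query, scheme, "query")
    _validate_residues(ref, scheme, "ref")
    if not query and not ref:
        return PairwiseAlignment("", "", 0, mode=mode)
    if mode in ("global", "semi_global"):
        if not query:
            score = 0 if mode == "semi_global" else -scheme.gap_cost(len(ref))
            return PairwiseAlignment(GAP * len(ref), ref, score, mode=mode)
        if not ref:
            score = 0 if mode == "semi_global" else -scheme.gap_cost(len(query))
            return PairwiseAlignment(query, GAP * len(query), score, mode=mode)
    elif not query or not ref:
        return PairwiseAlignment("", "", 0, mode="local")

    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend, mode)
    results = aligner.align(query, ref)
    if mode == "local" and results.score <= 0:
        return PairwiseAlignment("", "", 0, mode="local")
    best = results[0]
    q, r = _gapped_strings(best)
    return PairwiseAlignment(q, r, int(results.score), mode=mode)


def align_with_coords(
    query: str, ref: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> tuple[PairwiseAlignment, tuple[int, int], tuple[int, int]]:
    """Local alignment plus the 0-based half-open coordinates of the aligned
    segment on query and ref. Returns ((0,0),(0,0)) spans for empty results."""
    _validate_residues(query, scheme, "query")
    _validate_residues(ref, scheme, "ref")
    if not query or not ref:
        return PairwiseAlignment("", "", 0, mode="local"), (0, 0), (0, 0)
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend, "local")
    results = aligner.align(query, ref)
    if results.score <= 0:
        return PairwiseAlignment("", "", 0, mode="local"), (0, 0), (0, 0)
    best = results[0]
    q, r = _gapped_strings(best)
    (qspan, rspan) = (
        (int(best.coordinates[0][0]), int(best.coordinates[0][-1])),
        (int(best.coordinates[1][0]), int(best.coordinates[1][-1])),
    )
    # coordinates rows are (target, query) in Biopython terms; target==our query
    return PairwiseAlignment(q, r, int(results.score), mode="local"), qspan, rspan


def score_columns(aln: PairwiseAlignment, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Recompute an alignment's score from its gapped strings.

    Serves as the invariant check that ``score`` is consistent with the
    scheme: column substitution scores minus affine gap costs, with terminal
    gap runs free in ``semi_global`` mode.
    """
    q, r = aln.query_gapped, aln.ref_gapped
    n = len(q)
    if n == 0:
        return 0
    # identify terminal gap runs (free under semi_global)
    lead = 0
    while lead < n and (q[lead] == GAP or r[lead] == GAP):
        lead += 1
    tail = n
    while tail > lead and (q[tail - 1] == GAP or r[tail - 1] == GAP):
        tail -= 1
    free_terminal = aln.mode == "semi_global"

    total = 0
    gap_len = 0
    for i in range(n):
        qc, rc = q[i], r[i]
        if qc == GAP and rc == GAP:
            raise AlignmentError(f"gap/gap column at position {i}")
        terminal = i < lead or i >= tail
        if qc == GAP or rc == GAP:
            if terminal and free_terminal:
                continue
            gap_len += 1
            # affine: charge open+extend on first gap column, extend after
            total -= scheme.gap_extend
            if gap_len == 1:
                total -= scheme.gap_open
        else:
            gap_len = 0
            total += scheme.pair_score(qc, rc)
        # a gap run ends when the *kind* of gap flips; handle by resetting
        # when next column's gap pattern differs
        if i + 1 < n and (qc == GAP or rc == GAP):
            nq, nr = q[i + 1], r[i + 1]
            same_kind = (qc == GAP and nq == GAP and nr != GAP) or (rc == GAP and nr == GAP and nq != GAP)
            if not same_kind:
                gap_len = 0
    return total
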