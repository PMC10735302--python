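"""Translated homology search: obtain per-reference hits.

Three routes produce the same :class:`AlignedRegion` objects:

* :func:`parse_tabular` — read an existing tabular result (the 12 canonical
  BLAST tabular columns extended with ``qframe``, ``qseq_translated`` and
  ``sseq``, so the aligned residue strings needed by stitching are present);
* :func:`run_external_search` — invoke an external translated aligner
  (``blastx`` from NCBI BLAST+, or ``diamond blastx``) and parse its output;
* :func:`builtin_search` — a self-contained six-frame translated local
  search built on :mod:`markerstitch.pairwise`, used when no external
  aligner is wanted. A shared-k-mer prefilter keeps it fast; each query
  frame is searched recursively (best local hit, then both flanks) so that
  several segment pairs per frame can be reported.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import seqio
from .pairwise import (
    GAP,
    AlignmentError,
    PairwiseAlignment,
    ScoringScheme,
    DEFAULT_SCHEME,
    align_with_coords,
    score_columns,
)
from .seqio import SeqRecord

logger = logging.getLogger(__name__)

TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qframe", "qseq_translated", "sseq",
]

FRAMESHIFT_CHARS = ("/", "\\")


class TabularFormatError(ValueError):
    """Raised for malformed tabular search results."""


@dataclass
class AlignedRegion:
    """One translated-search hit against a reference protein.

    ``query_aa``/``ref_aa`` are the aligned residue strings ('-' marks a
    deletion in the query / an insertion relative to the reference).
    ``ref_first``/``ref_last`` are 1-based inclusive reference coordinates.
    ``query_codons`` optionally records, for each non-gap query residue in
    order, its source codon (3 nt each, in translation orientation) so the
    final marker can be emitted as nucleotides.
    """

    query_id: str
    ref_id: str
    query_aa: str
    ref_aa: str
    ref_first: int
    ref_last: int
    frame: int
    bitscore: float = 0.0
    raw_score: int = 0
    query_codons: str | None = None

    def __post_init__(self) -> None:
        if len(self.query_aa) != len(self.ref_aa):
            raise AlignmentError(
                f"hit {self.query_id}->{self.ref_id}: aligned strings differ in length"
            )
        if not (1 <= self.ref_first <= self.ref_last):
            raise ValueError(
                f"hit {self.query_id}->{self.ref_id}: bad reference interval "
                f"[{self.ref_first}, {self.ref_last}]"
            )
        n_ref = sum(1 for c in self.ref_aa if c != GAP)
        if n_ref != self.ref_last - self.ref_first + 1:
            raise ValueError(
                f"hit {self.query_id}->{self.ref_id}: {n_ref} reference residues but "
                f"interval [{self.ref_first}, {self.ref_last}]"
            )
        for i, (q, r) in enumerate(zip(self.query_aa, self.ref_aa)):
            if q == GAP and r == GAP:
                raise AlignmentError(f"hit {self.query_id}->{self.ref_id}: gap/gap column {i}")
        if self.query_codons is not None:
            n_q = sum(1 for c in self.query_aa if c != GAP)
            if len(self.query_codons) != 3 * n_q:
                raise ValueError(
                    f"hit {self.query_id}->{self.ref_id}: codon provenance length mismatch"
                )

    @property
    def span(self) -> int:
        return self.ref_last - self.ref_first + 1

    def query_residues(self) -> str:
        return self.query_aa.replace(GAP, "")

    def aligned_query_residues(self) -> str:
        """Query residues in columns aligned to a reference position
        (insertion columns excluded)."""
        return "".join(q for q, r in zip(self.query_aa, self.ref_aa) if q != GAP and r != GAP)

    def compute_raw_score(self, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
        """Score of the aligned strings under the scheme (local convention:
        the segment carries no terminal gaps)."""
        return score_columns(
            PairwiseAlignment(self.query_aa, self.ref_aa, 0, mode="semi_global"), scheme
        )


def _anchor_bounds(q: str, r: str, min_run: int) -> tuple[int, int] | None:
    """First/last column indices such that both ends sit on ``min_run``
    consecutive identical aligned columns; None if no such run exists."""
    n = len(q)
    ident = [q[i] == r[i] and q[i] != GAP for i in range(n)]
    run = 0
    first = None
    for i in range(n):
        run = run + 1 if ident[i] else 0
        if run == min_run:
            first = i - min_run + 1
            break
    if first is None:
        return None
    run = 0
    for i in range(n - 1, -1, -1):
        run = run + 1 if ident[i] else 0
        if run == min_run:
            return first, i + min_run - 1
    raise AssertionError("unreachable")


def anchor_ends(region: AlignedRegion, min_run: int = 4,
                scheme: ScoringScheme = DEFAULT_SCHEME) -> AlignedRegion | None:
    """Trim a hit back to its outermost runs of ``min_run`` consecutive
    identical aligned columns; returns None if no such run exists.

    Local alignments happily extend a few columns past the true homologous
    segment whenever noncoding translation matches by chance (any terminal
    column of an optimal local alignment scores positively, so such
    extensions are invisible to the score). Requiring each end to sit on a
    short run of exact matches removes those chance tails — and discards
    hits that are chance similarity throughout.
    """
    if min_run <= 0:
        return region
    q, r = region.query_aa, region.ref_aa
    n = len(q)
    bounds = _anchor_bounds(q, r, min_run)
    if bounds is None:
        return None
    first, last = bounds
    if first == 0 and last == n - 1:
        return region
    # count reference/query positions consumed by the trimmed flanks
    ref_cut_left = sum(1 for i in range(first) if r[i] != GAP)
    ref_cut_right = sum(1 for i in range(last + 1, n) if r[i] != GAP)
    q_cut_left = sum(1 for i in range(first) if q[i] != GAP)
    q_keep = sum(1 for i in range(first, last + 1) if q[i] != GAP)
    codons = region.query_codons
    if codons is not None:
        codons = codons[3 * q_cut_left : 3 * (q_cut_left + q_keep)]
    trimmed = replace(
        region,
        query_aa=q[first : last + 1],
        ref_aa=r[first : last + 1],
        ref_first=region.ref_first + ref_cut_left,
        ref_last=region.ref_last - ref_cut_right,
        query_codons=codons,
    )
    trimmed.raw_score = trimmed.compute_raw_score(scheme)
    return trimmed


def group_by_ref(regions: Iterable[AlignedRegion]) -> dict[str, list[AlignedRegion]]:
    grouped: dict[str, list[AlignedRegion]] = defaultdict(list)
    for region in regions:
        grouped[region.ref_id].append(region)
    return dict(grouped)


def parse_tabular(
    path: str | Path,
    references: Sequence[SeqRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    queries: Sequence[SeqRecord] | None = None,
) -> dict[str, list[AlignedRegion]]:
    """Parse a tabular search result into regions grouped by reference id.

    The file must carry the 15-column dialect in :data:`TABULAR_COLUMNS`
    (TSV, no header, ``#`` comment lines ignored). Rows whose aligned
    strings contain frameshift characters are dropped with a warning rather
    than fabricating residues. When ``queries`` is given, codon provenance
    is reconstructed from ``qstart``/``qend``/``qframe``.
    """
    ref_len = {r.id: len(r.seq) for r in references}
    query_seq = {q.id: q.seq for q in queries} if queries is not None else {}
    grouped: dict[str, list[AlignedRegion]] = defaultdict(list)
    with seqio._open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(TABULAR_COLUMNS):
                raise TabularFormatError(
                    f"{path}:{lineno}: expected {len(TABULAR_COLUMNS)} columns "
                    f"({' '.join(TABULAR_COLUMNS)}), got {len(fields)}"
                )
            row = dict(zip(TABULAR_COLUMNS, fields))
            qid, sid = row["qseqid"], row["sseqid"]
            if sid not in ref_len:
                raise TabularFormatError(f"{path}:{lineno}: unknown reference id {sid!r}")
            qseq, sseq = row["qseq_translated"], row["sseq"]
            if any(c in qseq or c in sseq for c in FRAMESHIFT_CHARS):
                logger.warning(
                    "%s:%d: dropping hit %s->%s containing frameshift characters",
                    path, lineno, qid, sid,
                )
                continue
            try:
                sstart, send = int(row["sstart"]), int(row["send"])
                frame = int(row["qframe"])
                bitscore = float(row["bitscore"])
                qstart, qend = int(row["qstart"]), int(row["qend"])
            except ValueError as exc:
                raise TabularFormatError(f"{path}:{lineno}: {exc}") from exc
            if sstart > send:
                raise TabularFormatError(
                    f"{path}:{lineno}: sstart {sstart} > send {send} (protein subject "
                    "coordinates must be ascending)"
                )
            if send > ref_len[sid]:
                raise TabularFormatError(
                    f"{path}:{lineno}: send {send} beyond reference {sid!r} "
                    f"length {ref_len[sid]}"
                )
            codons = None
            if qid in query_seq:
                codons = _codons_from_coords(query_seq[qid], qstart, qend, frame, qseq)
            region = AlignedRegion(
                query_id=qid, ref_id=sid, query_aa=qseq, ref_aa=sseq,
                ref_first=sstart, ref_last=send, frame=frame,
                bitscore=bitscore, query_codons=codons,
            )
            region.raw_score = region.compute_raw_score(scheme)
            grouped[sid].append(region)
    return dict(grouped)


def _codons_from_coords(query_nt: str, qstart: int, qend: int, frame: int, query_aa: str) -> str | None:
    """Reconstruct the codon string behind an aligned translated query.

    ``qstart``/``qend`` are 1-based nucleotide coordinates on the original
    query strand (BLAST convention: qstart > qend on the minus strand)."""
    n_res = sum(1 for c in query_aa if c != GAP)
    if frame >= 0 and qstart <= qend:
        segment = query_nt[qstart - 1 : qend]
    else:
        lo, hi = min(qstart, qend), max(qstart, qend)
        segment = seqio.revcomp(query_nt[lo - 1 : hi])
    if len(segment) != 3 * n_res:
        logger.warning("codon reconstruction failed for a hit (len %d vs %d residues)", len(segment), n_res)
        return None
    return segment


def write_tabular(regions: Iterable[AlignedRegion], path: str | Path) -> Path:
    """Write regions in the 15-column tabular dialect (round-trips with
    :func:`parse_tabular` except codon provenance)."""
    path = Path(path)
    with open(path, "wt") as handle:
        for r in regions:
            cols = sum(1 for q, s in zip(r.query_aa, r.ref_aa) if q != GAP and s != GAP)
            matches = sum(
                1 for q, s in zip(r.query_aa, r.ref_aa) if q != GAP and s != GAP and q == s
            )
            mismatch = cols - matches
            gapopen = 0
            prev_gap = False
            for q, s in zip(r.query_aa, r.ref_aa):
                is_gap = q == GAP or s == GAP
                if is_gap and not prev_gap:
                    gapopen += 1
                prev_gap = is_gap
            pident = 100.0 * matches / cols if cols else 0.0
            handle.write(
                "\t".join(
                    str(v)
                    for v in [
                        r.query_id, r.ref_id, f"{pident:.1f}", len(r.query_aa), mismatch,
                        gapopen, 0, 0, r.ref_first, r.ref_last, "0.0", f"{r.bitscore:.1f}",
                        r.frame, r.query_aa, r.ref_aa,
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# External aligner
# ---------------------------------------------------------------------------

_OUTFMT = "6 qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore qframe qseq sseq"


def run_external_search(
    query_path: str | Path,
    reference_fasta: str | Path,
    out_dir: str | Path,
    engine: str = "blastx",
    extra_options: Sequence[str] = (),
    masking: int = 0,
) -> Path:
    """Run an external translated search and return the tabular output path.

    ``engine`` is ``blastx`` (NCBI BLAST+) or ``diamond``. The database is
    built next to the output and kept for reuse; the command lines and exit
    status are logged. The query-side low-complexity masking is off by
    default (``masking=0``), which empirically raises query coverage for
    marker mining.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / "hits.tsv"
    if engine == "blastx":
        exe, makedb = "blastx", "makeblastdb"
        if shutil.which(exe) is None or shutil.which(makedb) is None:
            raise EnvironmentError(
                "blastx/makeblastdb not found on PATH; install NCBI BLAST+ "
                "or use the built-in search"
            )
        db = out_dir / "refdb"
        cmd_db = [makedb, "-in", str(reference_fasta), "-dbtype", "prot", "-out", str(db)]
        _run_logged(cmd_db)
        cmd = [
            exe, "-query", str(query_path), "-db", str(db),
            "-outfmt", _OUTFMT, "-out", str(out_path),
            "-seg", "no" if masking == 0 else "yes",
        ]
        cmd += list(extra_options)
        _run_logged(cmd)
    elif engine == "diamond":
        if shutil.which("diamond") is None:
            raise EnvironmentError(
                "diamond not found on PATH; install DIAMOND or use engine='blastx' "
                "or the built-in search"
            )
        db = out_dir / "refdb.dmnd"
        _run_logged(["diamond", "makedb", "--in", str(reference_fasta), "--db", str(db)])
        cmd = [
            "diamond", "blastx", "--query", str(query_path), "--db", str(db),
            "--out", str(out_path), "--outfmt", *_OUTFMT.split()[1:],
            "--masking", str(masking),
        ]
        cmd += list(extra_options)
        _run_logged(cmd)
    else:
        raise ValueError(f"unknown search engine {engine!r}")
    return out_path


def _run_logged(cmd: list[str]) -> None:
    logger.info("running: %s", " ".join(cmd))
    proc = subprocess.run(cmd, capture_output=True, text=True)
    logger.info("exit status %d", proc.returncode)
    if proc.returncode != 0:
        raise RuntimeError(
            f"external command failed ({proc.returncode}): {' '.join(cmd)}\n{proc.stderr}"
        )


# ---------------------------------------------------------------------------
# Built-in six-frame search
# ---------------------------------------------------------------------------

_KMER = 5


def _kmer_index(references: Sequence[SeqRecord]) -> dict[str, set[str]]:
    index: dict[str, set[str]] = defaultdict(set)
    for ref in references:
        s = ref.seq
        for i in range(len(s) - _KMER + 1):
            index[s[i : i + _KMER]].add(ref.id)
    return index


def _candidate_refs(frame_aa: str, index: Mapping[str, set[str]]) -> set[str]:
    hits: set[str] = set()
    for i in range(len(frame_aa) - _KMER + 1):
        ids = index.get(frame_aa[i : i + _KMER])
        if ids:
            hits |= ids
    return hits


def _frame_hits(
    query: SeqRecord,
    frame: int,
    frame_aa: str,
    ref: SeqRecord,
    scheme: ScoringScheme,
    min_score: int,
    anchor: int,
) -> list[AlignedRegion]:
    """All non-overlapping local hits of one translated frame against one
    reference: best hit, then recurse into the flanking segments.

    With ``anchor`` > 0 each raw local alignment is trimmed back to ends
    anchored on that many consecutive identities and then re-extended
    outwards over exact matches only. The optimal local path sometimes drags
    a homologous boundary residue into a chance gapped extension; trimming
    to anchors and re-extending gap-free restores such residues without
    readmitting the chance tail.
    """
    hits: list[AlignedRegion] = []

    def emit(aln, q0: int, ref_first: int) -> None:
        q, r = aln.query_gapped, aln.ref_gapped
        score = aln.score
        if anchor > 0:
            bounds = _anchor_bounds(q, r, anchor)
            if bounds is None:
                return
            first, last = bounds
            q0 += sum(1 for i in range(first) if q[i] != GAP)
            ref_first += sum(1 for i in range(first) if r[i] != GAP)
            q, r = q[first : last + 1], r[first : last + 1]
            # exact gap-free re-extension at both ends
            while q0 > 0 and ref_first > 1 and frame_aa[q0 - 1] == ref.seq[ref_first - 2]:
                q0 -= 1
                ref_first -= 1
                q, r = frame_aa[q0] + q, ref.seq[ref_first - 1] + r
            q_end = q0 + sum(1 for c in q if c != GAP)
            ref_last = ref_first + sum(1 for c in r if c != GAP) - 1
            while (
                q_end < len(frame_aa)
                and ref_last < len(ref.seq)
                and frame_aa[q_end] == ref.seq[ref_last]
            ):
                q, r = q + frame_aa[q_end], r + ref.seq[ref_last]
                q_end += 1
                ref_last += 1
        n_res = sum(1 for c in q if c != GAP)
        region = AlignedRegion(
            query_id=query.id, ref_id=ref.id,
            query_aa=q, ref_aa=r,
            ref_first=ref_first,
            ref_last=ref_first + sum(1 for c in r if c != GAP) - 1,
            frame=frame,
            bitscore=float(score),
            query_codons=_codons_for_span(query.seq, frame, q0, n_res),
        )
        region.raw_score = region.compute_raw_score(scheme)
        hits.append(region)

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < _KMER:
            return
        sub = frame_aa[lo:hi]
        aln, qspan, rspan = align_with_coords(sub, ref.seq, scheme)
        if aln.score < min_score or len(aln) == 0:
            return
        emit(aln, lo + qspan[0], rspan[0] + 1)
        recurse(lo, lo + qspan[0])
        recurse(lo + qspan[1], hi)

    recurse(0, len(frame_aa))
    return hits


def _codons_for_span(query_nt: str, frame: int, aa_offset: int, n_res: int) -> str:
    strand_nt = query_nt if frame > 0 else seqio.revcomp(query_nt)
    start = (abs(frame) - 1) + 3 * aa_offset
    return strand_nt[start : start + 3 * n_res]


def builtin_search(
    queries: Sequence[SeqRecord],
    references: Sequence[SeqRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_score: int = 100,
    anchor: int = 4,
) -> dict[str, list[AlignedRegion]]:
    """Six-frame translated local search of nucleotide queries against
    protein references.

    Every query is translated in all six frames; frames sharing at least one
    exact 5-mer with a reference are aligned locally under ``scheme`` and
    alignments with raw score >= ``min_score`` are emitted, with ends
    anchored on ``anchor`` consecutive identities (0 disables anchoring).
    The default cutoff (raw 100 ≈ 42 bits under BLOSUM62/11/1) keeps random
    matches out at marker-mining search-space sizes while retaining any
    faithful exon piece of roughly 25 residues or more.
    """
    index = _kmer_index(references)
    ref_by_id = {r.id: r for r in references}
    grouped: dict[str, list[AlignedRegion]] = defaultdict(list)
    for query in queries:
        for frame in (1, 2, 3, -1, -2, -3):
            frame_aa = seqio.translate(query.seq, frame)
            if len(frame_aa) < _KMER:
                continue
            for ref_id in sorted(_candidate_refs(frame_aa, index)):
                hits = _frame_hits(
                    query, frame, frame_aa, ref_by_id[ref_id], scheme, min_score, anchor
                )
                grouped[ref_id].extend(hits)
    return dict(grouped)
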