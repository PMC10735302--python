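"""Synthetic genome-skimming fixtures with known ground truth.

The generator emulates the situation the stitcher is built for: a set of
single-copy reference proteins; for each, a gene whose coding sequence is
the deterministic back-translation of the protein, interrupted by random
GT..AG introns ("genes in pieces"); optional per-site substitution noise;
and fragmentation into short, overlapping contigs of configurable length
(low N50), each on a random strand. A truth table records, per fragment,
the reference residue interval whose codons it fully contains and the
reading frame of the first such codon.

Paired short reads can be simulated from the contigs or genes, and read
pairs can be randomly subsampled while preserving mate pairing — the usual
way of titrating sequencing coverage in benchmark designs.

All randomness flows from ``spec.seed``; identical specs give byte-identical
outputs. What the generator does *not* emulate: quality-correlated error
profiles, indels, repeats/paralogy, and real intron length/site biases —
recovery rates measured on these fixtures are an upper bound for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqio
from .seqio import SeqRecord

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# alphabetically first codon per residue (deterministic back-translation)
_CODON_TABLE = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGA", "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "AGC", "T": "ACA", "V": "GTA", "W": "TGG", "Y": "TAC",
}

TRUTH_COLUMNS = ["fragment_id", "ref_id", "ref_first", "ref_last", "frame"]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic data set."""

    n_markers: int = 50
    marker_length_range: tuple[int, int] = (120, 240)  # residues
    intron_count_range: tuple[int, int] = (1, 3)
    intron_length_range: tuple[int, int] = (60, 180)  # nt
    min_exon_codons: int = 30
    fragment_length_range: tuple[int, int] = (400, 500)  # nt
    fragment_overlap: int = 200  # nt
    codon_aligned_introns: bool = True
    substitution_rate: float = 0.0
    read_length: int = 100
    insert_size: int = 300
    coverage: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.marker_length_range, self.intron_count_range,
            self.intron_length_range, self.fragment_length_range,
        ):
            if lo > hi or lo < 0:
                raise ValueError(f"empty or negative range ({lo}, {hi})")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.fragment_overlap >= self.fragment_length_range[0]:
            raise ValueError("fragment_overlap must be smaller than the shortest fragment")
        min_len = (self.intron_count_range[1] + 1) * self.min_exon_codons
        if self.marker_length_range[0] < min_len:
            raise ValueError(
                f"marker_length_range too short for {self.intron_count_range[1]} introns "
                f"with {self.min_exon_codons}-codon exons (need >= {min_len})"
            )


@dataclass
class GeneTruth:
    ref_id: str
    protein: str
    gene: str  # exons + introns, plus strand
    codon_starts: list[int]  # gene position of each reference codon


@dataclass
class FixtureSet:
    references: list[SeqRecord]
    contigs: list[SeqRecord]
    truth: pd.DataFrame
    genes: dict[str, GeneTruth]


def back_translate(protein: str) -> str:
    return "".join(_CODON_TABLE[aa] for aa in protein)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(list(_AA20), size=length - 1)
    return "M" + "".join(body)


def _random_intron(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list("ACGT"), size=max(length - 4, 0)))
    return "GT" + body + "AG"


def _intron_positions(
    rng: np.random.Generator, n_codons: int, k: int, min_exon: int
) -> list[int]:
    """k cut points (in codons) splitting the CDS into exons of >= min_exon
    codons each; uniform over admissible compositions."""
    if k == 0:
        return []
    slack = n_codons - (k + 1) * min_exon
    extras = np.sort(rng.integers(0, slack + 1, size=k))
    return [min_exon * (i + 1) + int(extras[i]) for i in range(k)]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [c for c in "ACGT" if c != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def generate_markers(spec: FixtureSpec, out_dir: str | Path | None = None) -> FixtureSet:
    """Generate reference proteins, fragmented genomic contigs and the truth
    table. When ``out_dir`` is given, writes ``references.fasta``,
    ``contigs.fasta`` and ``truth.tsv`` there."""
    rng = np.random.default_rng(spec.seed)
    references: list[SeqRecord] = []
    contigs: list[SeqRecord] = []
    truth_rows: list[dict] = []
    genes: dict[str, GeneTruth] = {}

    for m in range(spec.n_markers):
        ref_id = f"ref{m:04d}"
        length = int(rng.integers(spec.marker_length_range[0], spec.marker_length_range[1] + 1))
        protein = _random_protein(rng, length)
        cds = back_translate(protein)
        k = int(rng.integers(spec.intron_count_range[0], spec.intron_count_range[1] + 1))
        cuts = _intron_positions(rng, length, k, spec.min_exon_codons)

        gene_parts: list[str] = []
        codon_starts: list[int] = []
        pos = 0
        prev_cut = 0
        for cut in cuts + [length]:
            exon = cds[3 * prev_cut : 3 * cut]
            for c in range(prev_cut, cut):
                codon_starts.append(pos + 3 * (c - prev_cut))
            gene_parts.append(exon)
            pos += len(exon)
            if cut != length:
                ilen = int(rng.integers(spec.intron_length_range[0], spec.intron_length_range[1] + 1))
                if not spec.codon_aligned_introns:
                    ilen += int(rng.integers(0, 3))
                intron = _random_intron(rng, ilen)
                gene_parts.append(intron)
                pos += len(intron)
            prev_cut = cut
        gene = _mutate(rng, "".join(gene_parts), spec.substitution_rate)
        references.append(SeqRecord(id=ref_id, seq=protein, alphabet=seqio.AMINO_ACID))
        genes[ref_id] = GeneTruth(ref_id=ref_id, protein=protein, gene=gene, codon_starts=codon_starts)

        # fragmentation into overlapping contigs, random strand each
        start = 0
        frag_no = 0
        glen = len(gene)
        while start < glen:
            flen = int(rng.integers(spec.fragment_length_range[0], spec.fragment_length_range[1] + 1))
            end = min(start + flen, glen)
            frag_nt = gene[start:end]
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = frag_nt if strand == "+" else seqio.revcomp(frag_nt)
            frag_id = f"{ref_id}_frag{frag_no}"
            contigs.append(SeqRecord(id=frag_id, seq=oriented, alphabet=seqio.NUCLEOTIDE))

            inside = [
                i for i, c in enumerate(codon_starts) if c >= start and c + 3 <= end
            ]
            if inside:
                first_codon = codon_starts[inside[0]]
                # frame of the first fully contained codon, in the search
                # convention: negative frames translate the reverse
                # complement of the oriented fragment, i.e. the original
                # plus-strand slice, so the offset formula is shared.
                frame = (first_codon - start) % 3 + 1
                if strand == "-":
                    frame = -frame
                truth_rows.append(
                    {
                        "fragment_id": frag_id, "ref_id": ref_id,
                        "ref_first": inside[0] + 1, "ref_last": inside[-1] + 1,
                        "frame": frame,
                    }
                )
            frag_no += 1
            if end == glen:
                break
            start = end - spec.fragment_overlap

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    out = FixtureSet(references=references, contigs=contigs, truth=truth, genes=genes)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta(references, out_dir / "references.fasta")
        seqio.write_fasta(contigs, out_dir / "contigs.fasta")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return out


def simulate_reads(
    templates: list[SeqRecord],
    spec: FixtureSpec,
    out_r1: str | Path,
    out_r2: str | Path,
) -> tuple[Path, Path]:
    """Simulate paired-end reads at ``spec.coverage`` over the templates.

    Pair count = coverage * total_length / (2 * read_length); templates are
    sampled proportional to length, inserts are uniform within ±10% of
    ``insert_size`` (clipped to fit), and per-base substitution errors occur
    at ``spec.substitution_rate``. Templates shorter than the read length
    are skipped with a warning.
    """
    import logging

    rng = np.random.default_rng(spec.seed + 1)
    usable = [t for t in templates if len(t.seq) >= spec.read_length]
    for t in templates:
        if len(t.seq) < spec.read_length:
            logging.getLogger(__name__).warning(
                "template %s shorter than read length; skipped", t.id
            )
    if not usable:
        raise ValueError("no template is at least one read long")
    lengths = np.array([len(t.seq) for t in usable], dtype=float)
    total = lengths.sum()
    n_pairs = int(round(spec.coverage * total / (2 * spec.read_length)))
    weights = lengths / total

    r1: list[SeqRecord] = []
    r2: list[SeqRecord] = []
    for i in range(n_pairs):
        t = usable[int(rng.choice(len(usable), p=weights))]
        max_insert = min(len(t.seq), int(round(spec.insert_size * 1.1)))
        min_insert = min(max_insert, max(spec.read_length, int(round(spec.insert_size * 0.9))))
        insert = int(rng.integers(min_insert, max_insert + 1))
        start = int(rng.integers(0, len(t.seq) - insert + 1))
        fragment = t.seq[start : start + insert]
        fwd = fragment[: spec.read_length]
        rev = seqio.revcomp(fragment[-spec.read_length :])
        r1.append(SeqRecord(id=f"pair{i}/1", seq=_mutate(rng, fwd, spec.substitution_rate)))
        r2.append(SeqRecord(id=f"pair{i}/2", seq=_mutate(rng, rev, spec.substitution_rate)))
    return seqio.write_fastq(r1, out_r1), seqio.write_fastq(r2, out_r2)


def subsample_pairs(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    fraction: float,
    seed: int,
    out_r1: str | Path,
    out_r2: str | Path,
) -> tuple[Path, Path]:
    """Randomly retain each read pair with probability ``fraction``.

    Mate pairing is preserved line-for-line; the two inputs must hold the
    same number of records. Deterministic under ``seed``.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    reads1 = seqio.read_fastq(fastq_r1)
    reads2 = seqio.read_fastq(fastq_r2)
    if len(reads1) != len(reads2):
        raise ValueError(
            f"unpaired inputs: {len(reads1)} records in {fastq_r1} vs "
            f"{len(reads2)} in {fastq_r2}"
        )
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads1)) < fraction
    kept1 = [r for r, k in zip(reads1, keep) if k]
    kept2 = [r for r, k in zip(reads2, keep) if k]
    return seqio.write_fastq(kept1, out_r1), seqio.write_fastq(kept2, out_r2)
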