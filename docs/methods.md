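# Methods

`markerstitch` mines protein-coding phylogenetic markers from fragmented
nucleotide data (low-N50 assemblies or raw reads) by aligning translated
query sequences against a set of reference proteins — typically universal
single-copy orthologs (USCOs) — and stitching the resulting hits, guided by
each reference, into one continuous marker sequence per reference. This
note records the model, the parameters that matter, and the design choices
made where more than one reasonable construction existed.

## Pipeline model

A run proceeds through six stages:

1. **Pooling.** All reference protein FASTA files are concatenated into one
   pool with globally unique identifiers; query contigs may contribute hits
   to any reference.
2. **Translated search.** Hits are obtained either from an external
   BLASTX-style aligner (NCBI `blastx` or `diamond blastx`, tabular output
   with explicit aligned sequence columns), from a reusable tabular file of
   a previous run, or from the built-in six-frame translated local search.
   Each hit is an `AlignedRegion`: aligned query/reference residue strings,
   1-based inclusive reference interval, reading frame, and (when the
   nucleotide queries are at hand) the source codon of every query residue,
   so markers can be emitted as nucleotides codon-for-residue.
3. **Hit stitching.** Per reference, overlapping hits are merged by a stack
   algorithm into an ordered, non-overlapping tiling (below).
4. **Masking.** Unaligned query residues (insertion columns), the ambiguous
   amino acids B (D/N), J (I/L), X (unknown) and Z (E/Q), and stop codons
   `*` are removed; stops and ambiguous residues can be retained with
   `--retain-stops` / `--retain-ambiguous`. Removed residues become
   deletion columns so reference coordinates never shift.
5. **Trimming.** The concatenated marker is realigned to the reference and
   a sliding window removes residues in stretches whose distance to the
   reference is too high — the signature of noncoding sequence dragged into
   a translated alignment (below).
6. **Reporting.** Per-reference statistics and an aggregate summary.

## Scoring

Alignments are scored with a substitution matrix (BLOSUM62 by default;
any built-in Biopython matrix or an NCBI-format file may be substituted)
and affine gap penalties, default gap open 11 and gap extend 1 in the
BLAST convention: a gap of length L costs `open + L·extend`, so a single
residue gap costs 12. Gap penalties outside the matrix's customary range
are accepted with a warning rather than rejected, since no principled
numeric bound exists for arbitrary matrices.

Three alignment modes are used: *local* (Smith–Waterman) for the search,
*global* (Needleman–Wunsch) for overlap comparison on a fixed reference
slice, and *semi-global* (terminal gaps free on both sequences) for the
final realignment of a marker to its reference, where uncovered reference
tails must not be penalised. The dynamic programming is Biopython's C
`PairwiseAligner`; its first optimal traceback is deterministic, so
repeated runs are bit-identical. The test suite carries an independent
pure-Python Gotoh implementation as an oracle for all three modes.

## Hit stitching

Hits for one reference are sorted by where they align on the reference
(start ascending; ties: longer region first, then query id) and pushed onto
a stack one at a time. When the incoming region overlaps the region on top
of the stack, the top is popped and the two candidates are realigned *only
over the reference interval in which they overlap*; the higher-scoring
candidate keeps the overlap, and up to three sliced parts return to the
stack: the flank preceding the overlap (from the earlier region), the
winning overlap segment, and the flank following it (from whichever region
extends further right). A region contained inside another is handled as a
degenerate overlap — the outer region either survives unchanged or is split
around the inner region's winning segment. Because a later region can reach
past its immediate predecessor, passes repeat until no overlaps remain;
each pass strictly reduces the total pairwise overlap (asserted at run
time), which guarantees termination.

Three deliberate choices:

* **Overlap scoring excludes insertion columns.** The comparison asks which
  candidate better explains the contested reference slice. Residues in
  insertion columns do not align to any position of that slice, and the
  masking stage removes them regardless of the outcome; charging their gap
  cost would let a mismatch-ridden candidate outscore one that merely
  bridges an intron-sized insertion. The score compared is therefore the
  global alignment of each candidate's reference-aligned residues against
  the slice.
* **Slicing never rewrites residues.** The realignment decides the winner
  only; the winning segment is cut from the original aligned strings (and
  codon provenance), with insertion columns travelling with the reference
  position they follow.
* **Ties keep the earlier region** (lower start, then lexicographically
  smaller query id), for determinism.

Greedy per-overlap resolution is provably score-optimal when overlap
decisions do not interact — the generic case of contigs tiling a reference,
where region *i* overlaps only region *i+1*. When three regions share a
common position, a later overlap can re-decide a sub-interval of an earlier
one and greedy resolution is no longer guaranteed optimal; the algorithm is
kept greedy (simple, fast, and the winner-optimality, coverage-preservation
and termination invariants still hold), and the exhaustive-enumeration
oracle in the test suite therefore generates chain-overlap geometries,
while mutually-overlapping triples are exercised by the invariant tests.

## Hit-end anchoring

An optimal local alignment always ends on positively scoring columns, so it
happily extends a few columns past a true exon boundary whenever the
adjacent noncoding translation matches by chance — and such tails are
invisible to any score-based criterion. Two consequences were observed on
synthetic data: chance mismatches planted at hit ends win contested
intervals when packaged with a strong exact flank, and occasionally the
optimal path drags a true boundary residue into a gapped chance extension.
Hits are therefore trimmed back to ends anchored on a run of identical
aligned columns (`anchor_identities`, default 4; 0 disables), and the
built-in search — which knows the translated frame context — then
re-extends each end outwards over exact matches only, gap-free. Anchoring
also discards hits that are chance similarity throughout. For distant
references the default is mild: at 85% identity an anchor run is found
within one or two columns of the true end. Hits parsed from external
aligners are anchored in the pipeline with the same parameter.

## Sliding-window trimming

After realignment, windows of `window_size` alignment columns (default 15)
slide one column at a time; a window's distance is `1 − identical/aligned`
over its non-gap columns (gap-excluded identity — all-gap windows carry no
information and no vote). Wherever a window's distance exceeds
`distance_threshold` (default 0.5, strictly above), the *mismatching*
residues inside it are cut; identical residues are never cut, so a single
good match inside a bad neighbourhood survives. Cut residues become
deletion columns against the reference; insertion columns vanish with their
residue. This removal rule is idempotent (removing mismatches only lowers
every window's distance) and monotone in the threshold, and it removes a
planted zero-identity block exactly while leaving perfect flanks intact —
the behaviour that motivated the window design. Trimming can be disabled
wholesale (`--no-trim`); a threshold of 1.0 keeps everything.

The defaults (15 columns, 0.5) are package choices: the window must be wide
enough that a single mismatch cannot condemn its neighbourhood (at width 15
a window fails only when more than half its aligned columns disagree) and
narrow enough to resolve intron-sized noncoding intrusions, which at
typical intron lengths translate to well over 15 residues.

## Statistics

Per reference: reference length, recovered length, matches, mismatches,
deletions (reference-consuming gap columns *within* the alignment span —
terminal uncovered tails count against coverage only, keeping the deletion
and coverage variables non-redundant), query coverage
`100·aligned/reference_length`, and gap-excluded identity
`100·matches/(matches+mismatches)`. The aggregate reports mean, min,
median (midpoint convention for even counts) and max per variable, plus a
combined accuracy/completeness measure computed over totals:

    100 · (Σmatches / Σaligned) · (Σrecovered_length / Σreference_length)

i.e. percent identical matches relative to *all* reference positions,
aligned or not — 95.9% identity at 92.2% coverage gives 88.4.

## Synthetic data generator

The generator emulates the genome-skimming setting with exact ground truth:
random reference proteins (120–240 residues, methionine start); coding
sequences produced by deterministic back-translation (alphabetically first
codon per residue); 1–3 introns per gene (GT…AG, 60–180 nt) inserted at
codon boundaries with every exon at least 30 codons; optional uniform
per-site substitution noise; fragmentation into overlapping contigs
(400–500 nt, 200 nt overlap, random strand per fragment) emulating a
low-N50 assembly. The 200 nt overlap guarantees that every coding position
sits with ≥100 nt of context inside some fragment, hence inside an exact
exon piece of at least ~27 codons — comfortably above the built-in search's
default raw-score cutoff of 100 (≈42 bits), which in turn is high enough
that random intron translation essentially never qualifies at marker-mining
search-space sizes. Paired-end reads (100 nt, insert 300±10%) can be
simulated at a chosen coverage, and read pairs can be randomly subsampled
with mate pairing preserved. In read-based runs a hit can never exceed the
read length (33 codons at 100 nt), so the search cutoff should be lowered
accordingly (e.g. `--min-score 60`); coverage saturates with sequencing
depth as read boundaries leave short sub-threshold pieces at exon edges.

What the fixtures do **not** emulate: quality-correlated or indel errors,
repeats and paralogy (hence no chimera risk), biased codon usage, or
realistic intron site/length distributions. Perfect recovery on error-free
fixtures demonstrates the correctness of the stitching machinery, not the
field performance on diverged references; the substitution-noise setting
probes robustness but still underestimates real-data difficulty.

## Problem sizes and determinism

The test suite runs the full pipeline on 200 error-free intron-bearing
genes (recovering 200/200 markers at 100% identity and coverage, a few
seconds on one CPU), checks the stack algorithm against exhaustive overlap
enumeration on 1,000 random small instances (references ≤40 residues, ≤3
regions), and the aligner against the Gotoh oracle on hundreds of random
pairs of ≤12 residues. All randomness is seeded; property tests are
derandomised. Pipeline outputs are byte-identical across reruns with the
same configuration and seed (external-aligner runs depend on the external
binary's version).

## Known limitations

* Frameshift-aware stitching is not attempted: hits whose aligned strings
  contain frameshift characters from an external aligner are dropped with a
  warning rather than interpreted.
* Chimera formation from paralogous references is possible by construction
  (any reference-guided stitcher shares this); near-universal single-copy
  ortholog references are the intended use.
* The greedy overlap resolution is not globally optimal for triple-covered
  positions (see above).
* Codon provenance — and hence nucleotide output — is available only when
  the nucleotide queries accompany the hits.
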