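"""One-command pipeline: search -> stitch -> mask -> trim -> finalize -> report.

Also provides the multi-taxon helper that regroups per-taxon marker FASTAs
into one FASTA per reference for downstream multiple alignment.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__, search as search_mod, seqio
from .pairwise import ScoringScheme
from .refine import MaskPolicy, TrimPolicy, finalize
from .report import MarkerReport, marker_stats, write_reports
from .search import builtin_search, parse_tabular, run_external_search
from .seqio import SeqRecord
from .stitch import stitch

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    query_paths: list[str] = field(default_factory=list)
    reference_paths: list[str] = field(default_factory=list)
    mode: str = "contigs"  # contigs | reads
    tabular: str | None = None  # precomputed tabular search result
    engine: str = "builtin"  # builtin | blastx | diamond
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_score: int = 100
    min_bitscore: float = 0.0
    anchor_identities: int = 4  # hit ends must sit on this many identical columns; 0 = off
    retain_stops: bool = False
    retain_ambiguous: bool = False
    window_size: int = 15
    distance_threshold: float = 0.5
    no_trim: bool = False
    masking: int = 0
    frameshift: int | None = None
    query_label: str | None = None
    out_dir: str = "markerstitch_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(self.matrix, self.gap_open, self.gap_extend)

    def mask_policy(self) -> MaskPolicy:
        return MaskPolicy(retain_stops=self.retain_stops, retain_ambiguous=self.retain_ambiguous)

    def trim_policy(self) -> TrimPolicy:
        return TrimPolicy(
            window_size=self.window_size,
            distance_threshold=self.distance_threshold,
            enabled=not self.no_trim,
        )


class _RunLog:
    """JSON-lines run log: stage timings, in/out counts, parameters."""

    def __init__(self, path: Path):
        self.path = path
        self.handle = open(path, "wt")

    def event(self, stage: str, **payload) -> None:
        record = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, **payload}
        self.handle.write(json.dumps(record) + "\n")
        self.handle.flush()

    def close(self) -> None:
        self.handle.close()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Writes: pooled references, the reusable tabular hit file,
    ``markers_aa.fasta`` / ``markers_nt.fasta`` (headers
    ``<query_label>@<ref_id>``), both report TSVs, the resolved
    configuration and a run log.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out_dir / "run_log.jsonl")
    log.event("start", version=__version__, python=platform.python_version(),
              config=asdict(config))
    with open(out_dir / "config.yaml", "wt") as handle:
        yaml.safe_dump(asdict(config), handle)

    scheme = config.scheme()

    # --- input ---
    if not config.reference_paths:
        raise ValueError("at least one reference FASTA is required")
    pooled_path, references = seqio.pool_references(
        config.reference_paths, out_dir / "references_pooled.fasta"
    )
    queries: list[SeqRecord] = []
    for qp in config.query_paths:
        if config.mode == "reads" or str(qp).rstrip(".gz").endswith(("fastq", "fq")):
            queries.extend(seqio.read_fastq(qp))
        else:
            queries.extend(seqio.read_fasta(qp, alphabet=seqio.NUCLEOTIDE))
    log.event("input", n_queries=len(queries), n_references=len(references))

    # --- search ---
    t0 = time.perf_counter()
    already_anchored = False
    if config.tabular is not None:
        grouped = parse_tabular(config.tabular, references, scheme, queries=queries or None)
    elif config.engine == "builtin":
        if not queries:
            raise ValueError("no query sequences given")
        grouped = builtin_search(
            queries, references, scheme,
            min_score=config.min_score, anchor=config.anchor_identities,
        )
        already_anchored = True
    else:
        if len(config.query_paths) != 1:
            raise ValueError("external search expects exactly one query file")
        extra: list[str] = []
        if config.engine == "diamond":
            if config.frameshift is not None:
                extra += ["--frameshift", str(config.frameshift)]
        tab = run_external_search(
            config.query_paths[0], pooled_path, out_dir,
            engine=config.engine, extra_options=extra, masking=config.masking,
        )
        grouped = parse_tabular(tab, references, scheme, queries=queries or None)
    if config.min_bitscore > 0:
        grouped = {
            ref: [r for r in regions if r.bitscore >= config.min_bitscore]
            for ref, regions in grouped.items()
        }
        grouped = {ref: regions for ref, regions in grouped.items() if regions}
    if config.anchor_identities > 0 and not already_anchored:
        # builtin_search anchors (and exact-extends) its own hits
        anchored: dict[str, list] = {}
        for ref, regions in grouped.items():
            kept = [
                a for r in regions
                if (a := search_mod.anchor_ends(r, config.anchor_identities, scheme)) is not None
            ]
            if kept:
                anchored[ref] = kept
        grouped = anchored
    all_regions = [r for regions in grouped.values() for r in regions]
    search_mod.write_tabular(all_regions, out_dir / "hits.tsv")
    log.event("search", seconds=round(time.perf_counter() - t0, 3),
              n_hits=len(all_regions), n_references_hit=len(grouped))

    # --- stitch / refine / report per reference ---
    ref_by_id = {r.id: r for r in references}
    markers = []
    reports: list[MarkerReport] = []
    t0 = time.perf_counter()
    for ref_id in sorted(grouped):
        reference = ref_by_id[ref_id]
        stacked = stitch(grouped[ref_id], reference, scheme)
        marker = finalize(
            stacked, reference, scheme,
            trim_policy=config.trim_policy(), mask_policy=config.mask_policy(),
        )
        if marker is None:
            log.event("marker_absent", ref_id=ref_id)
            continue
        markers.append(marker)
        reports.append(marker_stats(marker, reference))
    log.event("stitch_refine", seconds=round(time.perf_counter() - t0, 3),
              n_markers=len(markers))

    # --- output ---
    label = config.query_label or (
        Path(config.query_paths[0]).stem if config.query_paths else "query"
    )
    aa_records = [
        SeqRecord(id=f"{label}@{m.ref_id}", seq=m.final_aa, alphabet=seqio.AMINO_ACID)
        for m in markers
    ]
    seqio.write_fasta(aa_records, out_dir / "markers_aa.fasta")
    nt_records = [
        SeqRecord(id=f"{label}@{m.ref_id}", seq=m.final_nt, alphabet=seqio.NUCLEOTIDE)
        for m in markers
        if m.final_nt
    ]
    seqio.write_fasta(nt_records, out_dir / "markers_nt.fasta")
    write_reports(reports, out_dir)
    log.event("done", n_markers=len(markers))
    log.close()
    return out_dir


def concat_taxa(
    marker_fastas: dict[str, str | Path], out_dir: str | Path
) -> list[Path]:
    """Regroup per-taxon marker FASTAs into one FASTA per reference.

    ``marker_fastas`` maps a unique taxon label to that taxon's
    ``markers_aa.fasta`` (headers ``<label>@<ref_id>``). Output files are
    named ``<ref_id>.fasta`` and carry one record per taxon that recovered
    the marker; missing taxa are simply absent (no placeholder).
    """
    labels = list(marker_fastas)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels")
    by_ref: dict[str, list[SeqRecord]] = {}
    for label, path in marker_fastas.items():
        for rec in seqio.read_fasta(path, alphabet=seqio.AMINO_ACID):
            ref_id = rec.id.split("@", 1)[1] if "@" in rec.id else rec.id
            by_ref.setdefault(ref_id, []).append(
                SeqRecord(id=label, seq=rec.seq, description=ref_id, alphabet=seqio.AMINO_ACID)
            )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ref_id in sorted(by_ref):
        paths.append(seqio.write_fasta(by_ref[ref_id], out_dir / f"{ref_id}.fasta"))
    return paths
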