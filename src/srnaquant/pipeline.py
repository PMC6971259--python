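"""End-to-end quantification: alignments in, three count tables out.

Stage order matters: unique reads establish the coverage track, UAR
clusters, and the first counts; multimaps are then placed against that
evidence; salvage runs last so it can prefer transcripts that already
carry expression; unannotated unique reads finally feed novel-locus
detection.  The run result carries a conservation audit — every read
copy ends up in exactly one of transcript counts, novel-locus counts,
or the unassigned bucket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import alignments as aln
from .alignments import ClusterIndex, ReadClass
from .discovery import (
    IsomiRRow,
    NovelClusterRow,
    clustered_mass,
    collect_isomirs,
    detect_novel_clusters,
)
from .outputs import TranscriptRow, compute_rpm, rpm_denominator, write_tables
from .placement import (
    CountTable,
    PlacementParams,
    PlacementResult,
    ROUTE_SALVAGE,
    accumulate,
    assign_uar,
    place_multimap,
)
from .reference import FeatureIndex, TranscriptSet, extend_and_index
from .salvage import salvage_reads

log = logging.getLogger(__name__)


@dataclass
class QuantifyConfig:
    params: PlacementParams = field(default_factory=PlacementParams)
    salvage_max_mismatches: int = 3
    salvage_both_strands: bool = False
    novel_min_reads: int = 5
    novel_max_gap: int = 50
    uar_min_density: int = 1


@dataclass
class RunResult:
    table: CountTable
    transcript_rows: List[TranscriptRow]
    isomir_rows: List[IsomiRRow]
    novel_rows: List[NovelClusterRow]
    class_tally: Dict[str, int]
    route_tally: Dict[str, int]
    total_copies: int

    def conservation_residual(self) -> float:
        """total input copies minus (transcripts + novel + unassigned)."""
        return self.total_copies - self.table.total()


def quantify_groups(
    groups: List[aln.ReadAlignmentGroup],
    unaligned: List[aln.ReadAlignmentGroup],
    ts: TranscriptSet,
    transcript_seqs: Dict[str, str],
    cfg: Optional[QuantifyConfig] = None,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> RunResult:
    """Run the full placement pipeline on pre-parsed alignment groups."""
    cfg = cfg or QuantifyConfig()
    p = cfg.params
    idx: FeatureIndex = extend_and_index(
        ts, extension=p.extension, min_overlap=p.min_overlap, chrom_lengths=chrom_lengths
    )

    by_class = aln.split_by_class(groups, p.max_multimaps)
    class_tally = {c.name: len(v) for c, v in by_class.items()}
    class_tally["UNALIGNED"] += len(unaligned)

    uar_hits = [(g.hits[0], g.copies) for g in by_class[ReadClass.UNIQUE]]
    clusters = aln.build_uar_clusters(uar_hits, cfg.uar_min_density, p.extension)
    cluster_idx = ClusterIndex(clusters)
    cov = aln.build_coverage(uar_hits)

    # unique reads: direct assignment or novel-locus stream
    uar_assignments: List[Tuple[str, List[str], int]] = []
    unannotated_uars: List[Tuple[object, int]] = []
    mirna_reads: List[Tuple[str, str, float]] = []
    by_id = ts.by_id()
    for g in by_class[ReadClass.UNIQUE]:
        hit = g.hits[0]
        res = assign_uar(hit.locus, len(g.sequence) or hit.locus.length, idx)
        if res is None:
            unannotated_uars.append((hit.locus, g.copies))
        else:
            tid, alts = res
            uar_assignments.append((tid, alts, g.copies))
            if by_id[tid].is_mature_mirna:
                mirna_reads.append((by_id[tid].name, g.sequence, float(g.copies)))

    # multimaps through the decision tree
    placements: List[Tuple[PlacementResult, int]] = []
    salvage_queue: List[Tuple[str, str, int]] = []
    route_tally: Dict[str, int] = {}
    for g in by_class[ReadClass.MULTI]:
        res = place_multimap(g, idx, cluster_idx, cov, p)
        route_tally[res.route] = route_tally.get(res.route, 0) + 1
        if res.route == ROUTE_SALVAGE and not res.assignments:
            salvage_queue.append((g.read_id, g.sequence, g.copies))
        else:
            placements.append((res, g.copies))
            _note_mirna(res, g.sequence, g.copies, by_id, mirna_reads)

    table = accumulate(placements, uar_assignments, max_alternatives=p.max_alternatives)

    # salvage: overflow, unaligned, and evidence-free multimaps
    for g in by_class[ReadClass.OVERFLOW] + by_class[ReadClass.UNALIGNED] + unaligned:
        salvage_queue.append((g.read_id, g.sequence, g.copies))
    salvaged = salvage_reads(
        salvage_queue, transcript_seqs, table,
        cfg.salvage_max_mismatches, cfg.salvage_both_strands,
    )
    n_rescued = 0
    for res, copies in salvaged:
        if res.assignments:
            n_rescued += 1
            seq = next(s for rid, s, c in salvage_queue if rid == res.read_id)
            _note_mirna(res, seq, copies, by_id, mirna_reads)
    accumulate(salvaged, [], table, p.max_alternatives)
    route_tally["SALVAGED"] = n_rescued
    route_tally["SALVAGE_FAILED"] = len(salvaged) - n_rescued

    # novel loci from unannotated unique reads
    novel_rows = detect_novel_clusters(unannotated_uars, cfg.novel_min_reads, cfg.novel_max_gap)
    inside, outside = clustered_mass(unannotated_uars, novel_rows)
    table.novel_mass += inside
    table.unassigned += outside

    denom = rpm_denominator(table)
    transcript_rows = compute_rpm(table, ts, p.max_alternatives)
    isomir_rows = collect_isomirs(mirna_reads, denom)

    total_copies = sum(g.copies for g in groups) + sum(g.copies for g in unaligned)
    result = RunResult(
        table, transcript_rows, isomir_rows, novel_rows,
        class_tally, route_tally, total_copies,
    )
    log.info(
        "classes=%s routes=%s conservation_residual=%.3g",
        class_tally, route_tally, result.conservation_residual(),
    )
    return result


def _note_mirna(res, sequence, copies, by_id, mirna_reads) -> None:
    for target, frac in res.assignments:
        if isinstance(target, str):
            rec = by_id.get(target)
            if rec is not None and rec.is_mature_mirna:
                mirna_reads.append((rec.name, sequence, frac * copies))


def run_quantify(
    sam_path: str,
    gtf_path: str,
    transcript_fasta: Optional[str],
    out_dir: Optional[str] = None,
    cfg: Optional[QuantifyConfig] = None,
) -> RunResult:
    """File-level entry point: SAM/BAM + GTF (+ transcript FASTA) -> tables."""
    from .reference import load_annotation, load_transcript_fasta

    cfg = cfg or QuantifyConfig()
    ts = load_annotation(gtf_path, extension=cfg.params.extension)
    seqs = load_transcript_fasta(transcript_fasta) if transcript_fasta else {}
    groups, unaligned = aln.parse_alignments(sam_path, cfg.params.max_multimaps)
    import pysam

    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        chrom_lengths = {sq["SN"]: sq["LN"] for sq in fh.header.get("SQ", [])}
    result = quantify_groups(groups, unaligned, ts, seqs, cfg, chrom_lengths)
    if out_dir:
        write_tables(result.transcript_rows, result.isomir_rows, result.novel_rows, out_dir)
    return result


def unique_baseline_counts(
    groups: List[aln.ReadAlignmentGroup],
    ts: TranscriptSet,
    params: Optional[PlacementParams] = None,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> Dict[str, float]:
    """Uniquely-aligned-reads-only quantification (comparison baseline).

    Discards every multimap, overflow, and unaligned read; unique reads
    are assigned by the same overlap/ranking rules as the pipeline.
    """
    p = params or PlacementParams()
    idx = extend_and_index(ts, p.extension, p.min_overlap, chrom_lengths)
    counts: Dict[str, float] = {}
    for g in groups:
        if g.classify(p.max_multimaps) is not ReadClass.UNIQUE:
            continue
        hit = g.hits[0]
        res = assign_uar(hit.locus, len(g.sequence) or hit.locus.length, idx)
        if res is not None:
            counts[res[0]] = counts.get(res[0], 0.0) + g.copies
    return counts
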