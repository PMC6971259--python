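"""Genome-alignment ingestion and uniquely-aligned-read (UAR) evidence.

Reads are grouped by name into :class:`ReadAlignmentGroup` objects
holding all equal-best genomic hits the aligner reported, and classed as
UNIQUE (one hit), MULTI (2..max hits), OVERFLOW (more) or UNALIGNED.
UARs provide two kinds of evidence used downstream: chained UAR
clusters (expression evidence at a locus) and a per-base coverage track
f_cov (density evidence weighted by proximity during placement).
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import pysam

from .reference import FeatureIndex, GenomicInterval

log = logging.getLogger(__name__)


class ReadClass(Enum):
    UNIQUE = "UNIQUE"
    MULTI = "MULTI"
    OVERFLOW = "OVERFLOW"
    UNALIGNED = "UNALIGNED"


@dataclass(frozen=True)
class AlignmentHit:
    """One genomic alignment of a read."""

    locus: GenomicInterval
    mismatches: int = 0
    read_sequence_as_aligned: str = ""


_COPIES_RE = re.compile(r"_x(\d+)$")


def copies_from_read_id(read_id: str) -> int:
    """Collapsed-FASTA convention: a header ``id_xN`` means N duplicates."""
    m = _COPIES_RE.search(read_id)
    return int(m.group(1)) if m else 1


@dataclass
class ReadAlignmentGroup:
    """One read with all its equal-best genomic loci (the multi-mapped set)."""

    read_id: str
    sequence: str
    hits: List[AlignmentHit] = field(default_factory=list)
    copies: int = 1

    def classify(self, max_multimaps: int = 50) -> ReadClass:
        n = len(self.hits)
        if n == 0:
            return ReadClass.UNALIGNED
        if n == 1:
            return ReadClass.UNIQUE
        if n <= max_multimaps:
            return ReadClass.MULTI
        return ReadClass.OVERFLOW


@dataclass(frozen=True)
class UARCluster:
    """A chained group of UARs on one strand.

    ``interval`` is the merged span of the member reads' extended
    footprints — the region inside which a multimap locus is considered
    supported by unique-read expression.
    """

    interval: GenomicInterval
    read_count: int


class CoverageTrack:
    """Sparse per (chrom, strand) map position -> UAR depth (f_cov)."""

    def __init__(self) -> None:
        self._depth: Dict[Tuple[str, str], Dict[int, int]] = defaultdict(dict)

    def add(self, hit: AlignmentHit, copies: int = 1) -> None:
        d = self._depth[(hit.locus.chrom, hit.locus.strand)]
        for p in range(hit.locus.start, hit.locus.end):
            d[p] = d.get(p, 0) + copies

    def depth(self, chrom: str, strand: str, pos: int) -> int:
        return self._depth.get((chrom, strand), {}).get(pos, 0)

    def window(self, chrom: str, strand: str, start: int, end: int) -> List[int]:
        """Depths over [start, end) as a list (dense, zeros filled)."""
        d = self._depth.get((chrom, strand), {})
        return [d.get(p, 0) for p in range(start, end)]

    def total_mass(self) -> int:
        return sum(v for d in self._depth.values() for v in d.values())


def _hit_from_segment(seg: pysam.AlignedSegment) -> Optional[AlignmentHit]:
    if seg.reference_start is None or seg.reference_end is None:
        return None
    strand = "-" if seg.is_reverse else "+"
    locus = GenomicInterval(seg.reference_name, seg.reference_start, seg.reference_end, strand)
    nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
    seq = seg.query_sequence or ""
    if seg.is_reverse and seq:
        seq = reverse_complement(seq)  # restore original read orientation
    return AlignmentHit(locus=locus, mismatches=int(nm), read_sequence_as_aligned=seq)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def parse_alignments(
    sam_path: str, max_multimaps: int = 50
) -> Tuple[List[ReadAlignmentGroup], List[ReadAlignmentGroup]]:
    """Read a SAM/BAM and group records by read name.

    Returns ``(aligned_groups, unaligned_groups)``.  Unaligned reads
    (flag 0x4) come back as empty-hit groups for the salvage stage.
    Malformed records are skipped with a warning; a missing header
    (no @SQ lines) is fatal.
    """
    groups: Dict[str, ReadAlignmentGroup] = {}
    order: List[str] = []
    with pysam.AlignmentFile(sam_path, check_sq=True) as fh:
        if not fh.header.get("SQ"):
            raise RuntimeError(f"{sam_path}: SAM header lacks @SQ lines")
        for seg in fh.fetch(until_eof=True):
            qname = seg.query_name
            if qname is None:
                log.warning("%s: record without read name skipped", sam_path)
                continue
            if qname not in groups:
                # original read orientation is restored per-hit below;
                # unaligned records are always stored as sequenced
                init_seq = (seg.query_sequence or "") if seg.is_unmapped else ""
                groups[qname] = ReadAlignmentGroup(
                    read_id=qname,
                    sequence=init_seq,
                    copies=copies_from_read_id(qname),
                )
                order.append(qname)
            g = groups[qname]
            if seg.is_unmapped:
                if not g.sequence and seg.query_sequence:
                    g.sequence = seg.query_sequence
                continue
            hit = _hit_from_segment(seg)
            if hit is None:
                log.warning("%s: malformed aligned record for %s skipped", sam_path, qname)
                continue
            if not g.sequence and hit.read_sequence_as_aligned:
                g.sequence = hit.read_sequence_as_aligned
            g.hits.append(hit)
    aligned = [groups[q] for q in order if groups[q].hits]
    unaligned = [groups[q] for q in order if not groups[q].hits]
    return aligned, unaligned


def split_by_class(
    groups: Iterable[ReadAlignmentGroup], max_multimaps: int = 50
) -> Dict[ReadClass, List[ReadAlignmentGroup]]:
    out: Dict[ReadClass, List[ReadAlignmentGroup]] = {c: [] for c in ReadClass}
    for g in groups:
        out[g.classify(max_multimaps)].append(g)
    return out


def build_uar_clusters(
    uars: Iterable[Tuple[AlignmentHit, int]],
    min_density: int = 1,
    extension: int = 50,
) -> List[UARCluster]:
    """Chain UARs whose ``extension``-nt-extended footprints overlap.

    ``uars`` yields (hit, copies) pairs from UNIQUE-class reads only.
    Chains holding fewer than ``min_density`` reads are dropped.
    """
    by_key: Dict[Tuple[str, str], List[Tuple[int, int, int]]] = defaultdict(list)
    for hit, copies in uars:
        loc = hit.locus
        by_key[(loc.chrom, loc.strand)].append(
            (max(0, loc.start - extension), loc.end + extension, copies)
        )
    clusters: List[UARCluster] = []
    for (chrom, strand), spans in by_key.items():
        spans.sort()
        cur_start, cur_end, cur_n = spans[0]
        for s, e, c in spans[1:]:
            if s <= cur_end:  # half-open overlap/adjacency chains
                cur_end = max(cur_end, e)
                cur_n += c
            else:
                if cur_n >= min_density:
                    clusters.append(
                        UARCluster(GenomicInterval(chrom, cur_start, cur_end, strand), cur_n)
                    )
                cur_start, cur_end, cur_n = s, e, c
        if cur_n >= min_density:
            clusters.append(UARCluster(GenomicInterval(chrom, cur_start, cur_end, strand), cur_n))
    clusters.sort(key=lambda cl: (cl.interval.chrom, cl.interval.strand, cl.interval.start))
    return clusters


class ClusterIndex:
    """Fast 'does this locus fall in a UAR cluster' lookups."""

    def __init__(self, clusters: Iterable[UARCluster]):
        from intervaltree import IntervalTree

        self._trees: Dict[Tuple[str, str], "IntervalTree"] = {}
        for cl in clusters:
            key = (cl.interval.chrom, cl.interval.strand)
            self._trees.setdefault(key, IntervalTree()).addi(
                cl.interval.start, cl.interval.end, cl
            )

    def has_overlap(self, locus: GenomicInterval) -> bool:
        tree = self._trees.get((locus.chrom, locus.strand))
        return bool(tree and tree.overlap(locus.start, locus.end))


def build_coverage(uars: Iterable[Tuple[AlignmentHit, int]]) -> CoverageTrack:
    """f_cov: per-position UAR depth, collapsed-read copies included."""
    cov = CoverageTrack()
    for hit, copies in uars:
        cov.add(hit, copies)
    return cov


def classify_multimap_case(
    g: ReadAlignmentGroup,
    idx: FeatureIndex,
    cluster_idx: "ClusterIndex",
    max_multimaps: int = 50,
) -> int:
    """Diagnostic taxonomy of a multimap's loci against annotation (A)
    and UAR-cluster (U) evidence.

    1. some loci have UAR clusters, none anywhere has annotation
    2. some loci have annotation, none anywhere has a UAR cluster
    3. at least one locus has both annotation and a UAR cluster
    4. no locus has either
    5. annotated loci and UAR-cluster loci both exist but never coincide
    """
    if g.classify(max_multimaps) is not ReadClass.MULTI:
        raise ValueError("case classification is defined for MULTI groups only")
    any_a = any_u = any_au = False
    for hit in g.hits:
        a = idx.has_overlap(hit.locus)
        u = cluster_idx.has_overlap(hit.locus)
        any_a |= a
        any_u |= u
        any_au |= a and u
    if any_au:
        return 3
    if any_a and any_u:
        return 5
    if any_a:
        return 2
    if any_u:
        return 1
    return 4
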