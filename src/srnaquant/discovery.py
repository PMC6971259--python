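"""Novel unannotated expression loci and isomiR sequence collection.

Uniquely aligned reads that overlap no annotated feature are chained
into candidate expression clusters: coordinate-sorted reads on one
strand join a chain while the gap between consecutive reads stays at or
below ``max_gap`` (default 50 nt); chains with at least ``min_reads``
(default 5) become reported loci.  IsomiR collection simply groups the
exact sequences of reads assigned to mature miRNAs — every distinct
sequence (trimmed, extended, or substituted variants) becomes its own
row, leaving subtype classification to downstream tools.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from .reference import GenomicInterval


@dataclass(frozen=True)
class NovelClusterRow:
    chrom: str
    strand: str
    start: int
    end: int
    count: int

    @property
    def cluster_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IsomiRRow:
    mirna_name: str
    sequence: str
    count: float
    rpm: float = 0.0


def detect_novel_clusters(
    uars: Iterable[Tuple[GenomicInterval, int]],
    min_reads: int = 5,
    max_gap: int = 50,
) -> List[NovelClusterRow]:
    """Chain unannotated UARs into expression clusters.

    ``uars`` yields (locus, copies) for unique reads with no annotation
    overlap.  Gap is measured end-to-start between coordinate-sorted
    reads (half-open), so abutting reads chain with gap 0.  The reported
    Count includes collapsed-read copies; the min_reads threshold is
    applied to the copy-weighted count.
    """
    by_key: Dict[Tuple[str, str], List[Tuple[int, int, int]]] = defaultdict(list)
    for locus, copies in uars:
        by_key[(locus.chrom, locus.strand)].append((locus.start, locus.end, copies))
    rows: List[NovelClusterRow] = []
    for (chrom, strand), spans in sorted(by_key.items()):
        spans.sort()
        c_start, c_end, c_n = spans[0]
        for s, e, c in spans[1:]:
            if s - c_end <= max_gap:
                c_end = max(c_end, e)
                c_n += c
            else:
                if c_n >= min_reads:
                    rows.append(NovelClusterRow(chrom, strand, c_start, c_end, c_n))
                c_start, c_end, c_n = s, e, c
        if c_n >= min_reads:
            rows.append(NovelClusterRow(chrom, strand, c_start, c_end, c_n))
    return rows


def clustered_mass(
    uars: Iterable[Tuple[GenomicInterval, int]],
    clusters: List[NovelClusterRow],
) -> Tuple[float, float]:
    """Split unannotated-UAR copy mass into (inside clusters, outside).

    Used for the conservation audit: cluster counts absorb the inside
    mass, the remainder goes to the unassigned bucket.
    """
    spans: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
    for row in clusters:
        spans[(row.chrom, row.strand)].append((row.start, row.end))
    inside = outside = 0.0
    for locus, copies in uars:
        in_cluster = any(
            locus.start >= s and locus.end <= e
            for s, e in spans.get((locus.chrom, locus.strand), ())
        )
        if in_cluster:
            inside += copies
        else:
            outside += copies
    return inside, outside


def collect_isomirs(
    mirna_reads: Iterable[Tuple[str, str, float]],
    denominator: float = 0.0,
) -> List[IsomiRRow]:
    """Group miRNA-assigned read sequences into isomiR rows.

    ``mirna_reads`` yields (mirna_name, read_sequence, weighted_count)
    where weighted_count already includes the assignment fraction and
    collapsed-read copies.  RPM uses the global small-RNA denominator.
    """
    tally: Dict[Tuple[str, str], float] = defaultdict(float)
    for name, seq, w in mirna_reads:
        tally[(name, seq)] += w
    scale = 1e6 / denominator if denominator > 0 else 0.0
    rows = [
        IsomiRRow(name, seq, count, count * scale)
        for (name, seq), count in tally.items()
        if count > 0
    ]
    rows.sort(key=lambda r: (-r.count, r.mirna_name, r.sequence))
    return rows
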