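"""Non-coding annotation loading and extended-interval overlap queries.

Small-RNA features (mature miRNAs, tRNAs, snoRNAs, ...) are treated as
single genomic intervals.  All coordinates are 0-based half-open
internally; GTF (1-based inclusive) and SAM (1-based) are converted at
the boundary.  For read-assignment queries every feature interval is
extended by a fixed number of nucleotides at each end (default 50) so
that reads produced by imprecise processing at feature boundaries can
still be assigned without biasing any particular biotype.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: gene_biotype values treated as mature microRNAs for placement priority.
MATURE_MIRNA_BIOTYPES = frozenset({"miRNA"})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strand-aware genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared nucleotides; 0 if different chrom/strand."""
        if self.chrom != other.chrom or self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def extended(self, nt: int, chrom_length: Optional[int] = None) -> "GenomicInterval":
        """Extend by ``nt`` at each end, clipped at 0 (and chrom end if known)."""
        start = max(0, self.start - nt)
        end = self.end + nt
        if chrom_length is not None:
            end = min(end, chrom_length)
        return replace(self, start=start, end=end)


@dataclass
class TranscriptRecord:
    """One annotated small-RNA feature (single-interval locus)."""

    transcript_id: str
    gene_id: str
    name: str
    biotype: str
    interval: GenomicInterval
    sequence: Optional[str] = None

    @property
    def is_mature_mirna(self) -> bool:
        return self.biotype in MATURE_MIRNA_BIOTYPES


@dataclass
class TranscriptSet:
    """Collection of transcript records plus the per-end extension (nt)."""

    records: List[TranscriptRecord] = field(default_factory=list)
    extension: int = 50
    skipped: int = 0  # GTF lines dropped for missing attributes

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> Dict[str, TranscriptRecord]:
        return {r.transcript_id: r for r in self.records}


class FeatureIndex:
    """Per (chrom, strand) interval tree over *extended* feature intervals.

    The original (unextended) intervals are retained on each record for
    coverage-ratio ranking, which must use true transcript lengths.
    """

    def __init__(self, min_overlap: int = 1):
        if min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        self.min_overlap = min_overlap
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self._extended: Dict[str, GenomicInterval] = {}

    def add(self, record: TranscriptRecord, extended: GenomicInterval) -> None:
        key = (extended.chrom, extended.strand)
        tree = self._trees.setdefault(key, IntervalTree())
        tree.addi(extended.start, extended.end, record)
        self._extended[record.transcript_id] = extended

    def extended_interval(self, transcript_id: str) -> GenomicInterval:
        return self._extended[transcript_id]

    def query(self, locus: GenomicInterval) -> List[TranscriptRecord]:
        """Strand- and chrom-matched records whose extended interval shares
        at least ``min_overlap`` nt with ``locus``, sorted by transcript_id."""
        tree = self._trees.get((locus.chrom, locus.strand))
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(locus.start, locus.end):
            ov = min(iv.end, locus.end) - max(iv.begin, locus.start)
            if ov >= self.min_overlap:
                hits.append(iv.data)
        hits.sort(key=lambda r: r.transcript_id)
        return hits

    def has_overlap(self, locus: GenomicInterval) -> bool:
        return bool(self.query(locus))


# GTF attribute parsing: both 'key "value";' (Ensembl) and key=value (GFF-ish)
_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"|(\w+)=([^;]+)')


def _parse_attributes(field9: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for m in _ATTR_RE.finditer(field9):
        if m.group(1):
            attrs[m.group(1)] = m.group(2)
        else:
            attrs[m.group(3)] = m.group(4).strip()
    return attrs


REQUIRED_ATTRS = ("gene_id", "gene_name", "gene_biotype")


def load_annotation(gtf_path: str, extension: int = 50) -> TranscriptSet:
    """Load a GTF of non-coding features into a :class:`TranscriptSet`.

    Every line must carry ``gene_id``, ``gene_name`` and ``gene_biotype``
    attributes; lines missing any of them are skipped with a warning.
    ``transcript_id`` defaults to ``gene_id`` when absent.  Duplicate
    transcript_ids (multi-exon features) are merged to their enclosing
    span.  1-based inclusive GTF coordinates become 0-based half-open.
    """
    ts = TranscriptSet(extension=extension)
    merged: Dict[str, TranscriptRecord] = {}
    try:
        fh = open(gtf_path)
    except OSError as exc:
        raise RuntimeError(f"cannot read annotation {gtf_path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                log.warning("%s:%d: malformed GTF line skipped", gtf_path, lineno)
                ts.skipped += 1
                continue
            chrom, _src, _feat, start1, end1, _score, strand, _frame, attr_str = fields[:9]
            attrs = _parse_attributes(attr_str)
            if any(a not in attrs for a in REQUIRED_ATTRS):
                log.warning("%s:%d: missing required attribute, skipped", gtf_path, lineno)
                ts.skipped += 1
                continue
            if strand not in ("+", "-"):
                log.warning("%s:%d: unstranded feature skipped", gtf_path, lineno)
                ts.skipped += 1
                continue
            tid = attrs.get("transcript_id", attrs["gene_id"])
            interval = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            if tid in merged:
                prev = merged[tid].interval
                merged[tid].interval = replace(
                    prev, start=min(prev.start, interval.start), end=max(prev.end, interval.end)
                )
            else:
                merged[tid] = TranscriptRecord(
                    transcript_id=tid,
                    gene_id=attrs["gene_id"],
                    name=attrs["gene_name"],
                    biotype=attrs["gene_biotype"],
                    interval=interval,
                )
    ts.records = list(merged.values())
    if not ts.records:
        raise RuntimeError(f"no usable records in annotation {gtf_path}")
    return ts


def extend_and_index(
    ts: TranscriptSet,
    extension: Optional[int] = None,
    min_overlap: int = 1,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> FeatureIndex:
    """Build a :class:`FeatureIndex` over intervals extended by ``extension``
    nt at each end (clipped at 0 and, when known, at the chromosome end)."""
    ext = ts.extension if extension is None else extension
    if ext < 0:
        raise ValueError("extension must be >= 0")
    idx = FeatureIndex(min_overlap=min_overlap)
    for rec in ts.records:
        clen = chrom_lengths.get(rec.interval.chrom) if chrom_lengths else None
        idx.add(rec, rec.interval.extended(ext, clen))
    return idx


def overlap_query(idx: FeatureIndex, locus: GenomicInterval) -> List[TranscriptRecord]:
    """Annotated features overlapping ``locus`` (see :meth:`FeatureIndex.query`)."""
    return idx.query(locus)


def load_transcript_fasta(fasta_path: str) -> Dict[str, str]:
    """Transcript sequences keyed by the first word of the FASTA header."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}


def attach_sequences(ts: TranscriptSet, seqs: Dict[str, str]) -> int:
    """Attach sequences to matching records; returns how many matched."""
    n = 0
    for rec in ts.records:
        if rec.transcript_id in seqs:
            rec.sequence = seqs[rec.transcript_id]
            n += 1
    return n
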