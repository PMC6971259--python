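"""Density-guided placement of multi-mapping reads.

A multimap with loci i = 1..MML is split across its valid loci in
proportion to a density score per locus:

    f_split(x_i, y_i) = f_score(x_i, y_i) / sum_j f_score(x_j, y_j)
    f_score(x_i, y_i) = sum_{p = x_i - r}^{y_i + r} f_cov(p) * f_prox(p)

where f_cov(p) is the UAR depth at genomic position p and f_prox is a
proximity kernel equal to 1 over the read body [x_i, y_i] and decaying
exponentially with scale n over the r-nt flanks.  The decision tree
first restricts loci by annotation (A) and UAR-cluster (U) evidence:
density splitting applies to loci with both; a single such locus takes
the whole read; annotation-only placements are guided by the coverage
ratio

    ratio = overlap * (L_transcript + L_read) / (L_transcript * L_read)

which ranks short fully-covered features (mature miRNAs, ratio -> 2)
above long hosts (precursors); UAR-only and evidence-free multimaps are
routed to a diagnostic tally or to transcriptome salvage respectively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .alignments import ClusterIndex, CoverageTrack, ReadAlignmentGroup, ReadClass
from .reference import FeatureIndex, GenomicInterval, TranscriptRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlacementParams:
    """All placement constants in one place.

    r           proximity range flanking the read (nt)
    n           exponential decay scale of the proximity kernel (nt)
    max_multimaps  loci cap beyond which a read is OVERFLOW
    min_overlap    minimum read/feature overlap for assignment (nt)
    extension      per-end extension of features and UARs (nt)
    """

    r: int = 50
    n: float = 10.0
    max_multimaps: int = 50
    min_overlap: int = 1
    extension: int = 50
    max_alternatives: int = 10

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if self.max_multimaps < 1:
            raise ValueError("max_multimaps must be >= 1")


Target = Union[str, GenomicInterval]  # transcript_id, or a bare locus

ROUTE_DENSITY_SPLIT = "DENSITY_SPLIT"
ROUTE_SINGLE_AU = "SINGLE_AU"
ROUTE_ANNOTATION_ONLY = "ANNOTATION_ONLY"
ROUTE_UAR_ONLY = "UAR_ONLY"
ROUTE_SALVAGE = "SALVAGE"


@dataclass
class PlacementResult:
    read_id: str
    assignments: List[Tuple[Target, float]] = field(default_factory=list)
    alternatives: List[str] = field(default_factory=list)
    route: str = ROUTE_SALVAGE

    def __post_init__(self) -> None:
        if self.assignments:
            total = sum(f for _, f in self.assignments)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fractions sum to {total}, expected 1")


def prox_weight(p: int, x: int, y: int, r: int, n: float) -> float:
    """Proximity kernel f_prox: 1 on the read body, exponential flanks.

    Defined over [x - r, y + r]; at the two window endpoints (excluded
    by the strict-inequality flank branches) the exponential is extended
    continuously to exp(-r/n).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if x <= p <= y:
        return 1.0
    if p < x:
        return math.exp(-(x - p) / n)
    return math.exp(-(p - y) / n)


def locus_score(locus: GenomicInterval, cov: CoverageTrack, params: PlacementParams) -> float:
    """f_score: proximity-weighted UAR depth summed over [x-r, y+r].

    The summation endpoint y+r is included (closed window); x_i = start,
    y_i = end - 1 in half-open coordinates.
    """
    x, y = locus.start, locus.end - 1
    lo, hi = x - params.r, y + params.r
    depths = cov.window(locus.chrom, locus.strand, lo, hi + 1)
    score = 0.0
    for off, d in enumerate(depths):
        if d:
            score += d * prox_weight(lo + off, x, y, params.r, params.n)
    return score


def split_fractions(scores: Sequence[float]) -> List[float]:
    """Normalize density scores to read fractions (f_split).

    All-zero scores fall back to a uniform split (logged): UAR clusters
    can exist at minimum density while the exact summation window
    catches no coverage.
    """
    if not scores:
        raise ValueError("split_fractions requires at least one locus")
    if any(s < 0 for s in scores):
        raise ValueError("scores must be >= 0")
    total = float(sum(scores))
    if total == 0.0:
        log.warning("all locus scores zero; falling back to uniform split")
        return [1.0 / len(scores)] * len(scores)
    return [s / total for s in scores]


def coverage_ratio(overlap: int, transcript_length: int, read_length: int) -> float:
    """Coverage ratio ranking candidate transcripts for a read.

    overlap * (L_t + L_r) / (L_t * L_r); maximal (=2) when the read and
    transcript coincide, so a 22 nt mature miRNA outranks its ~80 nt
    precursor for a fully contained 22 nt read.
    """
    if transcript_length <= 0 or read_length <= 0:
        raise ValueError("lengths must be > 0")
    if overlap < 1:
        raise ValueError("overlap must be >= 1")
    return overlap * (transcript_length + read_length) / (transcript_length * read_length)


def _overlap_for_ratio(locus: GenomicInterval, rec: TranscriptRecord) -> int:
    # ratio uses the unextended transcript; reads qualifying only via the
    # extension get a 1 nt floor so they remain rankable
    return max(1, locus.overlap_length(rec.interval))


def rank_transcripts(
    candidates: Sequence[TranscriptRecord],
    read_length: int,
    overlaps: Sequence[int],
) -> List[Tuple[TranscriptRecord, float]]:
    """Sort candidates by coverage ratio desc, then transcript_id asc."""
    if not candidates:
        raise ValueError("rank_transcripts requires candidates")
    ranked = [
        (rec, coverage_ratio(ov, rec.interval.length, read_length))
        for rec, ov in zip(candidates, overlaps)
    ]
    ranked.sort(key=lambda t: (-t[1], t[0].transcript_id))
    return ranked


def place_multimap(
    g: ReadAlignmentGroup,
    idx: FeatureIndex,
    cluster_idx: ClusterIndex,
    cov: CoverageTrack,
    params: PlacementParams,
) -> PlacementResult:
    """Run the placement decision tree on one MULTI read group.

    Per-locus evidence flags A (annotation overlap) and U (UAR-cluster
    overlap) select the route:

    - >= 2 loci with A and U: density split across them; each locus'
      fraction goes to its top-ranked transcript, co-overlapping
      transcripts become alternatives.
    - exactly 1 such locus: whole read there.
    - annotated loci only: the coverage ratio guides placement; with a
      mature miRNA among the candidates the single best-ratio transcript
      takes the read (ratio ties split equally), otherwise the read is
      split equally across each annotated locus' top-ratio transcript.
    - UAR-cluster loci only: density split across them, kept as a
      diagnostic (novel-locus counts remain UAR-only).
    - no evidence anywhere: routed to transcriptome salvage.
    """
    if g.classify(params.max_multimaps) is not ReadClass.MULTI:
        raise ValueError("place_multimap is defined for MULTI groups only")
    read_length = len(g.sequence) or g.hits[0].locus.length

    per_locus: List[Tuple[GenomicInterval, List[TranscriptRecord], bool]] = []
    for hit in g.hits:
        anns = idx.query(hit.locus)
        per_locus.append((hit.locus, anns, cluster_idx.has_overlap(hit.locus)))

    s_au = [(loc, anns) for loc, anns, u in per_locus if anns and u]
    s_a = [(loc, anns) for loc, anns, u in per_locus if anns]
    s_u = [loc for loc, anns, u in per_locus if u]

    def top_and_alts(
        loc: GenomicInterval, anns: List[TranscriptRecord]
    ) -> Tuple[str, List[str]]:
        ranked = rank_transcripts(
            anns, read_length, [_overlap_for_ratio(loc, r) for r in anns]
        )
        top = ranked[0][0].transcript_id
        return top, [r.transcript_id for r, _ in ranked[1:]]

    if len(s_au) >= 2:
        fracs = split_fractions(
            [locus_score(loc, cov, params) for loc, _ in s_au]
        )
        assignments: List[Tuple[Target, float]] = []
        alternatives: List[str] = []
        for (loc, anns), f in zip(s_au, fracs):
            top, alts = top_and_alts(loc, anns)
            assignments.append((top, f))
            alternatives.extend(alts)
        return PlacementResult(
            g.read_id, _merge(assignments), _dedupe(alternatives, assignments),
            ROUTE_DENSITY_SPLIT,
        )

    if len(s_au) == 1:
        loc, anns = s_au[0]
        top, alts = top_and_alts(loc, anns)
        return PlacementResult(
            g.read_id, [(top, 1.0)], _dedupe(alts, [(top, 1.0)]), ROUTE_SINGLE_AU
        )

    if s_a:
        # pool every transcript overlapping any annotated locus
        pool: Dict[str, Tuple[TranscriptRecord, int]] = {}
        for loc, anns in s_a:
            for rec in anns:
                ov = _overlap_for_ratio(loc, rec)
                prev = pool.get(rec.transcript_id)
                if prev is None or ov > prev[1]:
                    pool[rec.transcript_id] = (rec, ov)
        recs = [v[0] for v in pool.values()]
        ovs = [v[1] for v in pool.values()]
        ranked = rank_transcripts(recs, read_length, ovs)
        if any(rec.is_mature_mirna for rec in recs):
            best_ratio = ranked[0][1]
            winners = [r for r, ratio in ranked if abs(ratio - best_ratio) < 1e-12]
            frac = 1.0 / len(winners)
            assignments = [(r.transcript_id, frac) for r in winners]
        else:
            tops: List[str] = []
            for loc, anns in s_a:
                top, _ = top_and_alts(loc, anns)
                if top not in tops:
                    tops.append(top)
            frac = 1.0 / len(tops)
            assignments = [(t, frac) for t in tops]
        assigned_ids = {t for t, _ in assignments}
        alternatives = [
            r.transcript_id for r, _ in ranked if r.transcript_id not in assigned_ids
        ]
        return PlacementResult(g.read_id, assignments, alternatives, ROUTE_ANNOTATION_ONLY)

    if s_u:
        fracs = split_fractions([locus_score(loc, cov, params) for loc in s_u])
        assignments = [(loc, f) for loc, f in zip(s_u, fracs)]
        return PlacementResult(g.read_id, assignments, [], ROUTE_UAR_ONLY)

    return PlacementResult(g.read_id, [], [], ROUTE_SALVAGE)


def _merge(assignments: List[Tuple[Target, float]]) -> List[Tuple[Target, float]]:
    """Sum fractions landing on the same transcript (distinct loci may
    rank the same feature first)."""
    acc: Dict[Target, float] = {}
    order: List[Target] = []
    for t, f in assignments:
        if t not in acc:
            order.append(t)
        acc[t] = acc.get(t, 0.0) + f
    return [(t, acc[t]) for t in order]


def _dedupe(alts: List[str], assignments: List[Tuple[Target, float]]) -> List[str]:
    assigned = {t for t, _ in assignments if isinstance(t, str)}
    seen: List[str] = []
    for a in alts:
        if a not in assigned and a not in seen:
            seen.append(a)
    return seen


@dataclass
class CountTable:
    """Fractional per-transcript counts with bookkeeping buckets.

    Conservation contract: counts + novel_mass + unassigned equals the
    total read copies that entered the pipeline.
    """

    counts: Dict[str, float] = field(default_factory=dict)
    unique_reads: Dict[str, int] = field(default_factory=dict)
    alternatives: Dict[str, Dict[str, int]] = field(default_factory=dict)
    unassigned: float = 0.0
    novel_mass: float = 0.0
    uar_only_diagnostic: float = 0.0  # sub-tally of unassigned

    def add(self, transcript_id: str, amount: float, unique: bool = False) -> None:
        self.counts[transcript_id] = self.counts.get(transcript_id, 0.0) + amount
        if unique:
            self.unique_reads[transcript_id] = self.unique_reads.get(transcript_id, 0) + 1

    def note_alternatives(self, transcript_id: str, alt_ids: Iterable[str]) -> None:
        tally = self.alternatives.setdefault(transcript_id, {})
        for a in alt_ids:
            tally[a] = tally.get(a, 0) + 1

    def total(self) -> float:
        return sum(self.counts.values()) + self.novel_mass + self.unassigned


def assign_uar(
    hit_locus: GenomicInterval,
    read_length: int,
    idx: FeatureIndex,
) -> Optional[Tuple[str, List[str]]]:
    """Assign one UAR to its best-ratio overlapping transcript.

    Returns (transcript_id, alternatives) or None when the read overlaps
    no annotation (it then feeds novel-locus discovery).
    """
    anns = idx.query(hit_locus)
    if not anns:
        return None
    ranked = rank_transcripts(
        anns, read_length, [_overlap_for_ratio(hit_locus, r) for r in anns]
    )
    return ranked[0][0].transcript_id, [r.transcript_id for r, _ in ranked[1:]]


def accumulate(
    placements: Iterable[Tuple[PlacementResult, int]],
    uar_assignments: Iterable[Tuple[str, List[str], int]],
    table: Optional[CountTable] = None,
    max_alternatives: int = 10,
) -> CountTable:
    """Fold placement results and UAR assignments into a count table.

    ``placements`` yields (result, copies); ``uar_assignments`` yields
    (transcript_id, alternatives, copies) for annotated UARs.  UAR_ONLY
    fractions and unroutable mass land in the unassigned bucket.
    """
    t = table if table is not None else CountTable()
    for tid, alts, copies in uar_assignments:
        t.add(tid, float(copies), unique=True)
        if alts:
            t.note_alternatives(tid, alts[:max_alternatives])
    for res, copies in placements:
        if res.route == ROUTE_UAR_ONLY or not res.assignments:
            t.unassigned += float(copies)
            if res.route == ROUTE_UAR_ONLY:
                t.uar_only_diagnostic += float(copies)
            continue
        for target, frac in res.assignments:
            if isinstance(target, str):
                t.add(target, frac * copies)
        if res.alternatives:
            for target, _ in res.assignments:
                if isinstance(target, str):
                    t.note_alternatives(target, res.alternatives[:max_alternatives])
    return t
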