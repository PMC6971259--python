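"""Transcriptome salvage of overflow, unaligned, and evidence-free reads.

Reads that exceed the multimap cap, never aligned to the genome, or hit
loci with neither annotation nor unique-read support get a second
chance against the transcript sequences themselves: a stepwise Hamming
search that raises the allowed substitution count one unit at a time
(default max 3) and keeps only the first stratum that yields hits.
Salvaged reads preferentially join transcripts that already carry
expression from the genomic stage; otherwise the best-quality hit wins
with up to four runners-up recorded as alternatives.

The built-in scanner is a plain brute-force Hamming sweep over every
transcript offset — exact (stratum-minimal) by construction and
adequate for small-RNA transcriptomes; an external aligner can be
substituted at the CLI level for very large references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .alignments import reverse_complement
from .placement import CountTable, PlacementResult, ROUTE_SALVAGE

log = logging.getLogger(__name__)

MAX_RETAINED_HITS = 5  # 1 assignment + up to 4 alternatives


@dataclass(frozen=True)
class TranscriptHit:
    transcript_id: str
    mismatches: int
    offset: int
    overlap: int  # aligned nucleotides (= read length for contained hits)

    @property
    def quality_rank(self) -> Tuple[int, int, str]:
        # fewer mismatches, then longer overlap, then lexicographic id
        return (self.mismatches, -self.overlap, self.transcript_id)


def _hamming_hits(read: str, tid: str, seq: str, m: int) -> List[TranscriptHit]:
    L, T = len(read), len(seq)
    hits = []
    for off in range(0, T - L + 1):
        mm = 0
        window = seq[off : off + L]
        for a, b in zip(read, window):
            if a != b:
                mm += 1
                if mm > m:
                    break
        else:
            hits.append(TranscriptHit(tid, mm, off, L))
    return hits


def stepwise_align(
    read: str,
    transcripts: Dict[str, str],
    max_mismatches: int = 3,
    both_strands: bool = False,
) -> List[TranscriptHit]:
    """Hits of the first mismatch stratum m = 0, 1, ... that is non-empty.

    Substitutions only (no indels).  With ``both_strands`` the reverse
    complement of the read is also searched, for unstranded libraries.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    read = read.upper()
    queries = [read]
    if both_strands:
        queries.append(reverse_complement(read))
    if not read:
        return []
    for m in range(max_mismatches + 1):
        stratum: List[TranscriptHit] = []
        for tid, seq in transcripts.items():
            for q in queries:
                hits = _hamming_hits(q, tid, seq, m)
                stratum.extend(h for h in hits if h.mismatches == m)
        if stratum:
            stratum.sort(key=lambda h: h.quality_rank)
            return stratum
    return []


def assign_salvaged(
    read_id: str,
    hits: List[TranscriptHit],
    table: CountTable,
) -> PlacementResult:
    """Turn salvage hits into a placement.

    Transcripts already expressed in the count table take precedence:
    the highest-count one gets the whole read (exact ties split
    equally).  With no expressed candidate the top quality-ranked hit is
    assigned and up to four more are kept as alternatives.  No hits at
    all leaves the read for the unassigned bucket.
    """
    if not hits:
        return PlacementResult(read_id, [], [], ROUTE_SALVAGE)
    # one hit per transcript: keep each transcript's best
    best: Dict[str, TranscriptHit] = {}
    for h in hits:
        prev = best.get(h.transcript_id)
        if prev is None or h.quality_rank < prev.quality_rank:
            best[h.transcript_id] = h
    uniq = sorted(best.values(), key=lambda h: h.quality_rank)

    expressed = [h for h in uniq if table.counts.get(h.transcript_id, 0.0) > 0.0]
    if expressed:
        top_count = max(table.counts[h.transcript_id] for h in expressed)
        winners = [h for h in expressed if table.counts[h.transcript_id] == top_count]
        frac = 1.0 / len(winners)
        assignments = [(h.transcript_id, frac) for h in winners]
        assigned = {h.transcript_id for h in winners}
        alts = [h.transcript_id for h in uniq if h.transcript_id not in assigned]
        return PlacementResult(
            read_id, assignments, alts[: MAX_RETAINED_HITS - 1], ROUTE_SALVAGE
        )
    top = uniq[0]
    alts = [h.transcript_id for h in uniq[1:MAX_RETAINED_HITS]]
    return PlacementResult(read_id, [(top.transcript_id, 1.0)], alts, ROUTE_SALVAGE)


def salvage_reads(
    reads: Iterable[Tuple[str, str, int]],
    transcripts: Dict[str, str],
    table: CountTable,
    max_mismatches: int = 3,
    both_strands: bool = False,
) -> List[Tuple[PlacementResult, int]]:
    """Salvage a batch of (read_id, sequence, copies) against ``transcripts``."""
    out: List[Tuple[PlacementResult, int]] = []
    for read_id, seq, copies in reads:
        hits = stepwise_align(seq, transcripts, max_mismatches, both_strands)
        out.append((assign_salvaged(read_id, hits, table), copies))
    return out
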