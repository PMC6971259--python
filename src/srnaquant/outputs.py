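"""Serialization of the three result tables (TSV, deterministic bytes).

Transcripts, IsomiRs, and Unannotated Loci files carry fixed headers
and 2-decimal count formatting.  RPM normalizes by the total count
assigned to annotated small-RNA transcripts (novel loci and unassigned
reads are excluded from the denominator), so transcript RPM values sum
to one million whenever anything was assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

from .discovery import IsomiRRow, NovelClusterRow
from .placement import CountTable
from .reference import TranscriptSet

log = logging.getLogger(__name__)

TRANSCRIPT_HEADER = [
    "Transcript ID",
    "Biotype",
    "Transcript Name",
    "Count",
    "RPM",
    "Unique Reads",
    "Alternative Transcripts",
]
ISOMIR_HEADER = ["Transcript Name", "Sequence", "Count", "RPM"]
NOVEL_HEADER = ["Chromosome", "Strand", "Start", "End", "Cluster Length", "Count"]


@dataclass
class TranscriptRow:
    transcript_id: str
    biotype: str
    name: str
    count: float
    rpm: float
    unique_reads: int
    alternative_transcripts: str  # semicolon-joined ids, empty if none


def rpm_denominator(table: CountTable) -> float:
    """Total copies assigned to annotated small-RNA transcripts."""
    return sum(table.counts.values())


def compute_rpm(table: CountTable, ts: TranscriptSet, max_alternatives: int = 10) -> List[TranscriptRow]:
    """Build output rows with RPM for every expressed transcript."""
    denom = rpm_denominator(table)
    if denom <= 0:
        log.warning("zero small-RNA denominator; all RPM set to 0")
    by_id = ts.by_id()
    rows: List[TranscriptRow] = []
    for tid, count in table.counts.items():
        rec = by_id.get(tid)
        alt_tally = table.alternatives.get(tid, {})
        alts = sorted(alt_tally, key=lambda a: (-alt_tally[a], a))[:max_alternatives]
        rows.append(
            TranscriptRow(
                transcript_id=tid,
                biotype=rec.biotype if rec else "",
                name=rec.name if rec else "",
                count=count,
                rpm=count * 1e6 / denom if denom > 0 else 0.0,
                unique_reads=table.unique_reads.get(tid, 0),
                alternative_transcripts=";".join(alts),
            )
        )
    rows.sort(key=lambda r: (-r.count, r.transcript_id))
    return rows


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def write_transcripts(rows: List[TranscriptRow], path: str) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(TRANSCRIPT_HEADER) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.transcript_id,
                        r.biotype,
                        r.name,
                        _fmt(r.count),
                        _fmt(r.rpm),
                        str(r.unique_reads),
                        r.alternative_transcripts,
                    ]
                )
                + "\n"
            )


def write_isomirs(rows: List[IsomiRRow], path: str) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(ISOMIR_HEADER) + "\n")
        for r in rows:
            fh.write("\t".join([r.mirna_name, r.sequence, _fmt(r.count), _fmt(r.rpm)]) + "\n")


def write_novel(rows: List[NovelClusterRow], path: str) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(NOVEL_HEADER) + "\n")
        for r in sorted(rows, key=lambda r: (-r.count, r.chrom, r.start)):
            fh.write(
                "\t".join(
                    [r.chrom, r.strand, str(r.start), str(r.end), str(r.cluster_length), str(r.count)]
                )
                + "\n"
            )


def write_tables(
    transcript_rows: List[TranscriptRow],
    isomir_rows: List[IsomiRRow],
    novel_rows: List[NovelClusterRow],
    out_dir: str,
) -> Dict[str, str]:
    """Write the three TSVs into ``out_dir``; returns name -> path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "transcripts": os.path.join(out_dir, "transcripts.tsv"),
        "isomirs": os.path.join(out_dir, "isomirs.tsv"),
        "novel": os.path.join(out_dir, "unannotated_loci.tsv"),
    }
    write_transcripts(transcript_rows, paths["transcripts"])
    write_isomirs(isomir_rows, paths["isomirs"])
    write_novel(novel_rows, paths["novel"])
    return paths


def read_transcripts(path: str) -> List[TranscriptRow]:
    """Parse a transcripts TSV back (round-trip support)."""
    rows: List[TranscriptRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRANSCRIPT_HEADER:
            raise ValueError(f"unexpected header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(
                TranscriptRow(f[0], f[1], f[2], float(f[3]), float(f[4]), int(f[5]), f[6])
            )
    return rows
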