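"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from srnaquant import alignments as aln
from srnaquant import simulate as sim
from srnaquant.pipeline import QuantifyConfig, quantify_groups, unique_baseline_counts
from srnaquant.reference import GenomicInterval, TranscriptRecord, TranscriptSet


@pytest.fixture
def gtf_file(tmp_path):
    """Three usable features (mature miRNA inside a precursor + a tRNA)."""
    lines = [
        'chr1\tsrc\texon\t100\t121\t.\t+\t.\tgene_id "g1"; transcript_id "mir-x"; gene_name "miR-x"; gene_biotype "miRNA";',
        'chr1\tsrc\texon\t90\t169\t.\t+\t.\tgene_id "g1p"; transcript_id "mir-x-pre"; gene_name "mir-x"; gene_biotype "pre_miRNA";',
        'chr1\tsrc\texon\t500\t580\t.\t-\t.\tgene_id "g2"; transcript_id "trna-1"; gene_name "tRNA-1"; gene_biotype "tRNA";',
    ]
    p = tmp_path / "ann.gtf"
    p.write_text("\n".join(lines) + "\n")
    return str(p)


def make_transcript(tid, chrom, start, end, strand="+", biotype="tRNA", name=None, seq=None):
    return TranscriptRecord(
        tid, f"g_{tid}", name or tid, biotype,
        GenomicInterval(chrom, start, end, strand), seq,
    )


@pytest.fixture
def sam_text_factory(tmp_path):
    """Write a minimal SAM from (qname, flag, chrom, pos1, seq, nm) rows."""

    def _write(rows, chrom_lengths={"chr1": 10000}):
        lines = ["@HD\tVN:1.6"]
        for c, ln in chrom_lengths.items():
            lines.append(f"@SQ\tSN:{c}\tLN:{ln}")
        for qname, flag, chrom, pos1, seq, nm in rows:
            if flag & 4:
                lines.append(f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*")
            else:
                lines.append(
                    f"{qname}\t{flag}\t{chrom}\t{pos1}\t255\t{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{nm}"
                )
        p = tmp_path / "aln.sam"
        p.write_text("\n".join(lines) + "\n")
        return str(p)

    return _write


@pytest.fixture(scope="session")
def benchmark_bundle(tmp_path_factory):
    """Seeded 10^4-read benchmark: reference, reads, truth, alignments.

    Session-scoped because simulation plus exhaustive alignment is the
    expensive part and several acceptance checks share it.
    """
    d = tmp_path_factory.mktemp("bench")
    ref = sim.generate_reference(seed=1)
    ab = sim.default_abundances(ref, seed=1)
    reads, truth = sim.simulate_reads(ref, sim.default_pmfs(), ab, n_reads=10_000, seed=1)
    sam = str(d / "aln.sam")
    gtf = str(d / "ann.gtf")
    tx = str(d / "tx.fa")
    sim.align_and_write_sam(reads, ref.genome, sam)
    sim.write_gtf(ref.transcripts, gtf)
    sim.write_transcript_fasta(ref.transcripts, tx)
    groups, unaligned = aln.parse_alignments(sam)
    return {
        "dir": d, "ref": ref, "reads": reads, "truth": truth,
        "sam": sam, "gtf": gtf, "tx": tx,
        "groups": groups, "unaligned": unaligned,
    }


@pytest.fixture(scope="session")
def benchmark_result(benchmark_bundle):
    """Full pipeline run on the benchmark fixture."""
    b = benchmark_bundle
    return quantify_groups(
        b["groups"], b["unaligned"], b["ref"].transcripts,
        b["ref"].transcript_sequences(), QuantifyConfig(),
        b["ref"].chrom_lengths(),
    )


@pytest.fixture(scope="session")
def baseline_counts(benchmark_bundle):
    b = benchmark_bundle
    return unique_baseline_counts(
        b["groups"], b["ref"].transcripts, chrom_lengths=b["ref"].chrom_lengths()
    )
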