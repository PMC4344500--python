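"""File-format plumbing: FASTQ, truth tables, SAM, VCF/TSV variant tables,
coverage tracks and variant profiles.

All formats are plain text.  The VCF writer emits a minimal VCF v4.2 with
AF/DP/ADF/ADR/GENE/CLASS INFO fields; the TSV mirror carries the same
columns for spreadsheet-friendly use.  SAM export represents an
origin-wrapping alignment as a single record whose aligned block is
truncated at the reference end with the remainder soft-clipped (the
in-memory :class:`~heteroseek.read_processing.Alignment` keeps the full
wrapped span).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .comparative_analysis import VariantProfile
from .read_processing import Alignment, CoverageProfile, Read
from .refmodel import ReferenceGenome, revcomp
from .variant_calling import VariantCall

__all__ = [
    "write_fastq",
    "read_fastq",
    "write_truth_table",
    "read_truth_table",
    "write_sam",
    "write_vcf",
    "write_calls_tsv",
    "read_profile_tsv",
    "write_coverage_tsv",
]


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=np.array(rec.letter_annotations["phred_quality"], dtype=np.int16),
            )
        )
    return reads


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sam(
    alignments: Sequence[Alignment],
    reads: Sequence[Read],
    ref: ReferenceGenome,
    path: str | Path,
) -> None:
    """Minimal SAM: header plus mtDNA-mapped records."""
    seq_of = {r.id: r for r in reads}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.name, "LN": ref.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            if a.maps_to != "mtDNA":
                continue
            r = seq_of[a.read_id]
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            oriented = r.sequence if a.strand == "+" else revcomp(r.sequence)
            seg.query_sequence = oriented
            quals = r.qualities if a.strand == "+" else r.qualities[::-1]
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(int(q) + 33) for q in quals)
            )
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = 0
            seg.reference_start = a.ref_start - 1
            aligned = min(a.matched_length, ref.length - (a.ref_start - 1))
            cigar = [(0, aligned)]
            if aligned < a.matched_length:  # wraps the origin: soft-clip the rest
                cigar.append((4, a.matched_length - aligned))
            seg.cigartuples = cigar
            seg.mapping_quality = 60
            seg.set_tag("NM", len(a.mismatches))
            out.write(seg)


def write_vcf(
    calls: Sequence[VariantCall], ref: ReferenceGenome, path: str | Path
) -> None:
    """Minimal VCF v4.2 variant table."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=heteroseek\n")
        fh.write(f"##contig=<ID={ref.name},length={ref.length}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Variant frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Non-clonal depth">\n')
        fh.write('##INFO=<ID=ADF,Number=1,Type=Integer,Description="Alt support, forward strand">\n')
        fh.write('##INFO=<ID=ADR,Number=1,Type=Integer,Description="Alt support, reverse strand">\n')
        fh.write('##INFO=<ID=GENE,Number=.,Type=String,Description="Overlapping gene(s)">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="transition or transversion">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.pos, c.alt)):
            gene = ",".join(c.genes) if c.genes else "."
            info = (
                f"AF={c.frequency:.6g};DP={c.depth};ADF={c.support_forward};"
                f"ADR={c.support_reverse};GENE={gene};CLASS={c.substitution_class}"
            )
            fh.write(f"{ref.name}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


_CALL_COLUMNS = [
    "pos", "ref", "alt", "frequency", "support_forward", "support_reverse",
    "depth", "genes", "substitution_class",
]


def write_calls_tsv(calls: Sequence[VariantCall], path: str | Path) -> None:
    rows = [
        {
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "frequency": c.frequency,
            "support_forward": c.support_forward,
            "support_reverse": c.support_reverse,
            "depth": c.depth,
            "genes": ",".join(c.genes),
            "substitution_class": c.substitution_class,
        }
        for c in sorted(calls, key=lambda c: (c.pos, c.alt))
    ]
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_profile_tsv(
    path: str | Path, sample_id: str, reference_name: str
) -> VariantProfile:
    """Load a variant profile from the flat TSV mirror."""
    df = pd.read_csv(path, sep="\t")
    freqs = {
        (int(r.pos), str(r.ref), str(r.alt)): float(r.frequency)
        for r in df.itertuples()
    }
    depths = {
        (int(r.pos), str(r.ref), str(r.alt)): int(r.depth) for r in df.itertuples()
    }
    return VariantProfile(
        sample_id=sample_id,
        reference_name=reference_name,
        frequencies=freqs,
        depths=depths,
    )


def write_coverage_tsv(profile: CoverageProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"pos": np.arange(1, len(profile.depth) + 1), "depth": profile.depth}
    ).to_csv(path, sep="\t", index=False)
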