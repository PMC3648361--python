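"""File I/O: FASTA via Biopython, simple GFF3 and BED writers.

Internal coordinates are 0-based half-open throughout the package; GFF3
output converts to 1-based closed, BED stays 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    """Write sequences as FASTA, 60 columns per line."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def gff3_line(
    seqid: str,
    source: str,
    ftype: str,
    start0: int,
    end0: int,
    strand: str = ".",
    score: str = ".",
    attributes: str = ".",
) -> str:
    """One GFF3 line from a 0-based half-open interval (converted to 1-based)."""
    return "\t".join(
        [seqid, source, ftype, str(start0 + 1), str(end0), score, strand, ".",
         attributes]
    )


def write_gff3(path: str | Path, lines: Iterable[str]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in lines:
            fh.write(line + "\n")


def write_bed(
    path: str | Path,
    intervals: Iterable[tuple[str, int, int, str]],
) -> None:
    """BED4: (chrom, start, end, name), 0-based half-open as given."""
    with open(path, "w") as fh:
        for chrom, s, e, name in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
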