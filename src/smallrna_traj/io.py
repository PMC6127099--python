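"""Thin wrappers around Biopython for the formats the pipeline touches."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {id: uppercase sequence}, preserving file order."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(recs, str(path), "fasta")


def iter_fastq_seqs(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercase) from a FASTQ file."""
    with open(path) as handle:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            yield seq.upper()


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs with constant Phred+33 'I' qualities."""
    with open(path, "w") as handle:
        for rid, seq in reads:
            handle.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
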