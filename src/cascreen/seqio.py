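"""Light-weight sequence I/O shared across the pipeline.

FASTQ parsing goes through Biopython's ``FastqGeneralIterator`` (the fast
tuple-based path), FASTA through ``Bio.SeqIO`` and SAM through ``pysam``.
Reads are carried around as plain named tuples so the hot loops stay cheap.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from cascreen.errors import InputError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FastqRead(NamedTuple):
    name: str
    seq: str
    qual: str  # Phred+33


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mean_quality(qual: str) -> float:
    """Arithmetic mean Phred score of a Phred+33 quality string."""
    if not qual:
        return 0.0
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
    return float(arr.mean()) - 33.0


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime=0 keeps gzip output byte-identical across reruns
            import io
            return io.TextIOWrapper(
                gzip.GzipFile(str(path), "wb", mtime=0), encoding="ascii")
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream a (optionally gzipped) FASTQ file as FastqRead tuples."""
    with _open_text(path) as handle:
        try:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                if len(seq) != len(qual):
                    raise InputError(
                        f"FASTQ record {i} ({title.split()[0]}): sequence and "
                        f"quality lengths differ"
                    )
                yield FastqRead(title.split()[0], seq.upper(), qual)
        except ValueError as exc:  # malformed record from the parser
            raise InputError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> int:
    """Write FastqRead tuples to ``path`` (gzipped if it ends in .gz)."""
    n = 0
    chunk: list[str] = []
    with _open_text(path, "wt") as handle:
        for read in reads:
            chunk.append(f"@{read.name}\n{read.seq}\n+\n{read.qual}\n")
            n += 1
            if len(chunk) == 10000:
                handle.write("".join(chunk))
                chunk.clear()
        handle.write("".join(chunk))
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (multi-record) FASTA file into an id -> sequence dict."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def reads_from_sam(path: str | Path) -> Iterator[FastqRead]:
    """Yield primary-alignment reads of a SAM/BAM file as FastqRead tuples.

    Sequences are reported in original read orientation (pysam's
    ``get_forward_sequence``), so downstream anchored extraction behaves
    identically for FASTQ and SAM input.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.get_forward_sequence()
            if seq is None:
                continue
            quals = rec.get_forward_qualities()
            if quals is None:
                qual = "I" * len(seq)
            else:
                qual = "".join(chr(q + 33) for q in quals)
            yield FastqRead(rec.query_name, seq.upper(), qual)
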