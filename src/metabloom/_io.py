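"""Small I/O helpers: transparent gzip handling, FASTA/FASTQ iteration."""

from __future__ import annotations

import gzip
import os
from typing import Iterator

from Bio import SeqIO

from .errors import InputError


def open_maybe_gzip(path: str | os.PathLike, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fasta(path) -> Iterator[tuple[str, str]]:
    with open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq).upper()


def iter_fastq(path) -> Iterator[tuple[str, str]]:
    with open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def iter_fastq_pairs(path1, path2) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, seq1, seq2); raises on mate-count mismatch."""
    it1, it2 = iter_fastq(path1), iter_fastq(path2)
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise InputError("paired FASTQ files have different read counts")
        rid = r1[0]
        for suffix in ("/1", ".1", "_1"):
            if rid.endswith(suffix):
                rid = rid[: -len(suffix)]
                break
        yield rid, r1[1], r2[1]


def write_fastq(path, records) -> None:
    """Write (read_id, seq) records with dummy top-quality scores."""
    with open_maybe_gzip(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(path, records) -> None:
    with open_maybe_gzip(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
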