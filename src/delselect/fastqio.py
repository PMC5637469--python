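"""FASTQ / FASTA I/O helpers (Phred+33, paired files).

Reading goes through Biopython's SeqIO; writing of simulated batches uses
a direct chunked writer because a full-depth sample is millions of
records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO

from . import _seq
from .reads import ReadPair


def write_fastq_batch(
    path: str | Path,
    seqs: np.ndarray,
    quality: int,
    id_prefix: str,
    chunk: int = 100_000,
) -> None:
    """Write an (n, read_len) code matrix as FASTQ with constant quality."""
    seqs = np.asarray(seqs, dtype=np.uint8)
    n, read_len = seqs.shape
    qline = chr(quality + 33) * read_len
    with open(path, "w") as fh:
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            decoded = _seq.decode_matrix(seqs[lo:hi])
            fh.write(
                "".join(
                    f"@{id_prefix}:{i}\n{s}\n+\n{qline}\n"
                    for i, s in zip(range(lo, hi), decoded.tolist())
                )
            )


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Parse two mate FASTQ files (matched record order) into ReadPairs."""
    pairs = []
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        pairs.append(
            ReadPair(
                r1_seq=str(rec1.seq),
                r2_seq=str(rec2.seq),
                r1_qual=np.array(rec1.letter_annotations["phred_quality"]),
                r2_qual=np.array(rec2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def read_fastq_matrices(
    r1_path: str | Path, r2_path: str | Path
) -> tuple[np.ndarray, np.ndarray]:
    """Parse paired FASTQ into two equal-width code matrices.

    Requires uniform read length per mate (the simulator's output and
    typical raw Illumina data satisfy this).
    """
    def load(path: str | Path) -> np.ndarray:
        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
        if not seqs:
            raise ValueError(f"no reads in {path}")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"reads in {path} are not of uniform length")
        return _seq.encode_many(seqs, lengths.pop())

    m1, m2 = load(r1_path), load(r2_path)
    if m1.shape[0] != m2.shape[0]:
        raise ValueError("mate files contain different numbers of reads")
    return m1, m2


def write_fasta(path: str | Path, names, seqs) -> None:
    """Minimal FASTA writer for consensus/template exports."""
    with open(path, "w") as fh:
        for name, seq in zip(names, seqs):
            fh.write(f">{name}\n{seq}\n")
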