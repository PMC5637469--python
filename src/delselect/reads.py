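"""Paired-end read simulation, overlap merging and barcode extraction.

These are the per-read reference implementations: direct, loop-based, and
deliberately simple so they double as the oracle for the vectorised batch
engine in :mod:`delselect.bulk`.  Read 1 sequences the template strand
5'->3'; read 2 sequences the reverse complement.  Because the insert
(48 nt by default) is shorter than the read length (75 nt by default),
both reads run through into the adapter on the far side; merging clips
the adapters implicitly by reconstructing only the insert.

The error model is substitution-only with i.i.d. per-base errors, which
matches the substitution-dominant Illumina profile; indels are not
modelled (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .library import LibraryArchitecture

#: Illumina TruSeq adapter read-through stubs: what a read sees after
#: running off the 3' end of the insert (R1) or the 5' end (R2).
DEFAULT_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
DEFAULT_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"

DEFAULT_READ_LEN = 75
DEFAULT_QUALITY = 30
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_FRAC = 0.10
DEFAULT_MAX_PRIMER_MISMATCH = 1

MERGED = "merged"
NO_OVERLAP = "no_overlap"
TOO_MANY_MISMATCHES = "too_many_mismatches"


@dataclass
class ReadPair:
    """One simulated or parsed read pair (sequences + Phred qualities)."""

    r1_seq: str
    r2_seq: str
    r1_qual: np.ndarray
    r2_qual: np.ndarray
    origin_barcode: str | None = None

    def __post_init__(self) -> None:
        self.r1_qual = np.asarray(self.r1_qual, dtype=np.int16)
        self.r2_qual = np.asarray(self.r2_qual, dtype=np.int16)
        if len(self.r1_seq) != self.r1_qual.size:
            raise ValueError("r1 sequence/quality length mismatch")
        if len(self.r2_seq) != self.r2_qual.size:
            raise ValueError("r2 sequence/quality length mismatch")
        for qual in (self.r1_qual, self.r2_qual):
            if qual.size and not (2 <= qual.min() and qual.max() <= 41):
                raise ValueError("Phred scores must lie in [2, 41]")


@dataclass
class MergeResult:
    """Outcome of merging one pair: status, consensus insert, overlap."""

    status: str
    consensus: str | None
    overlap_len: int


@dataclass(frozen=True)
class BarcodeRejection:
    """Why a merged consensus yielded no usable barcode."""

    reason: str  # primer5_not_found | primer3_not_found | bad_barcode_length


def simulate_read_pair(
    template: str,
    read_len: int = DEFAULT_READ_LEN,
    error_rate: float = 0.001,
    adapters: tuple[str, str] = (DEFAULT_ADAPTER_R1, DEFAULT_ADAPTER_R2),
    seed: int | np.random.Generator | None = None,
    quality: int = DEFAULT_QUALITY,
    origin_barcode: str | None = None,
) -> ReadPair:
    """Simulate one Illumina-like pair from a template.

    R1 reads the template 5'->3' and, past its end, the R1 adapter
    (read-through); R2 reads the reverse complement and then the R2
    adapter.  Substitution errors are applied i.i.d. per base at
    ``error_rate``; qualities are constant ``quality``.
    """
    if not template:
        raise ValueError("template must be non-empty")
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    if not (0.0 <= error_rate <= 0.25):
        raise ValueError("error_rate must lie in [0, 0.25]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def build(strand: str, adapter: str) -> np.ndarray:
        full = strand + adapter
        if len(full) < read_len:  # past the adapter: pad (undefined cycles)
            full = full + "A" * (read_len - len(full))
        codes = _seq.encode(full[:read_len])
        err = rng.random(read_len) < error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            codes = codes.copy()
            codes[err] = (codes[err] + shift) % 4
        return codes

    r1 = build(template, adapters[0])
    r2 = build(_seq.revcomp(template), adapters[1])
    qual = np.full(read_len, quality, dtype=np.int16)
    return ReadPair(
        r1_seq=_seq.decode(r1),
        r2_seq=_seq.decode(r2),
        r1_qual=qual,
        r2_qual=qual.copy(),
        origin_barcode=origin_barcode,
    )


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> MergeResult:
    """Merge one pair by exhaustive overlap scanning.

    Every candidate insert length L from ``min_overlap`` to
    ``len(r1) + len(r2) - min_overlap`` is scored (this includes the
    short-insert regime where both reads run through into adapter).  Among
    candidates whose overlap mismatch fraction is within
    ``max_mismatch_frac``, the one maximising the number of matching
    bases wins (ties: larger overlap, then smaller L).  The consensus
    takes the higher-quality base at each disagreeing overlap position,
    ties going to read 1.

    If no candidate passes the mismatch threshold the status is
    ``too_many_mismatches`` when some candidate still matched at least
    ``min_overlap * (1 - max_mismatch_frac)`` bases, else ``no_overlap``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    r1 = _seq.encode(pair.r1_seq)
    r2rc = _seq.revcomp_matrix(_seq.encode(pair.r2_seq).reshape(1, -1))[0]
    q1 = pair.r1_qual
    q2r = pair.r2_qual[::-1]  # quality of r2rc position j is q2 reversed
    len1, len2 = r1.size, r2rc.size

    best_pass: tuple[int, int, int] | None = None  # (matches, overlap, -L)
    best_pass_L = -1
    best_any_matches = 0
    for L in range(min_overlap, len1 + len2 - min_overlap + 1):
        off = L - len2
        a, b = max(0, off), min(len1, L)
        ov = b - a
        if ov < min_overlap:
            continue
        matches = int(np.count_nonzero(r1[a:b] == r2rc[a - off : b - off]))
        best_any_matches = max(best_any_matches, matches)
        if (ov - matches) <= max_mismatch_frac * ov:
            key = (matches, ov, -L)
            if best_pass is None or key > best_pass:
                best_pass = key
                best_pass_L = L

    if best_pass is None:
        if best_any_matches >= min_overlap * (1.0 - max_mismatch_frac):
            return MergeResult(TOO_MANY_MISMATCHES, None, 0)
        return MergeResult(NO_OVERLAP, None, 0)

    L = best_pass_L
    off = L - len2
    cons = np.empty(L, dtype=np.uint8)
    for pos in range(L):
        in1 = pos < len1
        j = pos - off
        in2 = 0 <= j < len2
        if in1 and in2:
            cons[pos] = r1[pos] if q1[pos] >= q2r[j] else r2rc[j]
        elif in1:
            cons[pos] = r1[pos]
        else:
            cons[pos] = r2rc[j]
    return MergeResult(MERGED, _seq.decode(cons), best_pass[1])


def _best_primer_hit(
    cons: np.ndarray, primer: np.ndarray, start: int
) -> tuple[int, int]:
    """Leftmost minimum-mismatch placement of primer in cons[start:].

    Returns (position, mismatches); position -1 if the primer cannot fit.
    """
    last = cons.size - primer.size
    if last < start:
        return -1, primer.size + 1
    best_pos, best_mm = -1, primer.size + 1
    for s in range(start, last + 1):
        mm = int(np.count_nonzero(cons[s : s + primer.size] != primer))
        if mm < best_mm:
            best_pos, best_mm = s, mm
    return best_pos, best_mm


def extract_barcode(
    consensus: str,
    arch: LibraryArchitecture,
    max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH,
) -> str | BarcodeRejection:
    """Excise the encoding barcode from a merged consensus.

    Both primers are located by leftmost minimum-mismatch placement
    (substitutions only, no indels), primer3 strictly after primer5.  The
    enclosed region is returned iff its length equals the architecture's
    barcode length; otherwise a :class:`BarcodeRejection` explains which
    anchor failed.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    cons = _seq.encode(consensus)
    p5 = _seq.encode(arch.primer5)
    p3 = _seq.encode(arch.primer3)

    pos5, mm5 = _best_primer_hit(cons, p5, 0)
    if pos5 < 0 or mm5 > max_primer_mismatch:
        return BarcodeRejection("primer5_not_found")
    bc_start = pos5 + p5.size
    pos3, mm3 = _best_primer_hit(cons, p3, bc_start)
    if pos3 < 0 or mm3 > max_primer_mismatch:
        return BarcodeRejection("primer3_not_found")
    if pos3 - bc_start != arch.barcode_length:
        return BarcodeRejection("bad_barcode_length")
    return _seq.decode(cons[bc_start:pos3])
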