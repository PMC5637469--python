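"""Encoding-DNA architecture and synthetic pre-selection libraries.

The selection template is a short single-stranded DNA of the form

    5'-primer — encoding barcode — 3'-primer

(18 + 12 + 18 nt = 48 nt by default).  The 12 nt randomised region encodes
the attached small molecule; a known-active positive control ("spike-in")
carries an EcoRV recognition site inside its barcode so that its abundance
can also be read out by restriction digest.  This module builds
architectures, assembles templates, and generates pre-selection library
tables in which the spike-in is diluted into a pool of inactive members.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _seq

#: Default 18 nt primer-binding sites.  Only the length and role of the
#: primers matter to the model; these are fixed GC-balanced sequences that
#: contain no EcoRV site and are overridable in every entry point.
DEFAULT_PRIMER5 = "ACGCTAGCTGGCAATCGT"
DEFAULT_PRIMER3 = "CAGTTCGACCAGTTGGCA"

#: EcoRV recognition sequence (blunt cutter, GAT^ATC).
ECORV_SITE = "GATATC"

#: Default positive-control barcode: EcoRV site centred at offset 3 of the
#: 12 nt encoding region.
DEFAULT_SPIKE_BARCODE = "ACCGATATCTGG"

CLASS_CATALYST = "catalyst"
CLASS_INACTIVE = "inactive"


@dataclass(frozen=True)
class LibraryArchitecture:
    """Layout of the encoding template and the spike-in definition.

    Parameters
    ----------
    primer5, primer3:
        Constant primer-binding sites flanking the encoding region.
    barcode_length:
        Length of the randomised encoding region in nucleotides.
    spike_barcode:
        Barcode of the known-active positive control.
    digest_site, digest_site_offset:
        Restriction-enzyme recognition sequence carried by the spike-in
        and its 0-based offset within the spike barcode.
    """

    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    barcode_length: int = 12
    spike_barcode: str = DEFAULT_SPIKE_BARCODE
    digest_site: str = ECORV_SITE
    digest_site_offset: int = 3

    def __post_init__(self) -> None:
        for name in ("primer5", "primer3", "spike_barcode", "digest_site"):
            seq = getattr(self, name)
            if not _seq.is_dna(seq):
                raise ValueError(f"{name} must contain only A/C/G/T, got {seq!r}")
        if self.barcode_length < 0:
            raise ValueError("barcode_length must be non-negative")
        if len(self.spike_barcode) != self.barcode_length:
            raise ValueError(
                f"spike barcode length {len(self.spike_barcode)} != "
                f"barcode_length {self.barcode_length}"
            )
        off = self.digest_site_offset
        end = off + len(self.digest_site)
        if not (0 <= off and end <= self.barcode_length):
            raise ValueError("digest site does not fit in the barcode at that offset")
        if self.spike_barcode[off:end] != self.digest_site:
            raise ValueError(
                "digest_site does not occur in spike_barcode at digest_site_offset"
            )

    @property
    def template_length(self) -> int:
        return len(self.primer5) + self.barcode_length + len(self.primer3)

    def assemble(self, barcode: str) -> str:
        return assemble_template(self, barcode)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return {
            "primer5": self.primer5,
            "primer3": self.primer3,
            "barcode_length": self.barcode_length,
            "spike_barcode": self.spike_barcode,
            "digest_site": self.digest_site,
            "digest_site_offset": self.digest_site_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryArchitecture":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LibraryArchitecture":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Miniature architecture for tests and fixtures: 6 nt primers around a
#: 2 nt encoding region, with a 2 nt stand-in "digest site".
TINY_ARCHITECTURE = LibraryArchitecture(
    primer5="ACGTCA",
    primer3="TCACGT",
    barcode_length=2,
    spike_barcode="GA",
    digest_site="GA",
    digest_site_offset=0,
)


@dataclass
class LibraryTable:
    """Pre-selection pool: barcode -> (class, frequency).

    Rows are kept in a canonical deterministic order (background barcodes
    sorted lexicographically, spike-in appended last by :func:`spike_in`).
    Frequencies always sum to 1 within 1e-12.
    """

    barcodes: np.ndarray
    classes: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes)
        self.classes = np.asarray(self.classes)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if not (len(self.barcodes) == len(self.classes) == len(self.frequencies)):
            raise ValueError("column lengths differ")

    def __len__(self) -> int:
        return len(self.barcodes)

    def validate(self, barcode_length: int | None = None) -> None:
        if len(self) == 0:
            return
        if np.unique(self.barcodes).size != len(self):
            raise ValueError("duplicate barcodes in library table")
        lengths = {len(b) for b in self.barcodes.tolist()}
        if len(lengths) > 1:
            raise ValueError("barcodes of mixed length")
        if barcode_length is not None and lengths and lengths != {barcode_length}:
            raise ValueError(f"barcode length {lengths} != expected {barcode_length}")
        bad = set(self.classes.tolist()) - {CLASS_CATALYST, CLASS_INACTIVE}
        if bad:
            raise ValueError(f"unknown classes {bad}")
        if np.any(self.frequencies < 0):
            raise ValueError("negative frequency")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {self.frequencies.sum()!r}, not 1")

    def index_of(self, barcode: str) -> int:
        hits = np.flatnonzero(self.barcodes == barcode)
        if hits.size == 0:
            raise KeyError(barcode)
        return int(hits[0])

    def frequency_of(self, barcode: str) -> float:
        return float(self.frequencies[self.index_of(barcode)])

    def class_of(self, barcode: str) -> str:
        return str(self.classes[self.index_of(barcode)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "class": self.classes,
                "frequency": self.frequencies,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LibraryTable":
        df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
        return cls(
            barcodes=df["barcode"].to_numpy(),
            classes=df["class"].to_numpy(),
            frequencies=df["frequency"].to_numpy(dtype=float),
        )

    def to_fasta(self, arch: LibraryArchitecture, path: str | Path) -> None:
        """Write every member's assembled template as FASTA (id = barcode)."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(assemble_template(arch, b)), id=str(b), description=str(c))
            for b, c in zip(self.barcodes.tolist(), self.classes.tolist())
        ]
        seqio_write(records, str(path), "fasta")


def barcode_space_size(length: int) -> int:
    """Number of distinct DNA barcodes of the given length (4**length).

    A 12 nt encoding region addresses 16,777,216 molecules — the "greater
    than 16 million" capacity of the default architecture.
    """
    if length < 0:
        raise ValueError("barcode length must be non-negative")
    return 4**length


def assemble_template(arch: LibraryArchitecture, barcode: str) -> str:
    """Concatenate primer5 + barcode + primer3 into the full template."""
    if len(barcode) != arch.barcode_length:
        raise ValueError(
            f"barcode length {len(barcode)} != architecture length {arch.barcode_length}"
        )
    if not _seq.is_dna(barcode):
        raise ValueError(f"barcode must contain only A/C/G/T, got {barcode!r}")
    return arch.primer5 + barcode + arch.primer3


def templates_matrix(arch: LibraryArchitecture, barcodes) -> np.ndarray:
    """2-bit code matrix of assembled templates, one row per barcode."""
    barcodes = np.asarray(barcodes)
    n = len(barcodes)
    p5 = _seq.encode(arch.primer5)
    p3 = _seq.encode(arch.primer3)
    bc = _seq.encode_many(barcodes.tolist(), arch.barcode_length)
    out = np.empty((n, arch.template_length), dtype=np.uint8)
    out[:, : p5.size] = p5
    out[:, p5.size : p5.size + arch.barcode_length] = bc
    out[:, p5.size + arch.barcode_length :] = p3
    return out


def _sample_distinct_codes(
    rng: np.random.Generator, space: int, n: int, exclude: int
) -> np.ndarray:
    """Uniform sample of n distinct integers from [0, space) \\ {exclude}.

    Sequential-rejection sampling, vectorised: draws are processed in order
    of first occurrence, which makes the subset uniform over all
    n-subsets and fully determined by the generator state.
    """
    chosen: list[np.ndarray] = []
    seen = np.zeros(0, dtype=np.int64)
    need = n
    while need > 0:
        batch = rng.integers(0, space, size=max(2 * need, 64), dtype=np.int64)
        batch = batch[batch != exclude]
        # first occurrence order within the batch
        _, first_idx = np.unique(batch, return_index=True)
        fresh = batch[np.sort(first_idx)]
        if seen.size:
            fresh = fresh[~np.isin(fresh, seen)]
        take = fresh[:need]
        chosen.append(take)
        seen = np.concatenate([seen, take])
        need = n - seen.size
    return np.sort(np.concatenate(chosen))


def generate_library(
    arch: LibraryArchitecture, n_background: int, seed: int
) -> LibraryTable:
    """Generate a background-only library of distinct inactive barcodes.

    Barcodes are a uniform sample (without replacement) from the 4**L
    space, excluding the spike barcode, each at uniform frequency.  The
    result is canonical (lexicographically sorted) and deterministic for a
    given seed.
    """
    space = barcode_space_size(arch.barcode_length)
    if not (0 <= n_background <= space - 1):
        raise ValueError(
            f"n_background={n_background} outside [0, {space - 1}] "
            f"for barcode_length={arch.barcode_length}"
        )
    if n_background == 0:
        return LibraryTable(
            barcodes=np.empty(0, dtype=f"U{max(arch.barcode_length, 1)}"),
            classes=np.empty(0, dtype="U8"),
            frequencies=np.empty(0, dtype=float),
        )
    rng = np.random.default_rng(seed)
    spike_code = int(
        _seq.pack(_seq.encode(arch.spike_barcode).reshape(1, -1))[0]
    )
    codes = _sample_distinct_codes(rng, space, n_background, spike_code)
    barcodes = _seq.decode_matrix(_seq.unpack(codes, arch.barcode_length))
    table = LibraryTable(
        barcodes=barcodes,
        classes=np.full(n_background, CLASS_INACTIVE, dtype="U8"),
        frequencies=np.full(n_background, 1.0 / n_background),
    )
    table.validate(arch.barcode_length)
    return table


def enumerate_library(arch: LibraryArchitecture) -> LibraryTable:
    """Background library over the *entire* barcode space minus the spike.

    Practical only for short encoding regions (full N12 enumeration is
    16.7M rows); used by tests and the tiny fixtures.
    """
    space = barcode_space_size(arch.barcode_length)
    codes = np.arange(space, dtype=np.int64)
    spike_code = int(_seq.pack(_seq.encode(arch.spike_barcode).reshape(1, -1))[0])
    codes = codes[codes != spike_code]
    barcodes = _seq.decode_matrix(_seq.unpack(codes, arch.barcode_length))
    n = len(barcodes)
    return LibraryTable(
        barcodes=barcodes,
        classes=np.full(n, CLASS_INACTIVE, dtype="U8"),
        frequencies=np.full(n, 1.0 / n),
    )


def spike_in(
    library: LibraryTable, arch: LibraryArchitecture, dilution: float
) -> LibraryTable:
    """Dilute the positive control into the background library.

    The spike barcode enters at frequency 1/dilution (class ``catalyst``);
    background frequencies are rescaled by (1 - 1/dilution) so the table
    still sums to 1.  A 500-fold dilution gives spike frequency 0.002, a
    2000-fold dilution 0.0005.
    """
    if dilution < 1:
        raise ValueError("dilution must be >= 1")
    if np.any(library.barcodes == arch.spike_barcode):
        raise ValueError("spike barcode already present in library")
    f0 = 1.0 / dilution
    bl = max(arch.barcode_length, 1)
    barcodes = np.concatenate(
        [library.barcodes.astype(f"U{bl}"), np.array([arch.spike_barcode], dtype=f"U{bl}")]
    )
    classes = np.concatenate(
        [library.classes.astype("U8"), np.array([CLASS_CATALYST], dtype="U8")]
    )
    frequencies = np.concatenate([library.frequencies * (1.0 - f0), [f0]])
    table = LibraryTable(barcodes=barcodes, classes=classes, frequencies=frequencies)
    table.validate(arch.barcode_length)
    return table


def pooled_background_library(
    arch: LibraryArchitecture, pooled_barcode: str | None = None
) -> LibraryTable:
    """Aggregate two-class library: all background mass on one barcode.

    The marginal behaviour of the spike-in under selection and multinomial
    sequencing depends only on the spike's weight, so this pooled table is
    statistically exchangeable with an enumerated background for spike-in
    analyses while being constant-memory.
    """
    if pooled_barcode is None:
        pooled_barcode = "A" * arch.barcode_length
    if pooled_barcode == arch.spike_barcode:
        raise ValueError("pooled barcode collides with the spike barcode")
    return LibraryTable(
        barcodes=np.array([pooled_barcode], dtype=f"U{max(arch.barcode_length,1)}"),
        classes=np.array([CLASS_INACTIVE], dtype="U8"),
        frequencies=np.array([1.0]),
    )
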