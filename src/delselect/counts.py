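"""Barcode count tables (the sequencing readout currency of the pipeline)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountTable:
    """Mapping barcode -> non-negative read count.

    Rows are kept sorted lexicographically by barcode so that identical
    counting runs produce byte-identical TSV output.
    """

    barcodes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.barcodes) != len(self.counts):
            raise ValueError("column lengths differ")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("negative count")
        if np.unique(self.barcodes).size != len(self.barcodes):
            raise ValueError("duplicate barcodes in count table")

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, barcode: str, default: int = 0) -> int:
        hits = np.flatnonzero(self.barcodes == barcode)
        return int(self.counts[hits[0]]) if hits.size else default

    def frequencies(self) -> np.ndarray:
        total = self.total
        if total == 0:
            raise ValueError("empty count table has no frequencies")
        return self.counts / total

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.barcodes)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "CountTable":
        barcodes = np.array(sorted(d), dtype=object).astype(str)
        counts = np.array([d[b] for b in barcodes.tolist()], dtype=np.int64)
        return cls(barcodes=barcodes, counts=counts)

    def to_dict(self) -> dict[str, int]:
        return dict(zip(self.barcodes.tolist(), self.counts.tolist()))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"barcode": self.barcodes, "count": self.counts}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
        order = np.argsort(df["barcode"].to_numpy())
        return cls(
            barcodes=df["barcode"].to_numpy()[order],
            counts=df["count"].to_numpy(dtype=np.int64)[order],
        )
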