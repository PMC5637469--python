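"""Run configuration: one YAML document drives the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .library import LibraryArchitecture
from .reads import (
    DEFAULT_ADAPTER_R1,
    DEFAULT_ADAPTER_R2,
    DEFAULT_MAX_MISMATCH_FRAC,
    DEFAULT_MAX_PRIMER_MISMATCH,
    DEFAULT_MIN_OVERLAP,
    DEFAULT_QUALITY,
    DEFAULT_READ_LEN,
)
from .selection import SelectionParams


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one end-to-end mock-selection run.

    Defaults reproduce the sequencing mock selection: a 10^5-member
    background library, spike-in diluted 2000-fold, survival
    probabilities 0.30 / 1e-4 (ratio 3000), 10^6 read pairs per sample at
    2x75 nt with 0.1% substitution error.
    """

    architecture: LibraryArchitecture = field(default_factory=LibraryArchitecture)
    n_background: int = 100_000
    dilution: float = 2000.0
    selection: SelectionParams = field(default_factory=SelectionParams)
    read_len: int = DEFAULT_READ_LEN
    error_rate: float = 0.001
    adapters: tuple[str, str] = (DEFAULT_ADAPTER_R1, DEFAULT_ADAPTER_R2)
    quality: int = DEFAULT_QUALITY
    min_overlap: int = DEFAULT_MIN_OVERLAP
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC
    max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH
    pseudocount: float = 0.5
    outdir: Path | None = None
    write_reads: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")
        if self.read_len <= 0:
            raise ValueError("read_len must be positive")
        if not (0.0 <= self.error_rate <= 0.25):
            raise ValueError("error_rate must lie in [0, 0.25]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not (0.0 <= self.max_mismatch_frac < 1.0):
            raise ValueError("max_mismatch_frac must lie in [0, 1)")
        if self.max_primer_mismatch < 0:
            raise ValueError("max_primer_mismatch must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not (2 <= self.quality <= 41):
            raise ValueError("quality must be a Phred score in [2, 41]")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture.to_dict(),
            "library": {
                "n_background": self.n_background,
                "dilution": self.dilution,
            },
            "selection": {
                "p_cat": self.selection.p_cat,
                "p_bg": self.selection.p_bg,
                "depth_pre": self.selection.depth_pre,
                "depth_post": self.selection.depth_post,
            },
            "reads": {
                "read_len": self.read_len,
                "error_rate": self.error_rate,
                "adapter_r1": self.adapters[0],
                "adapter_r2": self.adapters[1],
                "quality": self.quality,
            },
            "analysis": {
                "pseudocount": self.pseudocount,
                "max_primer_mismatch": self.max_primer_mismatch,
                "min_overlap": self.min_overlap,
                "max_mismatch_frac": self.max_mismatch_frac,
            },
            "io": {
                "outdir": str(self.outdir) if self.outdir else None,
                "write_reads": self.write_reads,
            },
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        arch = (
            LibraryArchitecture.from_dict(d["architecture"])
            if "architecture" in d
            else LibraryArchitecture()
        )
        lib = d.get("library", {})
        sel = d.get("selection", {})
        rds = d.get("reads", {})
        ana = d.get("analysis", {})
        io = d.get("io", {})
        defaults = cls()
        return cls(
            architecture=arch,
            n_background=lib.get("n_background", defaults.n_background),
            dilution=lib.get("dilution", defaults.dilution),
            selection=SelectionParams(
                p_cat=sel.get("p_cat", defaults.selection.p_cat),
                p_bg=sel.get("p_bg", defaults.selection.p_bg),
                depth_pre=sel.get("depth_pre", defaults.selection.depth_pre),
                depth_post=sel.get("depth_post", defaults.selection.depth_post),
            ),
            read_len=rds.get("read_len", defaults.read_len),
            error_rate=rds.get("error_rate", defaults.error_rate),
            adapters=(
                rds.get("adapter_r1", defaults.adapters[0]),
                rds.get("adapter_r2", defaults.adapters[1]),
            ),
            quality=rds.get("quality", defaults.quality),
            min_overlap=ana.get("min_overlap", defaults.min_overlap),
            max_mismatch_frac=ana.get(
                "max_mismatch_frac", defaults.max_mismatch_frac
            ),
            max_primer_mismatch=ana.get(
                "max_primer_mismatch", defaults.max_primer_mismatch
            ),
            pseudocount=ana.get("pseudocount", defaults.pseudocount),
            outdir=Path(io["outdir"]) if io.get("outdir") else None,
            write_reads=io.get("write_reads", defaults.write_reads),
            seed=d.get("seed", defaults.seed),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
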