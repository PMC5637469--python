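"""Per-barcode fold enrichment and the in-silico restriction-digest readout.

Fold enrichment is the frequency ratio post/pre, the quantity the
selection experiment is scored on.  Counts are optionally smoothed with a
pseudocount (Haldane–Anscombe 0.5 by default) so members unobserved in
one sample still get a finite, flagged estimate; a 95% normal interval on
the log ratio accompanies each point estimate.  The restriction-digest
"gel" is emulated as the fraction of molecules whose assembled template
contains the recognition site — the same underlying frequency the gel
band quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _seq
from .counts import CountTable
from .library import LibraryArchitecture, templates_matrix


@dataclass
class EnrichmentRecord:
    """Pre/post observations and the enrichment estimate for one barcode."""

    barcode: str
    pre_count: int
    post_count: int
    pre_freq: float
    post_freq: float
    enrichment: float
    ci_low: float
    ci_high: float
    has_digest_site: bool
    absent_pre: bool


_COLUMNS = [
    "barcode",
    "pre_count",
    "post_count",
    "pre_freq",
    "post_freq",
    "enrichment",
    "ci_low",
    "ci_high",
    "has_digest_site",
    "absent_pre",
]


def digest_site_flags(arch: LibraryArchitecture, barcodes) -> np.ndarray:
    """True where a barcode's *assembled template* contains the digest site.

    The whole template is scanned, so a background barcode that spuriously
    creates the site (inside the barcode or across a primer junction) is
    flagged too.
    """
    barcodes = np.asarray(barcodes)
    if barcodes.size == 0:
        return np.zeros(0, dtype=bool)
    mat = templates_matrix(arch, barcodes)
    site = _seq.encode(arch.digest_site)
    k = site.size
    hits = np.zeros(barcodes.size, dtype=bool)
    for s in range(mat.shape[1] - k + 1):
        hits |= (mat[:, s : s + k] == site).all(axis=1)
    return hits


def enrichment_table(
    pre: CountTable,
    post: CountTable,
    pseudocount: float = 0.5,
    arch: LibraryArchitecture | None = None,
) -> pd.DataFrame:
    """Vectorised enrichment computation over the union of both tables.

    Smoothed frequency of barcode i in a sample with total n and K union
    barcodes is (count_i + a) / (n + a*K); enrichment is the post/pre
    ratio of those.  With pseudocount 0 a barcode absent pre-selection
    gets an infinite estimate and is flagged rather than dropped.
    Records are sorted by descending enrichment (ties: barcode).
    """
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("both count tables must be non-empty")
    if pre.total == 0 or post.total == 0:
        raise ValueError("count tables must have positive totals")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    a = float(pseudocount)

    union = np.union1d(pre.barcodes, post.barcodes)
    k = union.size
    pre_counts = pre.as_series().reindex(union, fill_value=0).to_numpy(dtype=np.int64)
    post_counts = post.as_series().reindex(union, fill_value=0).to_numpy(dtype=np.int64)

    n1 = pre.total + a * k
    n2 = post.total + a * k
    sa = pre_counts + a  # smoothed counts
    sb = post_counts + a
    pre_freq = sa / n1
    post_freq = sb / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(pre_freq > 0, post_freq / pre_freq, np.inf)
        enr = np.where(post_freq == 0, 0.0, enr)
        # normal approximation on log(ratio) using smoothed counts
        var = np.where(
            (sa > 0) & (sb > 0), 1.0 / sa - 1.0 / n1 + 1.0 / sb - 1.0 / n2, np.nan
        )
        half = 1.96 * np.sqrt(np.maximum(var, 0.0))
        log_e = np.where((enr > 0) & np.isfinite(enr), np.log(enr), np.nan)
        ci_low = np.exp(log_e - half)
        ci_high = np.exp(log_e + half)

    flags = (
        digest_site_flags(arch, union)
        if arch is not None
        else np.zeros(k, dtype=bool)
    )
    df = pd.DataFrame(
        {
            "barcode": union,
            "pre_count": pre_counts,
            "post_count": post_counts,
            "pre_freq": pre_freq,
            "post_freq": post_freq,
            "enrichment": enr,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "has_digest_site": flags,
            "absent_pre": pre_counts == 0,
        }
    )
    # descending enrichment, barcode as deterministic tie-break
    order = np.lexsort((df["barcode"].to_numpy(), -df["enrichment"].to_numpy()))
    return df.iloc[order].reset_index(drop=True)


def fold_enrichment(
    pre: CountTable,
    post: CountTable,
    pseudocount: float = 0.5,
    arch: LibraryArchitecture | None = None,
) -> list[EnrichmentRecord]:
    """Per-barcode enrichment records (see :func:`enrichment_table`)."""
    df = enrichment_table(pre, post, pseudocount, arch)
    return [
        EnrichmentRecord(
            barcode=str(row.barcode),
            pre_count=int(row.pre_count),
            post_count=int(row.post_count),
            pre_freq=float(row.pre_freq),
            post_freq=float(row.post_freq),
            enrichment=float(row.enrichment),
            ci_low=float(row.ci_low),
            ci_high=float(row.ci_high),
            has_digest_site=bool(row.has_digest_site),
            absent_pre=bool(row.absent_pre),
        )
        for row in df.itertuples(index=False)
    ]


def digest_fraction(table: CountTable, arch: LibraryArchitecture) -> float:
    """Fraction of molecules whose template carries the digest site.

    This is the in-silico analogue of quantifying the cut band on a
    restriction-digest gel; invariant under uniform scaling of counts.
    """
    if len(table) == 0 or table.total == 0:
        raise ValueError("count table must be non-empty")
    flags = digest_site_flags(arch, table.barcodes)
    return float(table.counts[flags].sum() / table.total)


@dataclass
class EnrichmentReport:
    """Full enrichment table plus the run summary (in-silico gel included)."""

    table: pd.DataFrame
    summary: dict
    metadata: dict

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def summary_to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"summary": self.summary, "metadata": self.metadata},
                fh,
                sort_keys=True,
            )


def spike_rank(df: pd.DataFrame, spike_barcode: str) -> int | None:
    """1-based enrichment rank of the spike among barcodes observed pre.

    Barcodes absent from the pre-selection sample have no defined
    frequency ratio (infinite under pseudocount 0) and are excluded from
    the ranking.
    """
    present = df[~df["absent_pre"]].reset_index(drop=True)
    hits = np.flatnonzero(present["barcode"].to_numpy() == spike_barcode)
    return int(hits[0]) + 1 if hits.size else None


def enrichment_report(
    records: pd.DataFrame | list[EnrichmentRecord],
    pre_digest: float,
    post_digest: float,
    spike_barcode: str | None = None,
    metadata: dict | None = None,
) -> EnrichmentReport:
    """Assemble the deterministic end-of-run report.

    The summary carries the spike's enrichment and rank (when a spike
    barcode is given) and the pre/post digest-site fractions — the
    in-silico counterpart of the gel readout.  Regenerating the report
    from the same inputs yields byte-identical TSV/YAML output.
    """
    if isinstance(records, list):
        if not records:
            raise ValueError("no enrichment records")
        df = pd.DataFrame([r.__dict__ for r in records])[_COLUMNS]
    else:
        if records.empty:
            raise ValueError("no enrichment records")
        df = records[_COLUMNS].copy()

    summary: dict = {
        "n_barcodes": int(len(df)),
        "digest_fraction_pre": float(pre_digest),
        "digest_fraction_post": float(post_digest),
        "digest_fold_change": (
            float(post_digest / pre_digest) if pre_digest > 0 else None
        ),
        "top_barcode": str(df.iloc[0]["barcode"]),
        "top_enrichment": float(df.iloc[0]["enrichment"]),
    }
    if spike_barcode is not None:
        hits = np.flatnonzero(df["barcode"].to_numpy() == spike_barcode)
        if hits.size:
            row = df.iloc[int(hits[0])]
            summary.update(
                spike_barcode=spike_barcode,
                spike_pre_count=int(row["pre_count"]),
                spike_post_count=int(row["post_count"]),
                spike_pre_freq=float(row["pre_freq"]),
                spike_post_freq=float(row["post_freq"]),
                spike_enrichment=float(row["enrichment"]),
                spike_rank=spike_rank(df, spike_barcode),
            )
        else:
            summary.update(spike_barcode=spike_barcode, spike_enrichment=None)
    return EnrichmentReport(table=df, summary=summary, metadata=metadata or {})
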