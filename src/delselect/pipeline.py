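"""End-to-end orchestration: generate -> select -> sequence -> process -> enrich.

One :class:`~delselect.config.RunConfig` drives the five stages; all
randomness descends from the single run seed through spawned
``SeedSequence`` children, so a rerun with the same config is
bit-identical, artifacts included.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _seq, bulk, fastqio
from .config import RunConfig
from .counts import CountTable
from .enrichment import (
    EnrichmentReport,
    digest_fraction,
    enrichment_report,
    enrichment_table,
)
from .library import (
    TINY_ARCHITECTURE,
    LibraryArchitecture,
    LibraryTable,
    enumerate_library,
    generate_library,
    spike_in,
    templates_matrix,
)
from .selection import (
    SelectionParams,
    enrichment_ceiling,
    expected_enrichment,
    simulate_selection,
)

logger = logging.getLogger("delselect")


@dataclass
class RunResult:
    """Everything one mock-selection run produced."""

    config: RunConfig
    library: LibraryTable
    pre_counts: CountTable  # sequenced molecules, naive sample (truth)
    post_counts: CountTable  # sequenced molecules, post-selection (truth)
    pre_processed: bulk.ProcessedSample
    post_processed: bulk.ProcessedSample
    report: EnrichmentReport

    @property
    def summary(self) -> dict:
        return self.report.summary

    @property
    def spike_enrichment(self) -> float | None:
        return self.report.summary.get("spike_enrichment")


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _simulate_sample_reads(
    counts: CountTable,
    arch: LibraryArchitecture,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    present = counts.counts > 0
    barcodes = counts.barcodes[present]
    reps = counts.counts[present]
    templates = templates_matrix(arch, barcodes)
    template_of_read = np.repeat(np.arange(len(barcodes)), reps)
    return bulk.simulate_read_pairs(
        templates,
        template_of_read,
        read_len=config.read_len,
        error_rate=config.error_rate,
        adapters=config.adapters,
        rng=rng,
    )


def _write_reject_log(
    path: Path, sample: str, processed: bulk.ProcessedSample
) -> None:
    status = processed.merge_status
    reason = processed.extract_reason
    bad = np.flatnonzero((status != bulk.MERGED) | (reason != bulk.OK))
    names = {bulk.NO_OVERLAP: "no_overlap", bulk.TOO_MANY_MISMATCHES: "too_many_mismatches"}
    rows = [
        (
            f"{sample}:{i}",
            names.get(int(status[i]))
            or bulk.REASON_NAMES.get(int(reason[i]), "unknown"),
        )
        for i in bad.tolist()
    ]
    pd.DataFrame(rows, columns=["read_id", "reason"]).to_csv(
        path, sep="\t", index=False
    )


def run_mock_selection(config: RunConfig) -> RunResult:
    """Execute one full mock selection and return all stage outputs.

    Stages: library construction (background + diluted spike-in),
    stochastic selection + multinomial sequencing, paired-end read
    simulation, read processing (merge, primer-anchored barcode
    extraction, counting), and enrichment analysis with the in-silico
    digest readout.  When ``config.outdir`` is set, every intermediate
    artifact is written there (reads only if ``config.write_reads``).
    """
    t0 = time.monotonic()
    ss = np.random.SeedSequence(config.seed)
    ss_lib, ss_sel, ss_pre, ss_post = ss.spawn(4)
    arch = config.architecture
    outdir = config.outdir
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    # stage 1: library
    background = generate_library(arch, config.n_background, _child_seed(ss_lib))
    library = spike_in(background, arch, config.dilution)
    logger.info(
        "library: %d background + spike at 1/%g", len(background), config.dilution
    )
    if outdir is not None:
        library.to_tsv(outdir / "library.tsv")

    # stage 2: selection + sequencing depth
    params = SelectionParams(
        p_cat=config.selection.p_cat,
        p_bg=config.selection.p_bg,
        depth_pre=config.selection.depth_pre,
        depth_post=config.selection.depth_post,
        seed=_child_seed(ss_sel),
    )
    pre_counts, post_counts = simulate_selection(library, params)
    logger.info(
        "selection: depths %d/%d, survival %g/%g",
        params.depth_pre,
        params.depth_post,
        params.p_cat,
        params.p_bg,
    )
    if outdir is not None:
        pre_counts.to_tsv(outdir / "pre_counts.tsv")
        post_counts.to_tsv(outdir / "post_counts.tsv")

    # stages 3+4: reads and processing, per sample
    processed: dict[str, bulk.ProcessedSample] = {}
    for sample, counts, child in (
        ("pre", pre_counts, ss_pre),
        ("post", post_counts, ss_post),
    ):
        rng = np.random.default_rng(child)
        r1, r2 = _simulate_sample_reads(counts, arch, config, rng)
        if outdir is not None and config.write_reads:
            fastqio.write_fastq_batch(
                outdir / f"{sample}_R1.fastq", r1, config.quality, f"{sample}"
            )
            fastqio.write_fastq_batch(
                outdir / f"{sample}_R2.fastq", r2, config.quality, f"{sample}"
            )
        result = bulk.process_pairs(
            r1,
            r2,
            arch,
            min_overlap=config.min_overlap,
            max_mismatch_frac=config.max_mismatch_frac,
            max_primer_mismatch=config.max_primer_mismatch,
            q1=config.quality,
            q2=config.quality,
        )
        processed[sample] = result
        s = result.stats
        logger.info(
            "%s: pairs in %d / merged %d / extracted %d / rejected %d",
            sample,
            s.pairs_in,
            s.merged,
            s.extracted,
            s.pairs_in - s.extracted,
        )
        if outdir is not None:
            result.counts.to_tsv(outdir / f"{sample}_recovered_counts.tsv")
            if config.write_reads:
                _write_reject_log(outdir / f"{sample}_rejects.tsv", sample, result)

    # stage 5: enrichment + digest readout
    pre_rec = processed["pre"].counts
    post_rec = processed["post"].counts
    table = enrichment_table(pre_rec, post_rec, config.pseudocount, arch)
    pre_digest = digest_fraction(pre_rec, arch)
    post_digest = digest_fraction(post_rec, arch)
    f0 = 1.0 / config.dilution
    metadata = {
        "seed": config.seed,
        "config": config.to_dict(),
        "expected_enrichment_closed_form": (
            expected_enrichment(f0, params.survival_ratio)
            if params.p_bg > 0
            else enrichment_ceiling(f0)
        ),
        "accounting": {s: processed[s].stats.as_dict() for s in ("pre", "post")},
    }
    report = enrichment_report(
        table,
        pre_digest,
        post_digest,
        spike_barcode=arch.spike_barcode,
        metadata=metadata,
    )
    # enrichment against the nominal dilution, alongside the measured-pre ratio
    spike_post = report.summary.get("spike_post_freq")
    report.summary["spike_enrichment_vs_nominal"] = (
        spike_post * config.dilution if spike_post is not None else None
    )
    if outdir is not None:
        report.to_tsv(outdir / "enrichment.tsv")
        report.summary_to_yaml(outdir / "summary.yaml")
    logger.info("run complete in %.1f s", time.monotonic() - t0)
    return RunResult(
        config=config,
        library=library,
        pre_counts=pre_counts,
        post_counts=post_counts,
        pre_processed=processed["pre"],
        post_processed=processed["post"],
        report=report,
    )


def replicate_spike_enrichment(
    dilution: float,
    p_cat: float,
    p_bg: float,
    depth: int = 1_000_000,
    seed: int = 0,
    n_background: int = 100_000,
    error_rate: float = 0.001,
    read_len: int = 75,
) -> dict:
    """One full-pipeline replicate of the mock selection, enrichment summary out.

    Convenience wrapper used to reproduce the experiment's headline
    numbers: library at 1/dilution spike frequency, stochastic selection,
    multinomial sequencing at the given depth per sample, read simulation
    and processing, and pseudocount-free frequency-ratio enrichment.
    """
    cfg = RunConfig(
        n_background=n_background,
        dilution=dilution,
        selection=SelectionParams(
            p_cat=p_cat, p_bg=p_bg, depth_pre=depth, depth_post=depth
        ),
        read_len=read_len,
        error_rate=error_rate,
        pseudocount=0.0,
        outdir=None,
        write_reads=False,
        seed=seed,
    )
    return run_mock_selection(cfg).summary


def tiny_config(outdir: Path | None = None, seed: int = 0) -> RunConfig:
    """Fixture-scale config: full 2-mer library (16 barcodes), 1000 pairs."""
    return RunConfig(
        architecture=TINY_ARCHITECTURE,
        n_background=15,
        dilution=16.0,
        selection=SelectionParams(p_cat=0.5, p_bg=0.05, depth_pre=500, depth_post=500),
        read_len=12,
        error_rate=0.002,
        min_overlap=5,
        outdir=outdir,
        seed=seed,
    )


def small_config(outdir: Path | None = None, seed: int = 0) -> RunConfig:
    """Fixture-scale config: 10^3 barcodes, 10^4 read pairs."""
    return RunConfig(
        n_background=1000,
        dilution=500.0,
        selection=SelectionParams(
            p_cat=0.2495, p_bg=0.002, depth_pre=5000, depth_post=5000
        ),
        outdir=outdir,
        seed=seed,
    )


def make_fixtures(size: str, outdir: str | Path, seed: int = 0) -> RunResult:
    """Write a deterministic miniature dataset for tests and examples.

    ``tiny`` covers the full 2-mer barcode space (16 members) with 1000
    read pairs; ``small`` uses the default 12 nt architecture with 10^3
    barcodes and 10^4 read pairs.  Repeated calls produce identical
    bytes.
    """
    outdir = Path(outdir)
    if size == "tiny":
        cfg = tiny_config(outdir / "tiny", seed=seed)
    elif size == "small":
        cfg = small_config(outdir / "small", seed=seed)
    else:
        raise ValueError(f"unknown fixture size {size!r} (expected tiny or small)")
    # tiny fixtures use the enumerated 2-mer background, not a sample
    return run_mock_selection(cfg)


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
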