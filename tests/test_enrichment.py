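"""Fold enrichment, confidence intervals and the in-silico digest readout."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delselect.counts import CountTable
from delselect.enrichment import (
    digest_fraction,
    digest_site_flags,
    enrichment_report,
    enrichment_table,
    fold_enrichment,
    spike_rank,
)
from delselect.library import LibraryArchitecture

SPIKE = LibraryArchitecture().spike_barcode
# background barcodes guaranteed free of the EcoRV site
BG = ["AAAACCCCGGGG", "CCCCGGGGTTTT", "TTTTAAAACCCC"]


def _table(d):
    return CountTable.from_dict(d)


class TestFoldEnrichment:
    def test_identical_tables_give_unit_enrichment(self):
        t = _table({BG[0]: 10, BG[1]: 30, SPIKE: 5})
        for rec in fold_enrichment(t, t, pseudocount=0.0):
            assert rec.enrichment == pytest.approx(1.0)

    def test_spike_frequency_ratio_reproduces_1200_fold(self):
        # sequencing mock selection: 500 / 10^6 pre, 600120 / 10^6 post
        pre = _table({SPIKE: 500, BG[0]: 999_500})
        post = _table({SPIKE: 600_120, BG[0]: 399_880})
        records = {r.barcode: r for r in fold_enrichment(pre, post, pseudocount=0.0)}
        assert records[SPIKE].enrichment == pytest.approx(1200.24)

    def test_pseudocount_keeps_zero_pre_counts_finite(self):
        pre = _table({BG[0]: 1000})
        post = _table({BG[0]: 990, BG[1]: 10})
        records = {r.barcode: r for r in fold_enrichment(pre, post, pseudocount=0.5)}
        novel = records[BG[1]]
        k = 2
        expected = ((10 + 0.5) / (1000 + 0.5 * k)) / ((0 + 0.5) / (1000 + 0.5 * k))
        assert novel.enrichment == pytest.approx(expected)
        assert math.isfinite(novel.enrichment)
        assert novel.absent_pre

    def test_zero_pseudocount_flags_absent_pre_as_infinite(self):
        pre = _table({BG[0]: 1000})
        post = _table({BG[0]: 990, BG[1]: 10})
        records = {r.barcode: r for r in fold_enrichment(pre, post, pseudocount=0.0)}
        assert math.isinf(records[BG[1]].enrichment)
        assert records[BG[1]].absent_pre

    def test_records_sorted_by_descending_enrichment(self):
        pre = _table({BG[0]: 100, BG[1]: 100, SPIKE: 100})
        post = _table({BG[0]: 10, BG[1]: 200, SPIKE: 90})
        enrichments = [r.enrichment for r in fold_enrichment(pre, post, 0.5)]
        assert enrichments == sorted(enrichments, reverse=True)

    def test_confidence_interval_brackets_the_estimate(self):
        pre = _table({BG[0]: 100, SPIKE: 20})
        post = _table({BG[0]: 60, SPIKE: 60})
        for rec in fold_enrichment(pre, post, pseudocount=0.5):
            assert rec.ci_low <= rec.enrichment <= rec.ci_high

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            enrichment_table(_table({}), _table({BG[0]: 1}))

    def test_weighted_mean_enrichment_is_one(self, rng):
        # with no pseudocount and full support, sum(pre_freq * E) == 1
        barcodes = [f"{a}{b}" for a in "ACGT" for b in "ACGT"]
        pre = CountTable(
            barcodes=np.array(barcodes), counts=rng.integers(1, 500, size=16)
        )
        post = CountTable(
            barcodes=np.array(barcodes), counts=rng.integers(1, 500, size=16)
        )
        records = fold_enrichment(pre, post, pseudocount=0.0)
        total = sum(r.pre_freq * r.enrichment for r in records)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_enrichment_capped_by_dilution_ceiling(self, rng):
        # spike enrichment can never exceed 1 / pre-frequency at alpha=0
        for _ in range(20):
            pre_counts = rng.integers(1, 1000, size=8)
            post_counts = rng.integers(0, 1000, size=8)
            post_counts[0] = max(post_counts[0], 1)
            barcodes = np.array([SPIKE] + BG + ["ACGT" * 3, "TGCA" * 3, "GGTT" * 3, "AATT" * 3])
            pre = CountTable(barcodes=barcodes, counts=pre_counts)
            post = CountTable(barcodes=barcodes, counts=post_counts)
            rec = {r.barcode: r for r in fold_enrichment(pre, post, 0.0)}[SPIKE]
            assert rec.enrichment <= 1.0 / rec.pre_freq + 1e-9

    def test_brute_force_oracle_equivalence(self, rng):
        # independent per-barcode recomputation on a random <=100-barcode table
        n = 100
        barcodes = np.unique(
            np.array(
                [
                    "".join(rng.choice(list("ACGT"), size=12).tolist())
                    for _ in range(n)
                ]
            )
        )
        n = len(barcodes)
        pre = CountTable(barcodes=barcodes, counts=rng.integers(0, 200, size=n) + 1)
        post = CountTable(barcodes=barcodes, counts=rng.integers(0, 200, size=n) + 1)
        alpha = 0.5
        records = {r.barcode: r for r in fold_enrichment(pre, post, alpha)}
        k = n
        n1, n2 = pre.total + alpha * k, post.total + alpha * k
        for b in barcodes.tolist():
            a = pre.get(b) + alpha
            c = post.get(b) + alpha
            expected = (c / n2) / (a / n1)
            var = 1 / a - 1 / n1 + 1 / c - 1 / n2
            rec = records[b]
            assert rec.enrichment == pytest.approx(expected, rel=1e-12)
            assert rec.ci_low == pytest.approx(expected * math.exp(-1.96 * math.sqrt(var)), rel=1e-9)
            assert rec.ci_high == pytest.approx(expected * math.exp(1.96 * math.sqrt(var)), rel=1e-9)


class TestDigestFraction:
    def test_pure_spike_is_fully_cut(self, arch):
        assert digest_fraction(_table({SPIKE: 50}), arch) == 1.0

    def test_spike_share_of_counts(self, arch):
        table = _table({SPIKE: 20, BG[0]: 50, BG[1]: 30})
        assert not digest_site_flags(arch, np.array(BG[:2])).any()
        assert digest_fraction(table, arch) == pytest.approx(0.20)

    def test_absent_site_gives_zero(self, arch):
        assert digest_fraction(_table({BG[0]: 10, BG[1]: 5}), arch) == 0.0

    def test_spurious_site_in_background_barcode_is_detected(self, arch):
        sneaky = "TTGATATCTTTT"  # EcoRV inside a non-spike barcode
        assert digest_site_flags(arch, np.array([sneaky]))[0]
        assert digest_fraction(_table({sneaky: 25, BG[0]: 75}), arch) == pytest.approx(0.25)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(scale=st.integers(min_value=2, max_value=1000))
    def test_invariant_under_uniform_scaling(self, scale):
        arch = LibraryArchitecture()
        table = _table({SPIKE: 3, BG[0]: 5, BG[1]: 2})
        scaled = CountTable(barcodes=table.barcodes, counts=table.counts * scale)
        assert digest_fraction(scaled, arch) == digest_fraction(table, arch)


class TestEnrichmentReport:
    def _report(self, arch):
        pre = _table({SPIKE: 5, BG[0]: 500, BG[1]: 495})
        post = _table({SPIKE: 600, BG[0]: 250, BG[1]: 150})
        table = enrichment_table(pre, post, 0.5, arch)
        return enrichment_report(
            table,
            digest_fraction(pre, arch),
            digest_fraction(post, arch),
            spike_barcode=arch.spike_barcode,
            metadata={"seed": 1},
        )

    def test_spike_with_largest_enrichment_ranks_first(self, arch):
        report = self._report(arch)
        assert report.summary["spike_rank"] == 1
        assert report.summary["top_barcode"] == SPIKE

    def test_summary_agrees_with_the_record(self, arch):
        report = self._report(arch)
        row = report.table[report.table["barcode"] == SPIKE].iloc[0]
        assert report.summary["spike_enrichment"] == pytest.approx(row["enrichment"])

    def test_regenerated_report_is_byte_identical(self, arch, tmp_path):
        paths = []
        for name in ("a.tsv", "b.tsv"):
            report = self._report(arch)
            path = tmp_path / name
            report.to_tsv(path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_rank_ignores_barcodes_absent_pre(self, arch):
        pre = _table({SPIKE: 5, BG[0]: 995})
        post = _table({SPIKE: 600, BG[0]: 399, BG[1]: 1})
        table = enrichment_table(pre, post, 0.0, arch)
        assert spike_rank(table, SPIKE) == 1
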