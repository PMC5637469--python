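"""Read simulation, overlap merging and barcode extraction (per-read path)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delselect._seq import revcomp
from delselect.library import LibraryArchitecture, assemble_template
from delselect.reads import (
    DEFAULT_ADAPTER_R1,
    DEFAULT_ADAPTER_R2,
    MERGED,
    NO_OVERLAP,
    TOO_MANY_MISMATCHES,
    BarcodeRejection,
    ReadPair,
    extract_barcode,
    merge_pair,
    simulate_read_pair,
)

TEMPLATE = LibraryArchitecture().assemble(LibraryArchitecture().spike_barcode)


def _pair(r1, r2, q1=None, q2=None):
    q1 = np.full(len(r1), 30) if q1 is None else np.asarray(q1)
    q2 = np.full(len(r2), 30) if q2 is None else np.asarray(q2)
    return ReadPair(r1_seq=r1, r2_seq=r2, r1_qual=q1, r2_qual=q2)


class TestSimulateReadPair:
    def test_error_free_reads_are_template_slices(self):
        pair = simulate_read_pair(TEMPLATE, read_len=40, error_rate=0.0, seed=0)
        assert pair.r1_seq == TEMPLATE[:40]
        assert pair.r2_seq == revcomp(TEMPLATE)[:40]

    def test_read_through_enters_the_adapter(self):
        # 48 nt template at 2x75: positions 49-75 of r1 are adapter bases
        pair = simulate_read_pair(TEMPLATE, read_len=75, error_rate=0.0, seed=0)
        assert pair.r1_seq[:48] == TEMPLATE
        assert pair.r1_seq[48:] == DEFAULT_ADAPTER_R1[:27]
        assert pair.r2_seq[:48] == revcomp(TEMPLATE)
        assert pair.r2_seq[48:] == DEFAULT_ADAPTER_R2[:27]

    def test_error_count_is_binomial(self):
        # ~10^5 simulated bases at 1% error: count within 3 binomial SE
        rng = np.random.default_rng(77)
        n_pairs, read_len, rate = 500, 100, 0.01
        errors = 0
        clean1 = TEMPLATE + DEFAULT_ADAPTER_R1 + "A" * 100
        clean2 = revcomp(TEMPLATE) + DEFAULT_ADAPTER_R2 + "A" * 100
        for _ in range(n_pairs):
            pair = simulate_read_pair(TEMPLATE, read_len=read_len, error_rate=rate, seed=rng)
            errors += sum(a != b for a, b in zip(pair.r1_seq, clean1[:read_len]))
            errors += sum(a != b for a, b in zip(pair.r2_seq, clean2[:read_len]))
        n_bases = 2 * n_pairs * read_len
        expected = n_bases * rate
        assert abs(errors - expected) < 3 * np.sqrt(expected * (1 - rate))

    def test_qualities_are_constant_phred(self):
        pair = simulate_read_pair(TEMPLATE, read_len=75, error_rate=0.0, seed=0, quality=35)
        assert set(pair.r1_qual.tolist()) == {35}

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            simulate_read_pair("", read_len=10)
        with pytest.raises(ValueError):
            simulate_read_pair(TEMPLATE, read_len=0)
        with pytest.raises(ValueError):
            simulate_read_pair(TEMPLATE, error_rate=0.5)


class TestMergePair:
    def test_error_free_round_trip_recovers_template(self):
        pair = simulate_read_pair(TEMPLATE, read_len=75, error_rate=0.0, seed=0)
        result = merge_pair(pair)
        assert result.status == MERGED
        assert result.consensus == TEMPLATE  # adapters clipped
        assert result.overlap_len == 48

    def test_partial_overlap_geometry(self):
        # insert longer than the read: overlap is read1+read2-insert
        pair = simulate_read_pair(TEMPLATE, read_len=30, error_rate=0.0, seed=0)
        result = merge_pair(pair)
        assert result.status == MERGED
        assert result.consensus == TEMPLATE
        assert result.overlap_len == 12

    def test_higher_quality_base_wins_disagreements(self):
        # one overlap disagreement: r1 carries Q40, r2 Q10 -> r1 base kept
        insert = "ACGTACGTACGTACGTACGT"
        r1 = insert
        mutated = insert[:10] + "T" + insert[11:]  # position 10 A->T in r2
        r2 = revcomp(mutated)
        q1 = np.full(20, 40)
        q2 = np.full(20, 10)
        result = merge_pair(_pair(r1, r2, q1, q2), min_overlap=10)
        assert result.status == MERGED
        assert result.consensus == insert
        # and the converse: r2's high-quality base overrides r1
        result2 = merge_pair(_pair(r1, r2, np.full(20, 10), np.full(20, 40)), min_overlap=10)
        assert result2.consensus == mutated

    def test_quality_tie_goes_to_read1(self):
        insert = "ACGTACGTACGTACGTACGT"
        mutated = insert[:10] + "T" + insert[11:]
        result = merge_pair(_pair(insert, revcomp(mutated)), min_overlap=10)
        assert result.consensus == insert

    def test_disjoint_reads_report_no_overlap(self):
        result = merge_pair(_pair("A" * 30, "A" * 30), min_overlap=10)
        # r2rc is poly-T: no offset matches anything
        assert result.status == NO_OVERLAP
        assert result.consensus is None

    def test_noisy_overlap_reports_too_many_mismatches(self):
        insert = TEMPLATE  # 48 nt, reads 40 nt, true overlap 32
        r1 = insert[:40]
        tail = insert[8:]
        corrupted = list(tail)
        for i in range(0, 32, 5):  # ~20% mismatches, evenly spread
            corrupted[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[corrupted[i]]
        r2 = revcomp("".join(corrupted))
        result = merge_pair(_pair(r1, r2), min_overlap=10, max_mismatch_frac=0.1)
        assert result.status == TOO_MANY_MISMATCHES

    def test_merge_is_strand_symmetric(self):
        pair = simulate_read_pair(TEMPLATE, read_len=75, error_rate=0.0, seed=0)
        swapped = _pair(pair.r2_seq, pair.r1_seq)
        result = merge_pair(swapped)
        assert result.status == MERGED
        assert result.consensus == revcomp(TEMPLATE)

    def test_min_overlap_validated(self):
        with pytest.raises(ValueError):
            merge_pair(_pair("ACGT", "ACGT"), min_overlap=0)


class TestExtractBarcode:
    def test_exact_template_inverts_assembly(self, arch):
        assert extract_barcode(TEMPLATE, arch) == arch.spike_barcode

    def test_one_primer_substitution_tolerated(self, arch):
        mutated = "T" + TEMPLATE[1:]
        assert arch.primer5[0] != "T"
        assert extract_barcode(mutated, arch, max_primer_mismatch=1) == arch.spike_barcode

    def test_two_primer_substitutions_rejected(self, arch):
        assert arch.primer5[:2] != "TT"
        mutated = "TT" + TEMPLATE[2:]
        result = extract_barcode(mutated, arch, max_primer_mismatch=1)
        assert isinstance(result, BarcodeRejection)
        assert result.reason == "primer5_not_found"

    def test_corrupt_primer3_rejected(self, arch):
        mutated = TEMPLATE[:31] + "TT" + TEMPLATE[33:]
        assert arch.primer3[1:3] != "TT"
        result = extract_barcode(mutated, arch, max_primer_mismatch=1)
        assert isinstance(result, BarcodeRejection)
        assert result.reason == "primer3_not_found"

    def test_wrong_spacing_reports_bad_barcode_length(self, arch):
        # one barcode base deleted: primers found but 11 nt between them
        truncated = arch.primer5 + arch.spike_barcode[:-1] + arch.primer3
        result = extract_barcode(truncated, arch, max_primer_mismatch=1)
        assert isinstance(result, BarcodeRejection)
        assert result.reason == "bad_barcode_length"

    def test_empty_consensus_rejected(self, arch):
        with pytest.raises(ValueError):
            extract_barcode("", arch)


@st.composite
def _round_trip_case(draw):
    barcode_length = draw(st.integers(min_value=4, max_value=12))
    p5_len = draw(st.integers(min_value=10, max_value=18))
    p3_len = draw(st.integers(min_value=10, max_value=18))
    primer5 = LibraryArchitecture().primer5[:p5_len]
    primer3 = LibraryArchitecture().primer3[:p3_len]
    barcode = "".join(
        draw(st.lists(st.sampled_from("ACGT"), min_size=barcode_length, max_size=barcode_length))
    )
    # avoid barcodes whose suffix mimics a primer3 prefix: those create a
    # legitimate earlier primer placement and a documented length rejection
    for k in range(1, barcode_length + 1):
        if barcode[-k:] == primer3[:k]:
            barcode = barcode[:-1] + ("A" if primer3[0] != "A" else "C")
    template_len = p5_len + barcode_length + p3_len
    read_len = draw(st.integers(min_value=25, max_value=90))
    # geometry must allow at least the minimum overlap
    if template_len > 2 * read_len - 10:
        read_len = (template_len + 10 + 1) // 2
    arch = LibraryArchitecture(
        primer5=primer5,
        primer3=primer3,
        barcode_length=barcode_length,
        spike_barcode=barcode,
        digest_site=barcode[:2],
        digest_site_offset=0,
    )
    return arch, barcode, read_len


class TestRoundTripProperty:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(case=_round_trip_case())
    def test_error_free_simulate_merge_extract_recovers_barcode(self, case):
        arch, barcode, read_len = case
        template = assemble_template(arch, barcode)
        pair = simulate_read_pair(template, read_len=read_len, error_rate=0.0, seed=1)
        merged = merge_pair(pair)
        assert merged.status == MERGED
        assert merged.consensus == template
        assert extract_barcode(merged.consensus, arch, max_primer_mismatch=0) == barcode
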