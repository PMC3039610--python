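"""Filter stages: removal rules, exact conservation, idempotence, symmetry."""

from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mpssdge import (
    ConfigurationError,
    PipelineError,
    SignatureTable,
    TagRead,
    apply_reliability_filter,
    apply_significance_filter,
    count_signatures,
    filter_low_quality,
    qc_library,
)

ADAPTER = "GATCGGAAGAGCGTCGTGTAG"


def _read(seq, run="run1", lib="libX"):
    return TagRead(seq, lib, run)


@pytest.mark.parametrize(
    "seq,kept",
    [
        ("GATCAAAAAAAAAAAAAAAAA", True),  # clean 21-mer
        ("GATCNAAAAAAAAAAAAAAAA", False),  # ambiguous base
        (ADAPTER, False),  # adaptor substring
        ("GATCAAAAAAAAAAAAAAAAAA", True),  # 22 nt: within +/- 1 of 21
        ("GATCAAAA", False),  # far off-length
    ],
)
def test_low_quality_rules(seq, kept):
    clean, report = filter_low_quality([_read(seq)], [ADAPTER], signature_length=21)
    assert (len(clean) == 1) is kept
    assert report.total_reads == 1
    assert report.high_quality_reads + report.low_quality_reads == 1


def test_empty_stream_gives_zero_report():
    clean, report = filter_low_quality([], [ADAPTER])
    assert clean == [] and report.total_reads == 0


def test_filter_tallies_nucleotides_and_gc():
    reads = [_read("GATCAAAAAAAAAAAAAAAAA"), _read("GGCCGGCCGGCCGGCCGGCCG")]
    clean, report = filter_low_quality(reads, [])
    assert report.total_nucleotides == 42
    assert report.hq_gc_bases == 2 + 21  # GC of both retained reads


def test_count_signatures_per_run():
    reads = [_read("A" * 21, "r1"), _read("A" * 21, "r1"), _read("A" * 21, "r2")]
    table = count_signatures(reads)
    assert len(table) == 1
    assert table.total("A" * 21) == 3
    assert table.counts["A" * 21] == Counter({"r1": 2, "r2": 1})
    assert table.library_total == 3


def test_count_signatures_empty():
    table = count_signatures([])
    assert len(table) == 0 and table.library_total == 0


def test_count_signatures_mixed_library_errors():
    with pytest.raises(PipelineError, match="mixed library"):
        count_signatures([_read("A" * 21, lib="x"), _read("A" * 21, lib="y")])


def test_tpm_against_direct_arithmetic():
    table = SignatureTable("mt", {"G" * 21: Counter({"r1": 31})}, library_total=10_576_876)
    assert round(table.tpm("G" * 21), 3) == 2.931


def test_reliability_filter_rules():
    table = SignatureTable(
        "x",
        {
            "A" * 21: Counter({"r1": 100}),  # one run only: removed
            "C" * 21: Counter({"r1": 1, "r2": 1}),  # two-run support: kept
        },
        library_total=102,
    )
    filtered, removed = apply_reliability_filter(table)
    assert set(filtered.signatures()) == {"C" * 21}
    assert removed == 100
    assert filtered.library_total == 2  # TPM denominator recomputed
    with pytest.raises(ConfigurationError):
        apply_reliability_filter(table, min_runs=0)


def test_reliability_filter_idempotent():
    table = SignatureTable(
        "x",
        {"A" * 21: Counter({"r1": 5}), "C" * 21: Counter({"r1": 2, "r2": 3})},
        library_total=10,
    )
    once, _ = apply_reliability_filter(table)
    twice, removed_again = apply_reliability_filter(once)
    assert twice.counts == once.counts and removed_again == 0


def _table(lib, sig_counts, total):
    return SignatureTable(lib, {s: Counter({"r1": c // 2 + c % 2, "r2": c // 2}) for s, c in sig_counts.items()}, total)


@pytest.mark.parametrize(
    "tpm_a,tpm_b,kept",
    [
        (2.9, 0.0, False),  # both below threshold
        (0.0, 3.0, True),  # threshold inclusive
        (500.0, 0.0, True),  # library-specific but abundant
    ],
)
def test_significance_filter_boundaries(tpm_a, tpm_b, kept):
    sig = "T" * 21
    total = 1_000_000
    ta = _table("a", {sig: int(tpm_a)} if tpm_a else {}, total)
    tb = _table("b", {sig: int(tpm_b)} if tpm_b else {}, total)
    fa, fb, _ = apply_significance_filter(ta, tb, 3.0)
    assert (sig in fa or sig in fb) is kept


def test_significance_filter_symmetric_and_idempotent():
    ta = _table("a", {"A" * 21: 10, "C" * 21: 1}, 1_000_000)
    tb = _table("b", {"A" * 21: 1, "G" * 21: 40}, 1_000_000)
    fa, fb, _ = apply_significance_filter(ta, tb)
    fb2, fa2, _ = apply_significance_filter(tb, ta)  # swapped labels
    assert set(fa.signatures()) == set(fa2.signatures())
    assert set(fb.signatures()) == set(fb2.signatures())
    ga, gb, _ = apply_significance_filter(fa, fb)
    assert set(ga.signatures()) == set(fa.signatures())
    assert gb.library_total == fb.library_total


seq_st = st.text(alphabet="ACGTN", min_size=21, max_size=21)
reads_st = st.lists(
    st.builds(TagRead, seq_st, st.just("lib"), st.sampled_from(["r1", "r2", "r3"])),
    max_size=60,
)


@given(reads_st)
def test_conservation_through_quality_and_reliability(reads):
    clean, report = filter_low_quality(reads, [ADAPTER])
    assert report.high_quality_reads + report.low_quality_reads == report.total_reads
    assert len(clean) == report.high_quality_reads
    table = count_signatures(clean, library_id="lib")
    assert table.counted_reads() == len(clean)
    filtered, removed = apply_reliability_filter(table)
    assert filtered.counted_reads() + removed == table.counted_reads()
    if filtered.library_total:
        total_tpm = sum(filtered.tpm(s) for s in filtered.signatures())
        assert abs(total_tpm - 1e6) <= 1e-6 * 1e6


def test_qc_library_matches_composed_stages(small_config):
    from mpssdge import generate_transcriptome, simulate_library

    cfg = small_config
    rng = cfg.rng()
    ref, truth = generate_transcriptome(cfg, rng)
    reads = list(simulate_library(ref, truth, "A", cfg, rng))
    adaptors = [ADAPTER]
    table1, rep1 = qc_library(iter(reads), adaptors, cfg.signature_length)
    clean, rep2 = filter_low_quality(reads, adaptors, cfg.signature_length)
    table2, removed = apply_reliability_filter(count_signatures(clean))
    assert rep1.total_reads == rep2.total_reads
    assert rep1.high_quality_reads == rep2.high_quality_reads
    assert rep1.unreliable_signature_reads == removed
    assert table1.counts == table2.counts
    assert table1.library_total == table2.library_total
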