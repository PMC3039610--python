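"""Signature quality control: three ordered filtering stages with accounting.

Stage 1 (quality): drop reads containing ambiguous bases (N), an adaptor
substring, or an off-spec length.
Stage 2 (run reliability): drop signatures observed in fewer than two
distinct sequencing runs of the library.
Stage 3 (TPM significance): drop signatures never reaching the TPM threshold
(default 3) in either library, evaluated on post-reliability totals.

Every stage conserves counts exactly (input = retained + removed) and the
QCReport accumulates the per-stage accounting (totals, percents with
round-half-up formatting, nucleotide and GC tallies).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

from ._util import ConfigurationError, PipelineError, percent


class TagRead(NamedTuple):
    """One sequenced signature read with its library and run labels."""

    sequence: str
    library_id: str
    run_id: str


@dataclass
class QCReport:
    """Per-library accounting across the three filter stages."""

    library_id: str = ""
    total_reads: int = 0
    total_nucleotides: int = 0
    low_quality_reads: int = 0
    high_quality_reads: int = 0
    hq_gc_bases: int = 0
    hq_bases: int = 0
    unreliable_signature_reads: Optional[int] = None
    reliable_reads: Optional[int] = None
    signatures_before_significance: Optional[int] = None
    signatures_after_significance: Optional[int] = None
    n_unigenes: Optional[int] = None

    @property
    def percent_high_quality(self) -> float:
        return percent(self.high_quality_reads, self.total_reads, 2)

    @property
    def percent_low_quality(self) -> float:
        return percent(self.low_quality_reads, self.total_reads, 2)

    @property
    def percent_unreliable(self) -> float:
        if self.unreliable_signature_reads is None:
            raise PipelineError("reliability stage has not run")
        return percent(self.unreliable_signature_reads, self.high_quality_reads, 1)

    @property
    def gc_percent(self) -> float:
        return percent(self.hq_gc_bases, self.hq_bases, 2)

    def validate(self) -> None:
        if self.high_quality_reads + self.low_quality_reads != self.total_reads:
            raise PipelineError("read accounting violated: hq + lq != total")
        if self.unreliable_signature_reads is not None:
            if self.reliable_reads != self.high_quality_reads - self.unreliable_signature_reads:
                raise PipelineError("reliable != high_quality - unreliable")

    @classmethod
    def from_stage_counts(
        cls,
        library_id: str,
        total_reads: int,
        low_quality_reads: int,
        unreliable_signature_reads: int | None = None,
        read_length: int = 75,
    ) -> "QCReport":
        """Build a report directly from stage totals (worked-example entry
        point: raw sequencer reads of ``read_length`` nt feed the nucleotide
        tally; the derived rows follow by exact arithmetic)."""
        hq = total_reads - low_quality_reads
        rep = cls(
            library_id=library_id,
            total_reads=total_reads,
            total_nucleotides=total_reads * read_length,
            low_quality_reads=low_quality_reads,
            high_quality_reads=hq,
        )
        if unreliable_signature_reads is not None:
            rep.unreliable_signature_reads = unreliable_signature_reads
            rep.reliable_reads = hq - unreliable_signature_reads
        rep.validate()
        return rep


@dataclass
class SignatureTable:
    """Per-library signature counts: signature -> per-run counts, with the
    library total used as the TPM denominator."""

    library_id: str
    counts: dict[str, Counter] = field(default_factory=dict)
    library_total: int = 0

    def signatures(self) -> Iterable[str]:
        return self.counts.keys()

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, signature: str) -> bool:
        return signature in self.counts

    def total(self, signature: str) -> int:
        return sum(self.counts[signature].values()) if signature in self.counts else 0

    def n_runs(self, signature: str) -> int:
        return len(self.counts.get(signature, ()))

    def tpm(self, signature: str) -> float:
        if self.library_total == 0:
            raise PipelineError("library_total is 0; cannot compute TPM")
        return self.total(signature) / self.library_total * 1e6

    def counted_reads(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        # header comment preserves the TPM denominator, which can exceed the
        # counted reads after the significance filter
        with open(path, "w", newline="") as fh:
            fh.write(f"# library_id={self.library_id}\tlibrary_total={self.library_total}\n")
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["signature", "run_counts", "total", "tpm"])
            for sig in sorted(self.counts):
                runs = ",".join(f"{r}:{c}" for r, c in sorted(self.counts[sig].items()))
                w.writerow([sig, runs, self.total(sig), f"{self.tpm(sig):.6f}"])

    @classmethod
    def from_tsv(cls, path: str | Path, library_id: str | None = None, library_total: int | None = None) -> "SignatureTable":
        counts: dict[str, Counter] = {}
        observed = 0
        with open(path, newline="") as fh:
            first = fh.readline()
            if first.startswith("#"):
                for field_ in first[1:].strip().split("\t"):
                    key, _, val = field_.partition("=")
                    if key.strip() == "library_id" and library_id is None:
                        library_id = val
                    elif key.strip() == "library_total" and library_total is None:
                        library_total = int(val)
            else:
                fh.seek(0)
            for row in csv.DictReader(fh, delimiter="\t"):
                c = Counter()
                for part in row["run_counts"].split(","):
                    run, n = part.rsplit(":", 1)
                    c[run] = int(n)
                counts[row["signature"]] = c
                observed += sum(c.values())
        return cls(
            library_id=library_id or "",
            counts=counts,
            library_total=library_total if library_total is not None else observed,
        )


def _is_low_quality(read: TagRead, adaptors: list[str], signature_length: int | None) -> bool:
    seq = read.sequence
    if signature_length is not None and abs(len(seq) - signature_length) > 1:
        return True
    if "N" in seq:
        return True
    return any(a in seq for a in adaptors)


def filter_low_quality(
    reads: Iterable[TagRead],
    adaptor_sequences: list[str] | None = None,
    signature_length: int | None = 21,
    library_id: str = "",
) -> tuple[list[TagRead], QCReport]:
    """Remove reads with ambiguous bases, adaptor substrings or bad length.

    A read is removed iff it contains >= 1 N, any adaptor sequence as an exact
    substring, or (when ``signature_length`` is given) a length outside the
    configured signature length +/- 1.  Counts are conserved in the report,
    which also tallies total nucleotides and the GC content of retained reads.
    """
    adaptors = adaptor_sequences or []
    report = QCReport(library_id=library_id)
    clean: list[TagRead] = []
    for read in reads:
        report.total_reads += 1
        report.total_nucleotides += len(read.sequence)
        if _is_low_quality(read, adaptors, signature_length):
            report.low_quality_reads += 1
        else:
            report.high_quality_reads += 1
            report.hq_bases += len(read.sequence)
            report.hq_gc_bases += read.sequence.count("G") + read.sequence.count("C")
            clean.append(read)
    report.validate()
    return clean, report


def count_signatures(clean_reads: Iterable[TagRead], library_id: str | None = None) -> SignatureTable:
    """Exact multiset counting of signatures with per-run subcounts.

    All reads must share one library_id (mixed libraries are an error)."""
    counts: dict[str, Counter] = {}
    total = 0
    for read in clean_reads:
        if library_id is None:
            library_id = read.library_id
        elif read.library_id != library_id:
            raise PipelineError(
                f"mixed library ids: expected {library_id!r}, got {read.library_id!r}"
            )
        counts.setdefault(read.sequence, Counter())[read.run_id] += 1
        total += 1
    return SignatureTable(library_id=library_id or "", counts=counts, library_total=total)


def apply_reliability_filter(
    table: SignatureTable, min_runs: int = 2
) -> tuple[SignatureTable, int]:
    """Drop signatures supported by fewer than ``min_runs`` distinct runs.

    Returns the filtered table (library_total recomputed from retained reads,
    so downstream TPM uses the reliable total) and the number of removed
    reads.
    """
    if min_runs < 1:
        raise ConfigurationError("min_runs must be >= 1")
    kept = {sig: c for sig, c in table.counts.items() if len(c) >= min_runs}
    retained_total = sum(sum(c.values()) for c in kept.values())
    removed_reads = table.counted_reads() - retained_total
    return (
        SignatureTable(library_id=table.library_id, counts=kept, library_total=retained_total),
        removed_reads,
    )


def apply_significance_filter(
    table_a: SignatureTable,
    table_b: SignatureTable,
    tpm_threshold: float = 3.0,
) -> tuple[SignatureTable, SignatureTable, dict]:
    """Keep signatures reaching ``tpm_threshold`` TPM in at least one library.

    TPM is evaluated on each table's post-reliability total (the threshold is
    inclusive: exactly 3 TPM is retained), and the retained tables keep that
    total as their TPM denominator.  The decision is symmetric in the two
    libraries.
    """
    if tpm_threshold < 0:
        raise ConfigurationError("tpm_threshold must be >= 0")
    union = set(table_a.signatures()) | set(table_b.signatures())
    keep = {
        sig
        for sig in union
        if (sig in table_a and table_a.tpm(sig) >= tpm_threshold)
        or (sig in table_b and table_b.tpm(sig) >= tpm_threshold)
    }
    out = []
    info: dict = {}
    for table in (table_a, table_b):
        kept = {sig: c for sig, c in table.counts.items() if sig in keep}
        out.append(
            SignatureTable(
                library_id=table.library_id, counts=kept, library_total=table.library_total
            )
        )
        info[table.library_id] = {
            "signatures_before": len(table),
            "signatures_after": len(kept),
        }
    return out[0], out[1], info


def qc_library(
    reads: Iterable[TagRead],
    adaptor_sequences: list[str] | None = None,
    signature_length: int | None = 21,
    min_runs: int = 2,
    library_id: str | None = None,
) -> tuple[SignatureTable, QCReport]:
    """Streaming quality + reliability pipeline for one library.

    Single pass over the read stream (never materializes the clean read
    list), then the run-reliability filter; returns the reliable table and a
    report with both stages filled in.
    """
    adaptors = adaptor_sequences or []
    report = QCReport(library_id=library_id or "")
    counts: dict[str, Counter] = {}
    for read in reads:
        if library_id is None:
            library_id = read.library_id
            report.library_id = library_id
        elif read.library_id != library_id:
            raise PipelineError(
                f"mixed library ids: expected {library_id!r}, got {read.library_id!r}"
            )
        report.total_reads += 1
        report.total_nucleotides += len(read.sequence)
        if _is_low_quality(read, adaptors, signature_length):
            report.low_quality_reads += 1
            continue
        report.high_quality_reads += 1
        report.hq_bases += len(read.sequence)
        report.hq_gc_bases += read.sequence.count("G") + read.sequence.count("C")
        counts.setdefault(read.sequence, Counter())[read.run_id] += 1
    table = SignatureTable(
        library_id=library_id or "", counts=counts, library_total=report.high_quality_reads
    )
    table, removed = apply_reliability_filter(table, min_runs=min_runs)
    report.unreliable_signature_reads = removed
    report.reliable_reads = report.high_quality_reads - removed
    report.validate()
    return table, report
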