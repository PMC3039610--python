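"""File formats: FASTA reference, FASTQ/TSV tag reads, ground-truth TSV.

Reads travel either as FASTQ (run label embedded in the read name suffix
``/run<k>``, constant quality since base qualities play no role downstream)
or as a 3-column TSV (sequence, library, run).  All writers are
deterministic: the same inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import PipelineError
from .signature_qc import TagRead
from .synthetic_data import GroundTruthRecord

_QUAL = "I"


def write_fasta(reference: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise PipelineError(f"duplicate gene identifier in FASTA: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fastq(reads: Iterable[TagRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@{read.library_id}.{i + 1}/{read.run_id}\n")
            fh.write(read.sequence + "\n+\n" + _QUAL * len(read.sequence) + "\n")


def read_fastq(path: str | Path, library_id: str | None = None) -> Iterator[TagRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        name = rec.id
        if "/" not in name:
            raise PipelineError(f"read name lacks '/run<k>' suffix: {name}")
        stem, run_id = name.rsplit("/", 1)
        lib = library_id if library_id is not None else stem.rsplit(".", 1)[0]
        yield TagRead(str(rec.seq), lib, run_id)


def write_reads_tsv(reads: Iterable[TagRead], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sequence", "library", "run"])
        for read in reads:
            w.writerow([read.sequence, read.library_id, read.run_id])


def read_reads_tsv(path: str | Path) -> Iterator[TagRead]:
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            yield TagRead(row["sequence"], row["library"], row["run"])


_GT_COLUMNS = [
    "gene_id",
    "true_tpm_A",
    "true_tpm_B",
    "fold_change",
    "de_label",
    "sense_signature",
    "antisense_signature",
]


def write_ground_truth(truth: Iterable[GroundTruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_GT_COLUMNS)
        for g in truth:
            w.writerow(
                [
                    g.gene_id,
                    f"{g.true_tpm_A:.6f}",
                    f"{g.true_tpm_B:.6f}",
                    f"{g.fold_change:.6g}",
                    g.de_label,
                    g.sense_signature or ".",
                    g.antisense_signature or ".",
                ]
            )


def read_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                GroundTruthRecord(
                    gene_id=row["gene_id"],
                    true_tpm_A=float(row["true_tpm_A"]),
                    true_tpm_B=float(row["true_tpm_B"]),
                    fold_change=float(row["fold_change"]),
                    de_label=row["de_label"],
                    sense_signature=None if row["sense_signature"] == "." else row["sense_signature"],
                    antisense_signature=None
                    if row["antisense_signature"] == "."
                    else row["antisense_signature"],
                )
            )
    return out
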