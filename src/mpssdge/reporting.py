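"""Summary artifacts: library accounting, abundance and ratio distributions,
and ground-truth recovery metrics for synthetic runs.

Abundance bins follow the arithmetic of percent-of-library abundance
(0.0001% of 10^6 = 1 TPM, 0.001% = 10 TPM, 0.01% = 100 TPM, 0.1% = 1000 TPM)
with lower-closed/upper-open edges except the unbounded top bin; a signature
absent from a library but present in the union is counted in the zero bin.
Ratio bins mirror the differential-expression rule's strict/complement
structure, so "twofold or greater" is exactly the count above 2 plus the
count below 0.5; library-specific signatures (ratio sentinel 0) form their
own category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from ._util import PipelineError, percent, round_half_up
from .diffexpr import DOWN, LIBRARY_SPECIFIC, UP, GeneExpressionRecord
from .signature_qc import QCReport, SignatureTable
from .synthetic_data import GroundTruthRecord

ABUNDANCE_LABELS = ("0", "(0,1)", "[1,10)", "[10,100)", "[100,1000)", "[1000,inf)")
RATIO_LABELS = ("0 (library-specific)", "(0,0.2)", "[0.2,0.5)", "[0.5,2]", "(2,5]", "(5,inf)")

_FOOTER = (
    "# Bin edges follow percent-of-library arithmetic (0.0001% = 1 TPM, "
    "0.001% = 10 TPM, 0.01% = 100 TPM, 0.1% = 1000 TPM); lower-closed, "
    "upper-open, top bin unbounded."
)


@dataclass
class AbundanceBins:
    library_id: str
    labels: tuple[str, ...] = ABUNDANCE_LABELS
    counts: list[int] = field(default_factory=lambda: [0] * len(ABUNDANCE_LABELS))

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def percents(self) -> list[float]:
        return [percent(c, self.total, 2) for c in self.counts]

    def to_text(self) -> str:
        lines = [f"Signature abundance distribution: {self.library_id}"]
        for label, c, pc in zip(self.labels, self.counts, self.percents):
            lines.append(f"  {label:<14} {c:>10d}  {pc:6.2f}%")
        lines.append(f"  {'total':<14} {self.total:>10d}")
        lines.append(_FOOTER)
        return "\n".join(lines) + "\n"


def _abundance_bin(tpm: float) -> int:
    if tpm == 0:
        return 0
    if tpm < 1:
        return 1
    if tpm < 10:
        return 2
    if tpm < 100:
        return 3
    if tpm < 1000:
        return 4
    return 5  # exactly 1000 TPM belongs to the top bin


def bin_abundance(
    table: SignatureTable, union_signatures: Optional[Iterable[str]] = None
) -> AbundanceBins:
    """Assign each signature of the union to exactly one TPM abundance bin.

    With ``union_signatures`` given (the two-library union), signatures
    absent from this table are counted in the zero bin; otherwise only the
    table's own signatures are binned.
    """
    sigs = set(union_signatures) if union_signatures is not None else set(table.signatures())
    bins = AbundanceBins(library_id=table.library_id)
    for sig in sigs:
        tpm = table.tpm(sig) if sig in table else 0.0
        bins.counts[_abundance_bin(tpm)] += 1
    return bins


@dataclass
class RatioBins:
    labels: tuple[str, ...] = RATIO_LABELS
    counts: list[int] = field(default_factory=lambda: [0] * len(RATIO_LABELS))

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def percents(self) -> list[float]:
        return [percent(c, self.total, 2) for c in self.counts]

    @property
    def twofold_or_greater(self) -> int:
        """count(r > 2) + count(r < 0.5), excluding library-specific."""
        return self.counts[1] + self.counts[2] + self.counts[4] + self.counts[5]

    def to_text(self) -> str:
        lines = ["Expression ratio (MT/WT) distribution"]
        for label, c, pc in zip(self.labels, self.counts, self.percents):
            lines.append(f"  {label:<22} {c:>10d}  {pc:6.2f}%")
        lines.append(f"  {'total':<22} {self.total:>10d}")
        lines.append(f"  twofold or greater (r > 2 or r < 0.5): {self.twofold_or_greater}")
        return "\n".join(lines) + "\n"


def _ratio_bin(r: float) -> int:
    if r == 0:
        return 0
    if r < 0.2:
        return 1
    if r < 0.5:
        return 2
    if r <= 2:
        return 3
    if r <= 5:
        return 4
    return 5


def bin_ratios(records: Sequence[GeneExpressionRecord]) -> RatioBins:
    """Exhaustive, mutually exclusive ratio binning of DE records."""
    bins = RatioBins()
    for rec in records:
        bins.counts[_ratio_bin(rec.ratio)] += 1
    return bins


def accounting_table(
    report_a: QCReport, report_b: QCReport, label_a: str = "WT", label_b: str = "MT"
) -> str:
    """Two-library summary accounting in the classic MPSS table layout.

    Rows requiring EST contig assembly (contig/singleton counts) are out of
    scope and omitted, noted in the footer.  Raises when a stage a row needs
    has not run.
    """
    rows: list[tuple[str, str, str]] = []

    def fmt(v: int | float | None, stage: str, decimals: int | None = None) -> str:
        if v is None:
            raise PipelineError(f"missing stage data: {stage}")
        if decimals is None:
            return f"{v:,}"
        return f"{round_half_up(v, decimals):.{decimals}f}"

    for name, attr, dec in (
        ("Total reads", "total_reads", None),
        ("Total nucleotides (nt)", "total_nucleotides", None),
        ("High-quality reads", "high_quality_reads", None),
        ("High-quality reads (%)", "percent_high_quality", 2),
        ("Low quality reads", "low_quality_reads", None),
        ("Low quality reads (%)", "percent_low_quality", 2),
        ("GC percentage of high-quality reads (%)", "gc_percent", 2),
        ("Unreliable signature reads", "unreliable_signature_reads", None),
        ("Unreliable signature reads (%)", "percent_unreliable", 1),
        ("Reliable significant reads", "reliable_reads", None),
        ("Number of unigenes", "n_unigenes", None),
    ):
        def get(rep: QCReport):
            try:
                v = getattr(rep, attr)
            except PipelineError:
                v = None
            if v is None and rep.total_reads == 0:
                return 0  # empty library renders as an all-zero table
            return v

        va, vb = get(report_a), get(report_b)
        if attr == "n_unigenes" and va is None and vb is None:
            continue
        rows.append((name, fmt(va, name, dec), fmt(vb, name, dec)))

    w0 = max(len(r[0]) for r in rows)
    w1 = max(len(label_a), max(len(r[1]) for r in rows))
    w2 = max(len(label_b), max(len(r[2]) for r in rows))
    lines = [f"{'':<{w0}}  {label_a:>{w1}}  {label_b:>{w2}}"]
    for name, va, vb in rows:
        lines.append(f"{name:<{w0}}  {va:>{w1}}  {vb:>{w2}}")
    lines.append("# Contig and singleton rows require EST assembly and are omitted.")
    return "\n".join(lines) + "\n"


@dataclass
class StratumMetrics:
    stratum: str
    n_true_de: int
    tp: int  # true DE called in the correct direction
    fp: int  # called up/down when truth is none or the opposite direction
    fn: int  # true DE not called in the correct direction

    @property
    def recall(self) -> float:
        return self.tp / self.n_true_de if self.n_true_de else float("nan")

    @property
    def precision(self) -> float:
        called = self.tp + self.fp
        return self.tp / called if called else float("nan")


@dataclass
class RecoveryReport:
    strata: list[StratumMetrics]
    overall: StratumMetrics
    n_genes_evaluated: int

    def to_text(self) -> str:
        lines = ["Ground-truth recovery (direction-aware)"]
        lines.append(f"  genes evaluated: {self.n_genes_evaluated}")
        for s in [self.overall] + self.strata:
            rec = "NA" if math.isnan(s.recall) else f"{s.recall:.4f}"
            prec = "NA" if math.isnan(s.precision) else f"{s.precision:.4f}"
            lines.append(
                f"  {s.stratum:<24} true_de={s.n_true_de:<6d} TP={s.tp:<6d} "
                f"FP={s.fp:<6d} FN={s.fn:<6d} recall={rec} precision={prec}"
            )
        return "\n".join(lines) + "\n"


def recovery_report(
    records: Sequence[GeneExpressionRecord],
    ground_truth: Sequence[GroundTruthRecord],
    tpm_strata: Sequence[float] = (0.0, 10.0, 50.0, 100.0),
) -> RecoveryReport:
    """Direction-aware precision/recall of DE calls against ground truth.

    Predictions are taken from sense-strand records (one per gene).  Truth
    direction comes from ``de_label``; a gene is a true positive when called
    in its true direction, a false positive when called up/down but truly
    non-DE (or called in the wrong direction).  Strata are defined on the
    gene's larger true TPM (max of the two conditions).  Record gene ids
    absent from the ground truth are an error.
    """
    truth_by_gene = {g.gene_id: g for g in ground_truth}
    pred: dict[str, str] = {}
    for rec in records:
        if rec.gene_id not in truth_by_gene:
            raise PipelineError(f"gene id not in ground truth: {rec.gene_id}")
        if rec.strand in ("sense", "."):
            pred[rec.gene_id] = rec.de_class

    edges = sorted(tpm_strata)
    labels = [
        f"tpm>=[{edges[i]:g},{edges[i + 1]:g})" if i + 1 < len(edges) else f"tpm>=[{edges[i]:g},inf)"
        for i in range(len(edges))
    ]
    strata = [StratumMetrics(lab, 0, 0, 0, 0) for lab in labels]
    overall = StratumMetrics("overall", 0, 0, 0, 0)

    def stratum_of(g: GroundTruthRecord) -> StratumMetrics:
        top = max(g.true_tpm_A, g.true_tpm_B)
        k = 0
        for i, e in enumerate(edges):
            if top >= e:
                k = i
        return strata[k]

    for gene_id, de_class in pred.items():
        truth = truth_by_gene[gene_id]
        true_dir = {"up": UP, "down": DOWN}.get(truth.de_label)
        called = de_class in (UP, DOWN)
        for s in (overall, stratum_of(truth)):
            if true_dir is not None:
                s.n_true_de += 1
                if de_class == true_dir:
                    s.tp += 1
                else:
                    s.fn += 1
                    if called:
                        s.fp += 1  # wrong direction
            elif called:
                s.fp += 1
    return RecoveryReport(strata=strata, overall=overall, n_genes_evaluated=len(pred))


def plot_abundance(bins: AbundanceBins, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(bins.labels)), bins.counts, color="0.3")
    ax.set_xticks(range(len(bins.labels)), bins.labels, rotation=45, ha="right")
    ax.set_ylabel("signatures")
    ax.set_title(f"Signature abundance (TPM), {bins.library_id}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ratios(bins: RatioBins, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(bins.labels)), bins.counts, color="0.3")
    ax.set_xticks(range(len(bins.labels)), bins.labels, rotation=45, ha="right")
    ax.set_ylabel("signatures")
    ax.set_title("Expression ratio (MT/WT)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
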