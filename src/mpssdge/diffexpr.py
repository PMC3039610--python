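"""Between-library differential expression for signature/tag counts.

The contrast compares a tag's (or gene's) count x1 of library total n1
against x2 of n2 with the classical two-proportion Z statistic for digital
expression data (Kal et al.):

    p_i = x_i / n_i,   p0 = (x1 + x2) / (n1 + n2)
    Z = (p1 - p2) / sqrt(p0 (1 - p0) (1/n1 + 1/n2))

with a two-sided normal tail probability p = 2 (1 - Phi(|Z|)).  A record is
called differentially expressed when its expression ratio (B/A on TPM)
exceeds the fold threshold (strictly > 2 or < 0.5 by default) AND p < alpha
(0.005 by default); tags detected in exactly one library carry the ratio
sentinel 0 and the class ``library_specific``, never up/down.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ConfigurationError, PipelineError

P_FLOOR = 1e-300

UP = "up_in_B"
DOWN = "down_in_B"
NOT_DE = "not_de"
LIBRARY_SPECIFIC = "library_specific"


@dataclass(frozen=True)
class DEConfig:
    fold_threshold: float = 2.0
    alpha: float = 0.005
    stricter_alpha: float = 0.001
    tpm_threshold: float = 3.0

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ConfigurationError("fold_threshold must be > 1")
        for name in ("alpha", "stricter_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ConfigurationError(f"{name} must be in (0, 1)")


@dataclass
class GeneExpressionRecord:
    """One gene/strand contrast between library A (WT) and library B (MT)."""

    gene_id: str
    strand: str
    x1: int  # count in A (WT)
    x2: int  # count in B (MT)
    n1: int
    n2: int
    tpm1: float
    tpm2: float
    ratio: float  # B/A on TPM; sentinel 0 for library-specific records
    z: float
    p: float
    de_class: str
    q: float | None = None


def tpm_normalize(count: int, library_total: int) -> float:
    """count / library_total * 1e6 (transcripts per million)."""
    if library_total < 1:
        raise PipelineError("library_total must be >= 1")
    if not 0 <= count <= library_total:
        raise PipelineError(f"count {count} outside [0, {library_total}]")
    return count / library_total * 1e6


def expression_ratio(tpm_b: float, tpm_a: float) -> float:
    """Expression ratio B/A; the sentinel 0 when exactly one side is 0.

    Both sides 0 cannot occur after the significance filter and is an error.
    """
    if tpm_a < 0 or tpm_b < 0:
        raise ConfigurationError("TPM values must be >= 0")
    if tpm_a == 0 and tpm_b == 0:
        raise PipelineError("expression ratio undefined: both TPMs are 0")
    if tpm_a == 0 or tpm_b == 0:
        return 0.0
    return tpm_b / tpm_a


def kal_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-proportion Z statistic and two-sided normal p-value.

    Z is signed as p1 - p2 (positive when the tag is relatively more abundant
    in library A).  p is clipped to [1e-300, 1].
    """
    if n1 < 1 or n2 < 1:
        raise PipelineError("library totals must be >= 1")
    if x1 == 0 and x2 == 0:
        raise PipelineError("kal_z undefined for x1 = x2 = 0 (pooled proportion is 0)")
    p1, p2 = x1 / n1, x2 / n2
    p0 = (x1 + x2) / (n1 + n2)
    denom = math.sqrt(p0 * (1 - p0) * (1 / n1 + 1 / n2))
    if denom == 0:  # x1 = n1, x2 = n2: pooled proportion 1
        raise PipelineError("kal_z undefined: pooled proportion is 1")
    z = (p1 - p2) / denom
    p = float(min(1.0, max(P_FLOOR, 2.0 * stats.norm.sf(abs(z)))))
    return z, p


def kal_z_vectorized(
    x1: np.ndarray, n1: int | np.ndarray, x2: np.ndarray, n2: int | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized kal_z for simulation-scale workloads (same formula)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    p1, p2 = x1 / n1, x2 / n2
    p0 = (x1 + x2) / (np.asarray(n1, dtype=float) + np.asarray(n2, dtype=float))
    denom = np.sqrt(p0 * (1 - p0) * (1 / np.asarray(n1, float) + 1 / np.asarray(n2, float)))
    z = (p1 - p2) / denom
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)
    return z, p


def classify_de(ratio: float, p: float, config: DEConfig = DEConfig()) -> str:
    """Apply the twofold/alpha rule: both inequalities strict.

    The ratio sentinel 0 (library-specific) is preserved as its own class and
    never assigned a direction.
    """
    if ratio == 0.0:
        return LIBRARY_SPECIFIC
    if p < config.alpha:
        if ratio > config.fold_threshold:
            return UP
        if ratio < 1.0 / config.fold_threshold:
            return DOWN
    return NOT_DE


class UnionStats(NamedTuple):
    union_size: int
    only_a: int
    only_b: int
    shared: int


def union_stats(genes_a: Iterable[str], genes_b: Iterable[str]) -> UnionStats:
    """Exact detection-set arithmetic between the two libraries."""
    a, b = set(genes_a), set(genes_b)
    return UnionStats(len(a | b), len(a - b), len(b - a), len(a & b))


def differential_expression(
    counts_a: Mapping[tuple[str, str], float] | Mapping[str, float],
    counts_b: Mapping[tuple[str, str], float] | Mapping[str, float],
    n1: int,
    n2: int,
    config: DEConfig = DEConfig(),
    add_q: bool = False,
) -> list[GeneExpressionRecord]:
    """Build one GeneExpressionRecord per key in the union of both count maps.

    Keys may be (gene, strand) tuples (mapped per-gene counts, the default
    contrast unit) or bare signature/gene strings (signature-level testing).
    Keys at zero in both libraries are skipped.  With ``add_q`` a
    Benjamini-Hochberg q-value column is added (not part of the twofold/alpha
    call, which uses raw p).
    """
    keys = sorted(set(counts_a) | set(counts_b), key=str)
    records: list[GeneExpressionRecord] = []
    for key in keys:
        x1 = int(round(counts_a.get(key, 0)))
        x2 = int(round(counts_b.get(key, 0)))
        if x1 == 0 and x2 == 0:
            continue
        gene, strand = key if isinstance(key, tuple) else (key, ".")
        tpm1 = tpm_normalize(x1, n1)
        tpm2 = tpm_normalize(x2, n2)
        ratio = expression_ratio(tpm2, tpm1)
        z, p = kal_z(x1, n1, x2, n2)
        records.append(
            GeneExpressionRecord(
                gene_id=gene,
                strand=strand,
                x1=x1,
                x2=x2,
                n1=n1,
                n2=n2,
                tpm1=tpm1,
                tpm2=tpm2,
                ratio=ratio,
                z=z,
                p=p,
                de_class=classify_de(ratio, p, config),
            )
        )
    if add_q and records:
        qvals = stats.false_discovery_control([r.p for r in records], method="bh")
        for r, q in zip(records, qvals):
            r.q = float(q)
    return records


_COLUMNS = ["gene", "strand", "x_wt", "x_mt", "tpm_wt", "tpm_mt", "ratio", "z", "p", "de_class"]


def records_to_frame(records: list[GeneExpressionRecord]) -> pd.DataFrame:
    rows = [
        (r.gene_id, r.strand, r.x1, r.x2, r.tpm1, r.tpm2, r.ratio, r.z, r.p, r.de_class)
        + ((r.q,) if r.q is not None else ())
        for r in records
    ]
    cols = _COLUMNS + (["q"] if records and records[0].q is not None else [])
    return pd.DataFrame(rows, columns=cols)


def write_de_tsv(records: list[GeneExpressionRecord], path: str | Path) -> None:
    frame = records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_de_tsv(path: str | Path) -> list[GeneExpressionRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                GeneExpressionRecord(
                    gene_id=row["gene"],
                    strand=row["strand"],
                    x1=int(row["x_wt"]),
                    x2=int(row["x_mt"]),
                    n1=0,
                    n2=0,
                    tpm1=float(row["tpm_wt"]),
                    tpm2=float(row["tpm_mt"]),
                    ratio=float(row["ratio"]),
                    z=float(row["z"]),
                    p=float(row["p"]),
                    de_class=row["de_class"],
                    q=float(row["q"]) if "q" in row and row["q"] else None,
                )
            )
    return records
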