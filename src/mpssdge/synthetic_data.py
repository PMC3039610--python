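"""Synthetic MPSS tag libraries with known ground truth.

Emulates the design of a two-library MPSS experiment: a reference
transcriptome whose transcripts carry DpnII (GATC) anchored virtual
signatures, a long-tailed (log-normal) abundance distribution renormalized to
transcripts per million (TPM), a designated differentially expressed subset
with known fold changes, several sequencing runs per library, and the
contamination classes a real library contains (adaptor reads, reads with
ambiguous bases, per-base substitution errors, optional junk singletons).

Reads are emitted directly as fixed-length signatures: the downstream
pipeline consumes signatures, so bead loading and adaptor biochemistry are
not modeled.  Everything is driven by one seeded ``numpy.random.Generator``;
a fixed seed fixes every emitted byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from ._util import ConfigurationError, PipelineError
from .signature_qc import TagRead
from .virtual_digest import ANTISENSE, SENSE, extract_virtual_signature, find_dpnii_sites

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")

#: Adaptor sequence used for adaptor-derived contaminant reads (Illumina-style
#: ligation adaptor; any read containing it is removed by the quality filter).
DEFAULT_ADAPTER = "GATCGGAAGAGCGTCGTGTAGGGA"

_CHUNK = 200_000


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic two-library experiment.

    Defaults mirror a deep MPSS profiling design: ~10^6 signature reads per
    library split over several sequencing runs, a long-tailed log-normal
    abundance distribution (so the bulk of distinct signatures sit below
    1 TPM), ~3% contaminated reads (1% adaptor + 2% ambiguous-base), a small
    per-base substitution error rate, and a designated DE subset at known
    fold change split evenly between up- and down-regulation.
    """

    n_genes: int = 2000
    transcript_length_range: tuple[int, int] = (200, 3000)
    abundance_log10_mean: float = 0.5
    abundance_log10_sigma: float = 1.0
    de_fraction: float = 0.05
    fold_changes: tuple[float, ...] = (4.0,)
    reads_per_library: int = 1_000_000
    n_runs: int = 4
    base_error_rate: float = 0.005
    adaptor_read_fraction: float = 0.01
    ambiguous_read_fraction: float = 0.02
    antisense_fraction: float = 0.3
    singleton_junk_fraction: float = 0.0
    gatc_fraction: float = 0.98
    signature_length: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        lo, hi = self.transcript_length_range
        if lo < self.signature_length or hi < lo:
            raise ConfigurationError(
                "transcript_length_range must satisfy signature_length <= lo <= hi"
            )
        for name in (
            "de_fraction",
            "base_error_rate",
            "adaptor_read_fraction",
            "ambiguous_read_fraction",
            "antisense_fraction",
            "singleton_junk_fraction",
            "gatc_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if any(f <= 0 for f in self.fold_changes):
            raise ConfigurationError("fold_changes must be positive")
        if self.reads_per_library < 1:
            raise ConfigurationError("reads_per_library must be >= 1")
        if self.n_runs < 2:
            raise ConfigurationError("n_runs must be >= 2")
        if self.abundance_log10_sigma < 0:
            raise ConfigurationError("abundance_log10_sigma must be >= 0")
        if self.signature_length not in (21, 22):
            raise ConfigurationError("signature_length must be 21 or 22")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruthRecord:
    """True state of one synthetic gene: abundance per condition, DE label,
    and the virtual signatures a digest of its transcript yields."""

    gene_id: str
    true_tpm_A: float
    true_tpm_B: float
    fold_change: float  # configured multiplicative fold (B/A); 1 for non-DE
    de_label: str  # 'up' | 'down' | 'none'
    sense_signature: Optional[str] = None
    antisense_signature: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.de_label == "none") != (self.fold_change == 1.0):
            raise ValueError(
                f"{self.gene_id}: de_label {self.de_label!r} inconsistent with "
                f"fold_change {self.fold_change}"
            )

    @property
    def expressed(self) -> bool:
        return self.sense_signature is not None and self.true_tpm_A + self.true_tpm_B > 0

    @property
    def realized_ratio(self) -> float:
        """True TPM ratio B/A after per-condition renormalization."""
        return self.true_tpm_B / self.true_tpm_A if self.true_tpm_A > 0 else math.inf


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _strip_dpnii(seq: str) -> str:
    # Replace the C of each GATC with A until none remain (each replacement
    # removes a C, so this terminates; GATC is its own reverse complement, so
    # a clean sense strand implies a clean antisense strand too).
    sites = find_dpnii_sites(seq)
    while sites:
        p = sites[0]
        seq = seq[: p + 3] + "A" + seq[p + 4 :]
        sites = find_dpnii_sites(seq)
    return seq


def generate_transcriptome(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GroundTruthRecord]]:
    """Generate the reference and its ground truth.

    The first ceil(gatc_fraction * n_genes) genes are guaranteed an eligible
    GATC anchor (one is injected when the random sequence lacks one); the
    remaining genes have every GATC removed so that the no-signature code
    path is exercised deterministically.  Abundances are drawn log-normal in
    log10 TPM, DE genes get their fold applied in condition B, and each
    condition is renormalized so expressed-gene TPM sums to 10^6.
    """
    n = config.n_genes
    lo, hi = config.transcript_length_range
    L = config.signature_length
    n_with_site = math.ceil(config.gatc_fraction * n)
    width = max(4, len(str(n)))

    reference: dict[str, str] = {}
    sense_sigs: list[Optional[str]] = []
    anti_sigs: list[Optional[str]] = []
    lengths = rng.integers(lo, hi + 1, size=n)
    for i in range(n):
        gene_id = f"G{i + 1:0{width}d}"
        seq = _random_sequence(rng, int(lengths[i]))
        if i < n_with_site:
            if extract_virtual_signature(seq, SENSE, L) is None:
                pos = int(rng.integers(0, len(seq) - L + 1))
                seq = seq[:pos] + "GATC" + seq[pos + 4 :]
        else:
            seq = _strip_dpnii(seq)
        reference[gene_id] = seq
        s = extract_virtual_signature(seq, SENSE, L)
        a = extract_virtual_signature(seq, ANTISENSE, L)
        sense_sigs.append(s.sequence if s else None)
        anti_sigs.append(a.sequence if a else None)

    expressed_mask = np.array([s is not None for s in sense_sigs])
    abundance = np.power(10.0, rng.normal(config.abundance_log10_mean, config.abundance_log10_sigma, n))
    abundance[~expressed_mask] = 0.0
    if not expressed_mask.any():
        raise PipelineError("no gene carries an eligible GATC anchor")

    # DE assignment: even up/down split among expressed genes, folds cycling
    # through config.fold_changes.
    expressed_idx = np.flatnonzero(expressed_mask)
    n_de = int(round(config.de_fraction * len(expressed_idx)))
    de_idx = rng.choice(expressed_idx, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    n_up = (n_de + 1) // 2
    labels = np.full(n, "none", dtype=object)
    folds = np.ones(n)
    for k, gi in enumerate(de_idx):
        f = config.fold_changes[k % len(config.fold_changes)]
        if k < n_up:
            labels[gi], folds[gi] = "up", f
        else:
            labels[gi], folds[gi] = "down", 1.0 / f

    abundance_b = abundance * folds
    tpm_a = abundance / abundance.sum() * 1e6
    tpm_b = abundance_b / abundance_b.sum() * 1e6

    truth = [
        GroundTruthRecord(
            gene_id=f"G{i + 1:0{width}d}",
            true_tpm_A=float(tpm_a[i]),
            true_tpm_B=float(tpm_b[i]),
            fold_change=float(folds[i]),
            de_label=str(labels[i]),
            sense_signature=sense_sigs[i],
            antisense_signature=anti_sigs[i],
        )
        for i in range(n)
    ]
    return reference, truth


def _encode(sigs: list[str]) -> np.ndarray:
    """Signatures -> (n, L) matrix of base indices 0..3."""
    flat = np.frombuffer("".join(sigs).encode("ascii"), dtype=np.uint8)
    idx = np.zeros_like(flat)
    for code, byte in enumerate(b"ACGT"):
        idx[flat == byte] = code
    return idx.reshape(len(sigs), -1)


def simulate_library(
    reference: dict[str, str],
    ground_truth: list[GroundTruthRecord],
    condition: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    library_id: str | None = None,
) -> Iterator[TagRead]:
    """Yield exactly ``reads_per_library`` TagReads for one condition.

    Per read: with probability ``adaptor_read_fraction`` an adaptor-derived
    sequence; else with probability ``ambiguous_read_fraction`` a signature
    with one position replaced by N; else with probability
    ``singleton_junk_fraction`` a random junk signature (unique, hence seen
    in a single run — exercises the reliability filter); else a gene drawn
    proportional to its condition abundance, emitting its antisense virtual
    signature with probability ``antisense_fraction`` (falling back to sense
    when the gene has no antisense tag) and applying i.i.d. per-base
    substitution errors.  Genes without a virtual signature never contribute.
    Run labels are uniform over ``run1..run<n_runs>``.
    """
    if condition not in ("A", "B"):
        raise ConfigurationError(f"condition must be 'A' or 'B', got {condition!r}")
    if library_id is None:
        library_id = f"lib{condition}"
    L = config.signature_length

    expressed = [g for g in ground_truth if g.expressed]
    tpms = np.array(
        [g.true_tpm_A if condition == "A" else g.true_tpm_B for g in expressed]
    )
    keep = tpms > 0
    expressed = [g for g, k in zip(expressed, keep) if k]
    tpms = tpms[keep]
    if not expressed:
        raise PipelineError("no expressed genes in this condition")
    probs = tpms / tpms.sum()

    sense_mat = _encode([g.sense_signature for g in expressed])  # type: ignore[misc]
    anti_mat = _encode(
        [g.antisense_signature or g.sense_signature for g in expressed]  # type: ignore[list-item]
    )
    has_anti = np.array([g.antisense_signature is not None for g in expressed])
    adapter_ascii = np.frombuffer(
        DEFAULT_ADAPTER[:L].ljust(L, "A").encode("ascii"), dtype=np.uint8
    )

    remaining = config.reads_per_library
    while remaining > 0:
        m = min(_CHUNK, remaining)
        remaining -= m

        adaptor_mask = rng.random(m) < config.adaptor_read_fraction
        amb_mask = ~adaptor_mask & (rng.random(m) < config.ambiguous_read_fraction)
        junk_mask = np.zeros(m, dtype=bool)
        if config.singleton_junk_fraction > 0:
            junk_mask = (
                ~adaptor_mask & ~amb_mask & (rng.random(m) < config.singleton_junk_fraction)
            )
        gidx = rng.choice(len(expressed), size=m, p=probs)
        anti_sel = (rng.random(m) < config.antisense_fraction) & has_anti[gidx]

        mat = np.where(anti_sel[:, None], anti_mat[gidx], sense_mat[gidx])
        if config.base_error_rate > 0:
            emask = rng.random((m, L)) < config.base_error_rate
            k = int(emask.sum())
            if k:
                mat[emask] = (mat[emask] + rng.integers(1, 4, size=k)) % 4
        ascii_mat = _BASES[mat]
        if amb_mask.any():
            npos = rng.integers(0, L, size=m)
            rows = np.flatnonzero(amb_mask)
            ascii_mat[rows, npos[rows]] = _N
        if junk_mask.any():
            rows = np.flatnonzero(junk_mask)
            ascii_mat[rows] = _BASES[rng.integers(0, 4, size=(len(rows), L))]
        if adaptor_mask.any():
            ascii_mat[adaptor_mask] = adapter_ascii
        runs = rng.integers(1, config.n_runs + 1, size=m)

        blob = ascii_mat.tobytes().decode("ascii")
        for i in range(m):
            yield TagRead(blob[i * L : (i + 1) * L], library_id, f"run{runs[i]}")


def simulate_experiment(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[GroundTruthRecord], list[TagRead], list[TagRead]]:
    """Convenience wrapper: reference + truth + both libraries, one seed."""
    rng = config.rng()
    reference, truth = generate_transcriptome(config, rng)
    reads_a = list(simulate_library(reference, truth, "A", config, rng))
    reads_b = list(simulate_library(reference, truth, "B", config, rng))
    return reference, truth, reads_a, reads_b
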