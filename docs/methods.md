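# Methods

This note documents the models and procedures implemented in `mpssdge`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate about real data.

## Signature model and virtual digest

An MPSS signature is the 21–22 nt fragment beginning at a DpnII recognition
site (`GATC`) and extending to the MmeI cut downstream. The virtual digest
reproduces this on the reference transcriptome: on each strand (the
transcript itself for *sense*, its reverse complement for *antisense*) the
anchor is the **3'-most** `GATC` with at least `signature_length − 4` bases
downstream, the classical MPSS/SAGE convention for 3'-anchored tags. The
anchor rule is configurable (`3p` | `5p` | `all`); `all` indexes every
eligible site and is useful when tags may derive from internal sites.
Coordinates are 0-based half-open; antisense anchors are reported on the
antisense strand's own coordinates. `GATC` is its own reverse complement, so
a transcript without a sense site also has no antisense site.

Signatures shared by several index entries carry an ambiguity class
(`multi_gene` when several genes collide on one strand, `multi_strand` when
sense and antisense entries collide). The default mapping policy excludes
ambiguous signatures from per-gene counts and tallies them separately, so
every read is counted exactly once; a `fractional` policy (equal split over
hits) is available but off by default. Count conservation —
Σ(gene, strand) + unmapped + ambiguous = Σ table counts — is asserted at
run time.

## Filtering stages

Three ordered filters, named for what they remove:

1. **Quality**: a read is removed iff it contains ≥1 ambiguous base (`N`),
   any configured adaptor sequence as an exact substring (no
   mismatch-tolerant matching), or a length outside the configured signature
   length ± 1.
2. **Run reliability** (`min_runs = 2`): signatures supported by fewer than
   two distinct sequencing runs of the library are removed; single-run
   signatures are characteristic MPSS artifacts. The library total — the
   TPM denominator — is recomputed from the retained reads.
3. **TPM significance** (threshold 3, inclusive): a signature is retained
   iff it reaches ≥ 3 TPM in at least one of the two libraries, evaluated on
   each library's post-reliability total. The decision is symmetric in the
   libraries and idempotent.

TPM is `count / library_total × 10^6`. The raw-stage table normalizes
against the high-quality total and the post-reliability table against the
reliable total; the post-significance tables deliberately **keep** the
reliable total as denominator (removing background signatures should not
inflate the TPM of the survivors), so only pre-significance tables sum to
10^6 TPM exactly. Percentages in accounting reports are rounded half-up
(2 decimals for quality and GC rows, 1 decimal for the unreliable row).

## Differential expression

The contrast unit is the mapped (gene, strand) count by default; a
signature-level contrast is available by passing signature-keyed count maps.
For counts x1 (library A, "WT") and x2 (library B, "MT") of totals n1, n2:

- `p_i = x_i / n_i`, `p0 = (x1 + x2)/(n1 + n2)`,
  `Z = (p1 − p2) / sqrt(p0 (1 − p0)(1/n1 + 1/n2))`, two-sided
  `p = 2(1 − Φ(|Z|))` floored at 10⁻³⁰⁰. Z² is algebraically the Pearson
  chi-square statistic of the 2×2 table, which the test suite verifies
  exhaustively against an independent implementation.
- DE call: `up_in_B` iff ratio > 2 **and** p < 0.005; `down_in_B` iff
  ratio < 0.5 **and** p < 0.005; both inequalities strict. The thresholds
  (fold 2, α 0.005, stricter α 0.001 for reporting) are configurable.
- Tags at zero in exactly one library get the ratio sentinel 0 and the class
  `library_specific`; they are never assigned a direction, and their Z is
  still computable. Tags at zero in both libraries cannot occur after the
  significance filter and raise.
- No multiple-testing correction is applied by default (the rule operates on
  raw p); Benjamini–Hochberg q-values can be appended as an extra column.

The normal approximation requires non-tiny expected counts; the type-I
calibration check therefore simulates null genes with expected counts ≥ 10.
Below that regime the test is anticonservative and an exact binomial test
would be preferable (out of scope here).

## Synthetic data generator

The generator emulates the structure of a deep two-library MPSS experiment:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 2000 | desk-scale transcriptome; tests use 50–2000 |
| `transcript_length_range` | 200–3000 nt | typical unigene/EST lengths |
| `abundance_log10_mean/sigma` | 0.5 / 1.0 | log-normal log10-TPM; reproduces the long tail where most distinct signatures sit below a few TPM while a handful exceed 1000 TPM |
| `reads_per_library` | 10⁶ | the depth of one MPSS library (1–2 million sampled transcripts) |
| `n_runs` | 4 | several sequencing runs per library; the per-run split is uniform — real run sizes vary, but no published split is available to emulate |
| `adaptor_read_fraction` | 0.01 | with `ambiguous_read_fraction` 0.02, ≈3% low-quality reads, the level seen in real libraries |
| `base_error_rate` | 0.005 | per-base substitution; short-read error scale |
| `antisense_fraction` | 0.3 | a substantial minority of tags from antisense transcription, as deep tag libraries show |
| `de_fraction`, `fold_changes` | 0.05, (4,) | designated DE subset, split evenly up/down |
| `gatc_fraction` | 0.98 | fraction of genes guaranteed an eligible anchor; the remainder have every GATC removed so the no-signature path is deterministic |
| `singleton_junk_fraction` | 0 | optional random junk tags (unique ⇒ single-run) to exercise the reliability filter |

Abundances are drawn per gene, zeroed for genes without a signature, and
renormalized so expressed-gene TPM sums to 10⁶ per condition. DE folds are
applied multiplicatively in condition B before renormalization;
`fold_change` in the ground truth records the configured fold (1 for
non-DE), while the *realized* ratio after renormalization is
`true_tpm_B / true_tpm_A` — the quantity ratio-recovery checks compare
against, since renormalization shifts all ratios by a common factor.

Reads are emitted as fixed-length signatures with constant FASTQ qualities:
the pipeline consumes signatures and never uses base qualities, and bead
loading/adaptor biochemistry is out of scope. Consequences for
interpretation: passing tests demonstrate correctness of counting,
filtering, mapping and testing logic under binomial sampling noise, but not
robustness to real-data features the generator omits — sequence-composition
bias, PCR duplication, run-size imbalance, per-cycle quality decay, or
cross-hybridization artifacts.

Everything is driven by one `numpy.random.Generator` seeded from the
config; a fixed seed fixes every emitted byte, and all writers order their
output deterministically, which the byte-level determinism check exercises
end to end.

## Reporting conventions

Abundance bins follow percent-of-library arithmetic: 0.0001% of 10⁶ = 1 TPM,
0.001% = 10, 0.01% = 100, 0.1% = 1000; edges are lower-closed/upper-open
with an unbounded top bin (exactly 1000 TPM is in the top bin), and a zero
bin holds union signatures absent from the library at hand. Ratio bins —
{0}, (0, 0.2), [0.2, 0.5), [0.5, 2], (2, 5], (5, ∞) — mirror the DE rule's
strict inequalities, so "twofold or greater" equals count(r > 2) +
count(r < 0.5) exactly. Accounting tables omit EST contig/singleton rows
(assembly is out of scope) with a footnote.

The recovery report is direction-aware: a true positive is a truly-DE gene
called in its true direction; a wrong-direction call counts as both a false
positive and a false negative. Strata are defined on a gene's larger true
TPM; precision over an empty call set is reported as NA.

## Problem sizes

The validation suite uses 4×10⁴–10⁶ reads per library and 300–2000 genes:
10⁶ noiseless reads for the recovery run (directional recall ≥ 90% for DE
genes with true TPM ≥ 50, in practice 100%), 2×10⁵ reads at full
contamination for integration tests, 20,000 null genes for type-I
calibration, and the exhaustive 51×51 count grid for the chi-square
equivalence check. These sizes give binomial standard errors comfortably
inside the asserted tolerances while keeping the whole suite under a minute.

## Known limitations

- The Z test assumes large library totals and non-tiny expected counts; no
  overdispersion (biological replication) is modeled — the two libraries
  are treated as exhaustive samples, as is standard for MPSS-era analysis.
- Mapping is exact-match only; sequencing errors in real tags land in
  `unmapped` rather than being rescued by mismatch-tolerant search.
- One signature per gene per strand under the default anchor rule; genes
  whose dominant tag derives from an internal site need `anchor="all"`.
- The significance filter operates at the signature level before mapping;
  gene-level TPM aggregation happens after mapping.
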