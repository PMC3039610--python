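"""Virtual restriction digest and tag-to-gene mapping.

MPSS/SAGE signatures are anchored at a DpnII recognition site (GATC) and
extend to the MmeI cut 21-22 nt downstream.  This module reproduces that
digest in silico on a reference transcriptome: for every transcript it
extracts one virtual signature per strand (the transcript's own strand gives
the *sense* tag, its reverse complement the *antisense* tag), builds a
signature -> (gene, strand, position) index, and assigns observed signature
counts to genes through exact lookup.

Signatures shared by several index entries are classified by ambiguity
(``multi_gene`` when one strand of several genes collides, ``multi_strand``
when sense and antisense entries collide) and are, by default, excluded from
per-gene counts and tallied separately so no read is ever double counted.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

from Bio import SeqIO

from ._util import ConfigurationError, PipelineError, reverse_complement

DPNII_SITE = "GATC"
SENSE = "sense"
ANTISENSE = "antisense"

ANCHOR_CHOICES = ("3p", "5p", "all")
AMBIGUITY_POLICIES = ("exclude", "fractional")


@dataclass(frozen=True)
class VirtualTag:
    """One in-silico signature: gene, strand, and 0-based anchor offset.

    ``start`` is the offset of the GATC anchor on the tag's own strand
    (for antisense tags, coordinates on the reverse-complemented transcript).
    """

    gene_id: str
    strand: str
    start: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence.startswith(DPNII_SITE):
            raise ValueError(f"virtual tag does not start with {DPNII_SITE}: {self.sequence}")


def find_dpnii_sites(sequence: str) -> list[int]:
    """All 0-based positions p with sequence[p:p+4] == 'GATC', ascending.

    Overlapping occurrences are all reported; positions containing N never
    match (exact string comparison).
    """
    sites = []
    p = sequence.find(DPNII_SITE)
    while p != -1:
        sites.append(p)
        p = sequence.find(DPNII_SITE, p + 1)
    return sites


def _eligible_sites(strand_seq: str, signature_length: int) -> list[int]:
    return [p for p in find_dpnii_sites(strand_seq) if p + signature_length <= len(strand_seq)]


def extract_virtual_signature(
    sequence: str,
    strand: str,
    signature_length: int,
    gene_id: str = "",
    anchor: str = "3p",
) -> Optional[VirtualTag]:
    """Extract the virtual signature on one strand, or None when no site fits.

    The tag is the GATC anchor plus the following ``signature_length - 4``
    bases; a site too close to the 3' end to provide them is ineligible.
    ``anchor`` selects the 3'-most (classical MPSS convention) or 5'-most
    eligible site.
    """
    if signature_length not in (21, 22):
        raise ConfigurationError("signature_length must be 21 or 22")
    if strand not in (SENSE, ANTISENSE):
        raise ConfigurationError(f"strand must be {SENSE!r} or {ANTISENSE!r}")
    if anchor not in ("3p", "5p"):
        raise ConfigurationError(f"anchor must be '3p' or '5p', got {anchor!r}")
    strand_seq = sequence if strand == SENSE else reverse_complement(sequence)
    sites = _eligible_sites(strand_seq, signature_length)
    if not sites:
        return None
    p = max(sites) if anchor == "3p" else min(sites)
    return VirtualTag(gene_id, strand, p, strand_seq[p : p + signature_length])


def _iter_all_tags(
    sequence: str, strand: str, signature_length: int, gene_id: str
) -> Iterator[VirtualTag]:
    strand_seq = sequence if strand == SENSE else reverse_complement(sequence)
    for p in _eligible_sites(strand_seq, signature_length):
        yield VirtualTag(gene_id, strand, p, strand_seq[p : p + signature_length])


@dataclass
class TagIndex:
    """Lookup from signature sequence to the virtual tags that produce it."""

    signature_length: int
    entries: dict[str, list[VirtualTag]] = field(default_factory=dict)

    def __contains__(self, signature: str) -> bool:
        return signature in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, signature: str) -> list[VirtualTag]:
        return self.entries.get(signature, [])

    def lookup_prefix(self, signature: str) -> list[VirtualTag]:
        """Exact lookup, falling back to matching a shorter observed read
        against tag prefixes (models MmeI 21/22 cut heterogeneity: a 21-mer
        read may derive from a 22-mer tag)."""
        hits = self.entries.get(signature, [])
        if hits or len(signature) >= self.signature_length:
            return hits
        cache = getattr(self, "_prefix_cache", None)
        if cache is None:
            cache = self._prefix_cache = {}
        k = len(signature)
        if k not in cache:
            pref: dict[str, list[VirtualTag]] = defaultdict(list)
            for seq, tags in self.entries.items():
                pref[seq[:k]].extend(tags)
            cache[k] = dict(pref)
        return cache[k].get(signature, [])

    def ambiguity_class(self, signature: str) -> str:
        """'unique', 'multi_strand' (both strands hit) or 'multi_gene'."""
        tags = self.entries[signature]
        if len(tags) == 1:
            return "unique"
        if len({t.strand for t in tags}) > 1:
            return "multi_strand"
        return "multi_gene"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["signature", "gene_id", "strand", "start"])
            for sig in sorted(self.entries):
                for t in self.entries[sig]:
                    w.writerow([sig, t.gene_id, t.strand, t.start])

    @classmethod
    def from_tsv(cls, path: str | Path, signature_length: int | None = None) -> "TagIndex":
        entries: dict[str, list[VirtualTag]] = defaultdict(list)
        length = signature_length
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                sig = row["signature"]
                if length is None:
                    length = len(sig)
                entries[sig].append(
                    VirtualTag(row["gene_id"], row["strand"], int(row["start"]), sig)
                )
        if length is None:
            raise PipelineError("empty tag index file")
        return cls(signature_length=length, entries=dict(entries))


def build_tag_index(
    reference: Mapping[str, str] | str | Path,
    signature_length: int = 21,
    anchor: str = "3p",
) -> TagIndex:
    """Digest every reference transcript on both strands into a TagIndex.

    ``reference`` is a gene_id -> sequence mapping or a FASTA path.  With
    ``anchor='all'`` every eligible site contributes a tag; otherwise one tag
    per gene per strand.  Duplicate gene identifiers are an error.
    """
    if anchor not in ANCHOR_CHOICES:
        raise ConfigurationError(f"anchor must be one of {ANCHOR_CHOICES}, got {anchor!r}")
    if isinstance(reference, (str, Path)):
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(reference), "fasta"):
            if rec.id in seqs:
                raise PipelineError(f"duplicate gene identifier in FASTA: {rec.id}")
            seqs[rec.id] = str(rec.seq).upper()
        reference = seqs
    if not reference:
        raise PipelineError("reference is empty")
    entries: dict[str, list[VirtualTag]] = defaultdict(list)
    for gene_id, seq in reference.items():
        for strand in (SENSE, ANTISENSE):
            if anchor == "all":
                tags: Iterable[VirtualTag] = _iter_all_tags(seq, strand, signature_length, gene_id)
            else:
                tag = extract_virtual_signature(seq, strand, signature_length, gene_id, anchor)
                tags = [tag] if tag is not None else []
            for t in tags:
                entries[t.sequence].append(t)
    return TagIndex(signature_length=signature_length, entries=dict(entries))


@dataclass
class MappingResult:
    """Per (gene, strand) mapped counts plus unmapped/ambiguous tallies."""

    counts: dict[tuple[str, str], float] = field(default_factory=dict)
    unmapped: float = 0.0
    ambiguous: float = 0.0
    total: float = 0.0

    def gene_counts(self, strand: str | None = None) -> dict[str, float]:
        out: dict[str, float] = defaultdict(float)
        for (gene, s), c in self.counts.items():
            if strand is None or s == strand:
                out[gene] += c
        return dict(out)

    def strand_total(self, strand: str) -> float:
        return sum(c for (_, s), c in self.counts.items() if s == strand)

    def genes_detected(self, strand: str | None = None) -> set[str]:
        return {g for (g, s), c in self.counts.items() if c > 0 and (strand is None or s == strand)}

    def mapped_total(self) -> float:
        return sum(self.counts.values())

    def check_conservation(self) -> None:
        got = self.mapped_total() + self.unmapped + self.ambiguous
        if abs(got - self.total) > 1e-6 * max(1.0, self.total):
            raise PipelineError(f"count conservation violated: {got} != {self.total}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene_id", "strand", "count"])
            for (gene, strand) in sorted(self.counts):
                w.writerow([gene, strand, _fmt_count(self.counts[(gene, strand)])])
            w.writerow(["__unmapped__", ".", _fmt_count(self.unmapped)])
            w.writerow(["__ambiguous__", ".", _fmt_count(self.ambiguous)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MappingResult":
        res = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                c = float(row["count"])
                if row["gene_id"] == "__unmapped__":
                    res.unmapped = c
                elif row["gene_id"] == "__ambiguous__":
                    res.ambiguous = c
                else:
                    res.counts[(row["gene_id"], row["strand"])] = c
        res.total = res.mapped_total() + res.unmapped + res.ambiguous
        return res


def _fmt_count(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else repr(c)


def map_signatures(
    table,
    index: TagIndex,
    ambiguity_policy: str = "exclude",
    prefix_match: bool = False,
) -> MappingResult:
    """Assign a SignatureTable's counts to genes through the index.

    Unique signatures add their full count to their (gene, strand); signatures
    absent from the index are tallied as unmapped.  Ambiguous signatures are
    excluded and tallied (default) or split equally over their hits
    (``fractional``).  With ``prefix_match``, an observed read shorter than
    the indexed tag length may match a tag's prefix (MmeI cut
    heterogeneity); off by default.  Count conservation is exact by
    construction and verified before returning.
    """
    if ambiguity_policy not in AMBIGUITY_POLICIES:
        raise ConfigurationError(
            f"ambiguity_policy must be one of {AMBIGUITY_POLICIES}, got {ambiguity_policy!r}"
        )
    res = MappingResult()
    counts: dict[tuple[str, str], float] = defaultdict(float)
    for sig in table.signatures():
        c = table.total(sig)
        res.total += c
        tags = index.lookup_prefix(sig) if prefix_match else index.lookup(sig)
        if not tags:
            res.unmapped += c
        elif len(tags) == 1:
            t = tags[0]
            counts[(t.gene_id, t.strand)] += c
        elif ambiguity_policy == "fractional":
            share = c / len(tags)
            for t in tags:
                counts[(t.gene_id, t.strand)] += share
        else:
            res.ambiguous += c
    res.counts = dict(counts)
    res.check_conservation()
    return res
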