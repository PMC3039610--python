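"""Virtual digest: site finding, tag extraction, index, mapping conservation."""

from collections import Counter

import pytest

from mpssdge import (
    ConfigurationError,
    PipelineError,
    SignatureTable,
    build_tag_index,
    extract_virtual_signature,
    find_dpnii_sites,
    generate_transcriptome,
    map_signatures,
    SyntheticConfig,
)
from mpssdge._util import reverse_complement
from mpssdge.virtual_digest import ANTISENSE, SENSE, TagIndex


@pytest.mark.parametrize(
    "seq,sites",
    [
        ("AAAA", []),
        ("GATCGATC", [0, 4]),
        ("AGATCA", [1]),
        ("GANCGATC", [4]),  # N never matches
        ("", []),
    ],
)
def test_find_dpnii_sites(seq, sites):
    assert find_dpnii_sites(seq) == sites


def test_extract_single_site_by_hand():
    tag = extract_virtual_signature("TTGATCAAACCCGGGTTTAAACCC", SENSE, 21)
    assert tag.sequence == "GATCAAACCCGGGTTTAAACC"
    assert tag.start == 2 and tag.strand == SENSE


def test_extract_absent_cases():
    assert extract_virtual_signature("A" * 50, SENSE, 21) is None
    # only site 10 nt before the 3' end: not enough downstream bases
    seq = "A" * 30 + "GATC" + "A" * 6
    assert extract_virtual_signature(seq, SENSE, 21) is None


def test_extract_picks_three_prime_most_eligible_site():
    seq = "GATC" + "A" * 10 + "GATC" + "T" * 17 + "CC"
    tag = extract_virtual_signature(seq, SENSE, 21)
    assert tag.start == 14
    tag5 = extract_virtual_signature(seq, SENSE, 21, anchor="5p")
    assert tag5.start == 0


def test_extract_antisense_uses_reverse_complement():
    seq = "TTGATCAAACCCGGGTTTAAACCC"
    rc = reverse_complement(seq)
    # the antisense tag of the reverse complement is the sense tag of seq
    tag = extract_virtual_signature(rc, ANTISENSE, 21)
    sense_tag = extract_virtual_signature(seq, SENSE, 21)
    assert tag.sequence == sense_tag.sequence == "GATCAAACCCGGGTTTAAACC"
    # and seq itself has no eligible antisense site (too close to the 3' end)
    assert extract_virtual_signature(seq, ANTISENSE, 21) is None


def test_index_collision_classes():
    core = "GATC" + "ACGTAC" * 3  # shared 22-mer prefix holder
    tagseq = core[:21]
    g1 = "TT" + tagseq + "AAAA"
    g2 = "CCCC" + tagseq + "GG"
    idx = build_tag_index({"g1": g1, "g2": g2}, 21)
    assert idx.ambiguity_class(tagseq) == "multi_gene"

    # a gene equal to another's reverse complement: sense tag == antisense tag
    g3 = reverse_complement(g1)
    idx2 = build_tag_index({"g1": g1, "g3": g3}, 21)
    assert idx2.ambiguity_class(tagseq) == "multi_strand"


def test_index_duplicate_fasta_ids_error(tmp_path):
    fa = tmp_path / "dup.fasta"
    fa.write_text(">g1\nGATCAAACCCGGGTTTAAACCTT\n>g1\nGATCAAACCCGGGTTTAAACCTT\n")
    with pytest.raises(PipelineError, match="duplicate"):
        build_tag_index(fa, 21)


def test_index_roundtrip_with_synthetic_truth():
    cfg = SyntheticConfig(n_genes=200, seed=13)
    ref, truth = generate_transcriptome(cfg, cfg.rng())
    idx = build_tag_index(ref, cfg.signature_length)
    for g in truth:
        if g.sense_signature:
            hits = idx.lookup(g.sense_signature)
            assert any(t.gene_id == g.gene_id and t.strand == SENSE for t in hits)


def test_index_tsv_serialization_lossless(tmp_path):
    idx = build_tag_index(
        {"g1": "TTGATCAAACCCGGGTTTAAACCC", "g2": "AAGATCGTGTGTGTGTGTGTGTGTA"}, 21
    )
    path = tmp_path / "index.tsv"
    idx.to_tsv(path)
    idx2 = TagIndex.from_tsv(path)
    assert idx2.signature_length == 21

    def flat(index):
        return {
            s: sorted((t.gene_id, t.strand, t.start) for t in v)
            for s, v in index.entries.items()
        }

    assert flat(idx) == flat(idx2)


def _table(counts):
    return SignatureTable("lib", {s: Counter({"r1": c}) for s, c in counts.items()},
                          sum(counts.values()))


def test_map_unmapped_and_ambiguous_policies():
    tagseq = ("GATC" + "ACGTAC" * 3)[:21]
    idx = build_tag_index({"g1": "TT" + tagseq + "AAAA", "g2": "CCCC" + tagseq + "GG"}, 21)
    table = _table({tagseq: 10, "T" * 21: 50})
    res = map_signatures(table, idx)
    assert res.unmapped == 50 and res.ambiguous == 10
    assert res.mapped_total() + res.unmapped + res.ambiguous == res.total == 60

    frac = map_signatures(table, idx, "fractional")
    assert frac.ambiguous == 0
    assert frac.counts[("g1", SENSE)] == pytest.approx(5.0)
    with pytest.raises(ConfigurationError):
        map_signatures(table, idx, "bogus")


def test_prefix_match_maps_short_reads_against_longer_tags():
    seq = "TTGATCAAACCCGGGTTTAAACCC"
    idx = build_tag_index({"g1": seq}, 22)
    tag22 = extract_virtual_signature(seq, SENSE, 22).sequence
    table = _table({tag22[:21]: 7})
    strict = map_signatures(table, idx)
    assert strict.unmapped == 7
    relaxed = map_signatures(table, idx, prefix_match=True)
    assert relaxed.counts[("g1", SENSE)] == 7 and relaxed.unmapped == 0


def test_strand_antisymmetry_under_reference_reverse_complement():
    cfg = SyntheticConfig(n_genes=100, seed=17)
    ref, truth = generate_transcriptome(cfg, cfg.rng())
    table = _table({g.sense_signature: 5 for g in truth if g.sense_signature})
    idx_fwd = build_tag_index(ref, 21)
    idx_rev = build_tag_index({k: reverse_complement(v) for k, v in ref.items()}, 21)
    res_fwd = map_signatures(table, idx_fwd)
    res_rev = map_signatures(table, idx_rev)
    assert res_fwd.strand_total(SENSE) == res_rev.strand_total(ANTISENSE)
    assert res_fwd.strand_total(ANTISENSE) == res_rev.strand_total(SENSE)
    assert res_fwd.unmapped == res_rev.unmapped
    assert res_fwd.ambiguous == res_rev.ambiguous


def test_mapping_result_tsv_roundtrip(tmp_path, small_result):
    path = tmp_path / "mapping.tsv"
    small_result.mapping_a.to_tsv(path)
    from mpssdge.virtual_digest import MappingResult

    again = MappingResult.from_tsv(path)
    assert again.counts == small_result.mapping_a.counts
    assert again.unmapped == small_result.mapping_a.unmapped
    assert again.ambiguous == small_result.mapping_a.ambiguous
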