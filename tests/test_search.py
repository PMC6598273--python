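"""Bidirectional index contract, scheme completeness, oracle equivalence of
the indexed search, and merge/filter semantics."""

import itertools

import numpy as np
import pytest

from varguide._dna import revcomp
from varguide.fixtures import (GenomeSequence, PlantSpec, SyntheticSpec,
                               Variant, generate_genome, plant_offtargets,
                               random_guide)
from varguide.search import (BidirectionalIndex, GuideError, PamSet,
                             brute_force_search, default_scheme,
                             merge_and_filter, search_guide,
                             window_sequences, write_bed)
from varguide.variant_genome import build_variant_genome


def hit_key(h):
    return (h.contig, h.start, h.strand, h.n_mismatches)


# -- index ------------------------------------------------------------------

def test_bidirectional_extension_order_independent():
    idx = BidirectionalIndex([GenomeSequence("s", "ACGT")])
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    # locate "CG" by prepend-then-append and append-then-prepend
    a = idx.extend_right(idx.extend_left(idx.root(), enc["C"]), enc["G"])
    b = idx.extend_left(idx.extend_right(idx.root(), enc["G"]), enc["C"])
    assert a == b
    assert sorted(idx.locate(a)) == [1]


def test_index_counts_match_naive_kmer_counts():
    genome = generate_genome(SyntheticSpec(genome_length=10_000, rng_seed=47))
    idx = BidirectionalIndex([genome])
    seq = genome.seq
    for kmer in ("".join(p) for p in itertools.product("ACGT", repeat=4)):
        naive = sum(seq[i:i + 4] == kmer for i in range(len(seq) - 3))
        assert idx.count(kmer) == naive


def test_index_rejects_empty_input():
    with pytest.raises(ValueError):
        BidirectionalIndex([])


# -- scheme -----------------------------------------------------------------

@pytest.mark.parametrize("k", [0, 1, 2, 3])
def test_scheme_enumerates_every_error_pattern_exactly_once(k):
    scheme = default_scheme(k)
    positions = range(20)
    for m in range(k + 2):
        for pattern in itertools.combinations(positions, m):
            accepting = scheme.accepting_searches(frozenset(pattern))
            assert len(accepting) == (1 if m <= k else 0), (pattern, accepting)


# -- guide search -----------------------------------------------------------

def test_exact_planted_site_found_and_pam_gated(guide):
    genome = generate_genome(SyntheticSpec(genome_length=5000, rng_seed=53))
    edited, (site,) = plant_offtargets(
        genome, PlantSpec(guide=guide, n_sites=1, mismatch_counts=(0,)),
        seed=54)
    idx = BidirectionalIndex([edited])
    hits = search_guide(idx, guide, PamSet(("NGG",)), 0)
    assert [(h.start, h.strand, h.n_mismatches) for h in hits] == \
        [(site.start, "+", 0)]
    assert search_guide(idx, guide, PamSet(("NGA",)), 0) == []


def test_search_validates_guide(small_genome):
    idx = BidirectionalIndex([small_genome])
    with pytest.raises(GuideError):
        search_guide(idx, "ACGT", PamSet())
    with pytest.raises(ValueError):
        search_guide(idx, "A" * 20, PamSet(), max_mismatches=9)


def test_empty_pamset_brute_force_is_empty(small_genome, guide):
    hits = brute_force_search([small_genome], guide, PamSet(motifs=()), 8)
    assert hits == []


def test_polyA_guide_hits_only_where_gg_follows():
    genome = GenomeSequence("s", "A" * 40 + "GG" + "A" * 10)
    hits = brute_force_search([genome], "A" * 20 + "AGG", PamSet(("NGG",)), 0)
    # PAM NGG needs GG at protospacer offsets 21..22, i.e. start = 19
    assert {(h.start, h.strand) for h in hits} == {(19, "+")}


@pytest.mark.parametrize("pams", [("NGG",), ("NGG", "NGA")])
def test_indexed_search_equals_brute_force(guide, pams):
    genome = generate_genome(SyntheticSpec(genome_length=15_000, rng_seed=59))
    edited, _sites = plant_offtargets(
        genome, PlantSpec(guide=guide, n_sites=5,
                          mismatch_counts=(0, 2, 4, 6, 8),
                          pam_choices=pams, strand_mix=0.5), seed=60)
    idx = BidirectionalIndex([edited])
    for k in range(9):
        a = search_guide(idx, guide, PamSet(pams), k)
        b = brute_force_search([edited], guide, PamSet(pams), k)
        assert {hit_key(h) for h in a} == {hit_key(h) for h in b}


def test_hit_sets_grow_monotonically_with_budget(planted, guide):
    edited, _ = planted
    idx = BidirectionalIndex([edited])
    prev = set()
    for k in range(9):
        cur = {hit_key(h) for h in search_guide(idx, guide, PamSet(("NGG",)), k)}
        assert prev <= cur
        prev = cur


def test_mismatch_positions_are_strand_invariant(guide):
    genome = generate_genome(SyntheticSpec(genome_length=5000, rng_seed=61))
    edited, sites = plant_offtargets(
        genome, PlantSpec(guide=guide, n_sites=2, mismatch_counts=(3, 3),
                          strand_mix=1.0), seed=62)
    hits = brute_force_search([edited], guide, PamSet(("NGG",)), 3)
    by_pos = {(h.start, h.strand): h for h in hits}
    for s in sites:
        h = by_pos[(s.start, "-")]
        assert h.mismatch_positions == s.mismatch_positions
        assert h.protospacer == s.protospacer  # guide-oriented read


def test_n_bases_never_match():
    guide = "ACGT" * 5 + "AGG"
    genome = GenomeSequence("s", "TTTT" + guide[:20] + "AGG" + "TTTT")
    n_genome = GenomeSequence("s", "TTTT" + "N" + guide[1:20] + "AGG" + "TTTT")
    assert brute_force_search([genome], guide, PamSet(("NGG",)), 0)
    hits = brute_force_search([n_genome], guide, PamSet(("NGG",)), 0)
    assert hits == []
    hits1 = brute_force_search([n_genome], guide, PamSet(("NGG",)), 1)
    assert [h.n_mismatches for h in hits1] == [1]


# -- merge and filter -------------------------------------------------------

def _merge_fixture(guide):
    genome = generate_genome(SyntheticSpec(genome_length=20_000, rng_seed=67))
    edited, sites = plant_offtargets(
        genome, PlantSpec(guide=guide, n_sites=3,
                          mismatch_counts=(0, 0, 2)), seed=68)
    return edited, sites


def test_on_target_origin_removed_but_twin_flagged(guide):
    edited, sites = _merge_fixture(guide)
    perfect = [s for s in sites if not s.mismatch_positions]
    origin = (edited.name, perfect[0].start, perfect[0].strand)
    hits = brute_force_search([edited], guide, PamSet(("NGG",)), 2)
    merged = merge_and_filter(hits, [], [], on_targets=[origin])
    starts = {h.start for h in merged}
    assert perfect[0].start not in starts
    twin = [h for h in merged if h.start == perfect[1].start][0]
    assert "perfect_match" in twin.flags


def test_hom_alt_variant_removes_reference_hit(guide):
    edited, sites = _merge_fixture(guide)
    site = sites[0]
    pos0 = site.start + 5
    ref = edited.seq[pos0]
    v = Variant(edited.name, pos0 + 1, ref, "A" if ref != "A" else "C",
                (1, 1), True, "hom")
    windows = build_variant_genome(edited, [v])
    hits = brute_force_search([edited], guide, PamSet(("NGG",)), 2)
    merged = merge_and_filter(hits, [], windows, on_targets=[])
    assert site.start not in {h.start for h in merged if h.source == "reference"}


def test_het_variant_keeps_reference_hit(guide):
    edited, sites = _merge_fixture(guide)
    site = sites[0]
    pos0 = site.start + 5
    ref = edited.seq[pos0]
    v = Variant(edited.name, pos0 + 1, ref, "A" if ref != "A" else "C",
                (0, 1), True, "het")
    windows = build_variant_genome(edited, [v])
    hits = brute_force_search([edited], guide, PamSet(("NGG",)), 2)
    merged = merge_and_filter(hits, [], windows, on_targets=[])
    assert site.start in {h.start for h in merged if h.source == "reference"}


def test_duplicate_variant_hits_collapse_with_union_of_ids(guide):
    """The same site reached via combinations {v1} and {v1,v2} must come out
    as a single record."""
    genome = generate_genome(SyntheticSpec(genome_length=10_000, rng_seed=71))
    edited, (site,) = plant_offtargets(
        genome, PlantSpec(guide=guide, n_sites=1, mismatch_counts=(2,)),
        seed=72)
    p = site.mismatch_positions[0]
    pos0 = site.start + (p - 1)
    v1 = Variant(edited.name, pos0 + 1, edited.seq[pos0], guide[p - 1],
                 (0, 1), False, "v1")
    # a second unphased het just outside the protospacer, inside the window
    pos2 = site.start + 30
    ref2 = edited.seq[pos2]
    v2 = Variant(edited.name, pos2 + 1, ref2, "A" if ref2 != "A" else "C",
                 (0, 1), False, "v2")
    windows = build_variant_genome(edited, sorted([v1, v2],
                                                  key=lambda v: v.pos))
    (w,) = windows
    assert len(w.allele_sequences) == 3  # {v1}, {v2}, {v1,v2}
    seqs, resolver = window_sequences(windows)
    var_hits = search_guide(BidirectionalIndex(seqs), guide,
                            PamSet(("NGG",)), 1)
    merged = merge_and_filter([], var_hits, windows, on_targets=[],
                              resolver=resolver)
    at_site = [h for h in merged if h.start == site.start]
    assert len(at_site) == 1
    assert at_site[0].variant_ids == ("v1",)
    assert at_site[0].n_mismatches == 1


def test_bed_output_is_bed6_plus(tmp_path, guide, planted):
    edited, _ = planted
    hits = brute_force_search([edited], guide, PamSet(("NGG",)), 4,
                              guide_id="g1")
    path = tmp_path / "hits.bed"
    write_bed(hits, path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == len(hits)
    for line in lines:
        f = line.split("\t")
        assert len(f) == 11
        assert f[0] == edited.name and f[3] == "g1"
        assert int(f[2]) - int(f[1]) == 23
        assert f[5] in "+-"
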