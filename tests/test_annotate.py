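import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_ref_hits
from saltmir.annotate import (
    AnnotationContext,
    GenomeHit,
    GenomeIndex,
    ReferenceMatcher,
    categorize,
    category_distribution,
    map_perfect,
    match_with_mismatches,
)
from saltmir.io import revcomp

SEQ = st.text(alphabet="ACGT", min_size=18, max_size=30)


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(42)
    return {"chr1": "".join(rng.choice(list("ACGT"), 600))}


def test_plus_strand_hit(toy_genome):
    tag = toy_genome["chr1"][100:121]
    hits = map_perfect([tag], toy_genome)[tag]
    assert GenomeHit("chr1", 100, 121, "+") in hits
    for h in hits:
        assert h.end - h.start == len(tag)


def test_minus_strand_hit(toy_genome):
    tag = revcomp(toy_genome["chr1"][100:121])
    hits = map_perfect([tag], toy_genome)[tag]
    assert GenomeHit("chr1", 100, 121, "-") in hits


def test_absent_tag_unmapped(toy_genome):
    tag = "A" * 25  # vanishingly unlikely in random background; check anyway
    assert tag not in toy_genome["chr1"]
    assert map_perfect([tag], toy_genome)[tag] == []


def test_all_occurrences_returned():
    genome = {"chr1": "T" * 40 + "ACGTACGTACGTACGTACGTAC" + "G" * 30 + "ACGTACGTACGTACGTACGTAC"}
    tag = "ACGTACGTACGTACGTACGTAC"
    hits = map_perfect([tag], genome)[tag]
    assert {(h.start, h.strand) for h in hits} >= {(40, "+"), (92, "+")}


# ---------------------------------------------------------------------------
# mismatch matching


def test_exact_reference_hit():
    refs = {"m1": "ACGTACGTACGTACGTACGTA"}
    hits = match_with_mismatches("ACGTACGTACGTACGTACGTA", refs, 2)
    assert hits[0].ref_id == "m1" and hits[0].distance == 0


def test_three_mismatches_rejected():
    ref = "AAAAAAAAAAAAAAAAAAAAA"
    tag = "AAATAAATAAATAAAAAAAAA"
    assert match_with_mismatches(tag, {"m1": ref}, 2) == []


def test_tag_longer_than_reference_skipped():
    assert match_with_mismatches("A" * 25, {"m1": "A" * 21}, 2) == []


def test_sliding_offset_hit():
    ref = "G" + "ACGTACGTACGTACGTACGTA"  # tag at offset 1 with 1 substitution
    tag = "ACGTACGTACGTACGTACGTT"
    hits = match_with_mismatches(tag, {"m1": ref}, 2)
    assert hits == [(("m1"), 1, 1)]


@settings(max_examples=200, deadline=None)
@given(st.integers(0, 100_000), st.integers(0, 3))
def test_matcher_agrees_with_brute_force(seed, max_mm):
    rng = np.random.default_rng(seed)
    refs = {
        f"r{i}": "".join(rng.choice(list("ACGT"), int(rng.integers(18, 50))))
        for i in range(4)
    }
    n = int(rng.integers(18, 31))
    if rng.random() < 0.5:
        base = refs[f"r{int(rng.integers(0, 4))}"]
        if len(base) >= n:
            start = int(rng.integers(0, len(base) - n + 1))
            tag = list(base[start : start + n])
            for _ in range(int(rng.integers(0, 4))):
                tag[int(rng.integers(0, n))] = str(rng.choice(list("ACGT")))
            tag = "".join(tag)
        else:
            tag = "".join(rng.choice(list("ACGT"), n))
    else:
        tag = "".join(rng.choice(list("ACGT"), n))
    expected = brute_ref_hits(tag, refs, max_mm)
    assert [tuple(h) for h in match_with_mismatches(tag, refs, max_mm)] == expected
    seeded = ReferenceMatcher(refs, max_mm).find(tag)
    assert [tuple(h) for h in seeded] == expected


# ---------------------------------------------------------------------------
# categorization


@pytest.fixture(scope="module")
def ctx():
    return AnnotationContext(
        mature_ref={"peu-miR1a": "ACGTACGTACGTACGTACGTA"},
        ncrna_ref={"rRNA_1": "TTTTGGGGCCCCAAAATTTTGGGGCCCC"},
        exons=[
            ("chr1", 100, 200, "+", "tx1"),
            ("chr1", 300, 400, "+", "tx1"),
        ],
        repeats=[("chr1", 500, 600)],
    )


def hit(start, end, strand="+"):
    return GenomeHit("chr1", start, end, strand)


def test_known_mirna_beats_exon(ctx):
    # matches the mature reference AND overlaps an exon: miRNA wins
    assert categorize("ACGTACGTACGTACGTACGTA", [hit(150, 171)], ctx) == "known_miRNA"


def test_exon_antisense(ctx):
    tag = "G" * 21
    assert categorize(tag, [hit(120, 141, "-")], ctx) == "exon_antisense"


def test_exon_sense(ctx):
    assert categorize("G" * 21, [hit(120, 141, "+")], ctx) == "exon_sense"


def test_intron_derived_from_exon_gap(ctx):
    assert categorize("G" * 21, [hit(220, 241, "+")], ctx) == "intron_sense"
    assert categorize("G" * 21, [hit(220, 241, "-")], ctx) == "intron_antisense"


def test_ncrna_exact_substring(ctx):
    assert categorize("TTTTGGGGCCCCAAAATTTT", [hit(700, 720)], ctx) == "ncRNA"


def test_repeat(ctx):
    assert categorize("G" * 21, [hit(510, 531)], ctx) == "repeat"


def test_unknown_and_unmapped(ctx):
    assert categorize("G" * 21, [hit(700, 721)], ctx) == "unknown"
    assert categorize("G" * 21, [], ctx) == "unmapped"


def test_multi_locus_best_category_wins(ctx):
    # one hit in an exon, one in unannotated space: exon wins over unknown
    assert categorize("G" * 21, [hit(700, 721), hit(120, 141)], ctx) == "exon_sense"


def test_reference_order_does_not_matter():
    refs = {"b": "ACGTACGTACGTACGTACGTA", "a": "ACGTACGTACGTACGTACGTA"}
    ctx1 = AnnotationContext(mature_ref=refs, ncrna_ref={}, exons=[])
    ctx2 = AnnotationContext(
        mature_ref=dict(reversed(list(refs.items()))), ncrna_ref={}, exons=[]
    )
    tag = "ACGTACGTACGTACGTACGTA"
    h = [hit(0, 21)]
    assert categorize(tag, h, ctx1) == categorize(tag, h, ctx2)


def test_category_tallies_conserve_reads(small_tags):
    tags = small_tags["tags"]
    annot = small_tags["annotation"]
    dist = category_distribution(tags, annot)
    for lib, total in small_tags["totals"].items():
        mapped = dist.loc[dist.category != "unmapped", f"total_{lib}"].sum()
        unmapped = dist.loc[dist.category == "unmapped", f"total_{lib}"].sum()
        assert mapped + unmapped == total
    assert set(dist.category) <= {
        "known_miRNA", "ncRNA", "repeat", "exon_sense", "exon_antisense",
        "intron_sense", "intron_antisense", "unknown", "unmapped",
    }
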