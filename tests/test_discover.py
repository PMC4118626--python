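import numpy as np
import pytest

from saltmir.discover import (
    DiscoveryParams,
    MiRNARecord,
    call_conserved,
    call_novel,
    catalog_frame,
    family_summary,
)
from saltmir.io import to_dna, to_rna


def truth_by_class(data, cls):
    return {k: r for k, r in data.truth.items() if r.cls == cls}


def test_conserved_recovery_on_small_run(small_data, small_tags):
    records = call_conserved(
        small_tags["tags"],
        small_data.mature_ref,
        small_data.precursor_ref,
        genome=small_tags["index"],
    )
    called_matures = {r.mature_seq for r in records}
    planted = truth_by_class(small_data, "conserved")
    recovered = sum(
        1 for rec in planted.values() if to_rna(rec.mature_seq) in called_matures
    )
    assert recovered == len(planted)
    for r in records:
        assert r.cls == "conserved"
        assert r.family.startswith("miR")
        assert r.total_reads >= 5
        assert r.first_nt == r.mature_seq[0]
        assert to_dna(r.mature_seq) in to_dna(r.precursor_seq)


def test_conserved_star_detection(small_data, small_tags):
    records = call_conserved(
        small_tags["tags"], small_data.mature_ref, small_data.precursor_ref
    )
    planted = {to_rna(r.mature_seq): r for r in truth_by_class(small_data, "conserved").values()}
    starred = [r for r in records if r.star_seq]
    assert starred, "no star evidence found"
    for r in starred:
        rec = planted.get(r.mature_seq)
        if rec is not None:
            assert r.star_seq == to_rna(rec.star_seq)
            assert r.duplex is not None and r.duplex.overhang3 in (1, 2, 3)


def test_min_reads_threshold(small_data):
    mature = next(iter(small_data.mature_ref.values()))
    ref_id = next(iter(small_data.mature_ref))
    low = {to_dna(mature): {"3dSL": 4}}
    ok = {to_dna(mature): {"3dSL": 5}}
    kw = dict(
        mature_ref={ref_id: mature},
        precursor_ref={ref_id: small_data.precursor_ref[ref_id]},
    )
    assert call_conserved(low, **kw) == []
    called = call_conserved(ok, **kw)
    assert len(called) == 1 and called[0].id == ref_id


def test_missing_precursor_skipped_with_warning(small_data, caplog):
    mature = next(iter(small_data.mature_ref.values()))
    ref_id = next(iter(small_data.mature_ref))
    tags = {to_dna(mature): {"3dSL": 50}}
    with caplog.at_level("WARNING"):
        out = call_conserved(tags, {ref_id: mature}, {})
    assert out == []
    assert "precursor" in caplog.text


def test_novel_recovery_on_small_run(small_data, small_tags):
    annot = small_tags["annotation"]
    unknown = annot.loc[annot.category == "unknown", "sequence"].tolist()
    conserved = call_conserved(
        small_tags["tags"], small_data.mature_ref, small_data.precursor_ref,
        genome=small_tags["index"],
    )
    novel = call_novel(
        small_tags["tags"], unknown, small_data.genome,
        genome_index=small_tags["index"],
        conserved_loci=[r.locus for r in conserved if r.locus],
    )
    planted = truth_by_class(small_data, "novel")
    called_matures = {r.mature_seq for r in novel}
    assert all(to_rna(rec.mature_seq) in called_matures for rec in planted.values())
    # no false calls: every novel record sits on a planted novel locus
    for r in novel:
        assert any(
            r.locus.chrom == rec.chrom and r.locus.start < rec.end and rec.start < r.locus.end
            for rec in planted.values()
        )
        assert r.star_seq, "require_star default emits only star-supported records"
        assert r.id.startswith("peu-sM")


def test_novel_requires_star_by_default(small_data, small_tags):
    planted = next(iter(truth_by_class(small_data, "novel").values()))
    mature = to_dna(planted.mature_seq)
    tags = {mature: {"3dSL": 50}}  # no star tag present
    out = call_novel(tags, [mature], small_data.genome, genome_index=small_tags["index"])
    assert out == []
    relaxed = call_novel(
        tags, [mature], small_data.genome, genome_index=small_tags["index"],
        params=DiscoveryParams(require_star=False),
    )
    assert len(relaxed) == 1


def test_exon_tags_never_reach_novel_calling(small_data, small_tags):
    """Annotation precedence: candidates are drawn from 'unknown' tags only."""
    annot = small_tags["annotation"]
    unknown = set(annot.loc[annot.category == "unknown", "sequence"])
    exonic = set(annot.loc[annot.category.str.startswith("exon"), "sequence"])
    assert unknown.isdisjoint(exonic)
    novel = call_novel(
        small_tags["tags"], sorted(unknown), small_data.genome,
        genome_index=small_tags["index"],
    )
    for r in novel:
        for chrom, start, end, _strand, _tx in small_data.exons:
            assert not (r.locus.chrom == chrom and r.locus.start < end and start < r.locus.end)


def make_record(family, counts):
    return MiRNARecord(
        id=f"x-{family}", cls="conserved", family=family, mature_seq="A" * 21,
        precursor_seq="A" * 80, mfe=-30.0, counts=counts,
    )


def test_family_summary_single_family():
    df = family_summary([make_record("miR156", {"L": 10})])
    assert df.loc[0, "fraction_L"] == 1.0


def test_family_summary_equal_split():
    df = family_summary(
        [make_record("miR156", {"L": 50}), make_record("miR166", {"L": 50})]
    )
    assert list(df["fraction_L"]) == [0.5, 0.5]


def test_family_summary_planted_dominant_family():
    rng = np.random.default_rng(8)
    records = [
        make_record("miR156", {"L": int(rng.poisson(6000))}),
        make_record("miR166", {"L": int(rng.poisson(2000))}),
        make_record("miR167", {"L": int(rng.poisson(2000))}),
    ]
    df = family_summary(records)
    frac = df.loc[df.family == "miR156", "fraction_L"].iloc[0]
    assert frac == pytest.approx(0.6, abs=0.05)


def test_family_summary_fractions_sum_to_one(small_data, small_tags):
    records = call_conserved(
        small_tags["tags"], small_data.mature_ref, small_data.precursor_ref
    )
    df = family_summary(records)
    for lib in small_tags["totals"]:
        col = f"fraction_{lib}"
        if col in df:
            assert df[col].sum() == pytest.approx(1.0, abs=1e-9)


def test_family_summary_requires_conserved():
    with pytest.raises(ValueError):
        family_summary([])


def test_catalog_frame_roundtrippable(small_data, small_tags):
    records = call_conserved(
        small_tags["tags"], small_data.mature_ref, small_data.precursor_ref
    )
    df = catalog_frame(records)
    assert {"id", "class", "family", "mature_seq", "mfe"} <= set(df.columns)
    assert len(df) == len(records)
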