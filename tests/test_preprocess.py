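import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltmir.config import CleanParams, DEFAULT_ADAPTER3, DEFAULT_ADAPTER5
from saltmir.io import write_fastq
from saltmir.preprocess import (
    clean_reads,
    collapse_tags,
    common_specific_summary,
    summary_from_counts,
)

A3 = DEFAULT_ADAPTER3
A5 = DEFAULT_ADAPTER5
INSERT21 = "ACGTACGTACGTACGTACGTA"


def fastq(tmp_path, reads, name="in.fastq"):
    path = tmp_path / name
    write_fastq(path, [(f"r{i}", s, q) for i, (s, q) in enumerate(reads)])
    return path


def run(tmp_path, reads, **kw):
    return clean_reads(fastq(tmp_path, reads), A3, A5, CleanParams(**kw))


def test_insert_plus_adapter_retained(tmp_path):
    seq = INSERT21 + A3
    clean, stats = run(tmp_path, [(seq, "I" * len(seq))])
    assert clean == [INSERT21]
    assert stats.clean_reads == 1 and stats.length_histogram == {21: 1}


@pytest.mark.parametrize(
    "length,kept",
    [(17, False), (18, True), (30, True), (31, False)],
)
def test_length_boundaries_closed_interval(tmp_path, length, kept):
    insert = ("ACGT" * 10)[:length]
    seq = insert + A3
    clean, stats = run(tmp_path, [(seq, "I" * len(seq))])
    if kept:
        assert clean == [insert]
    else:
        assert clean == []
        assert stats.removed["length_out_of_range"] == 1


def test_polya_removed(tmp_path):
    seq = "A" * 20 + A3
    clean, stats = run(tmp_path, [(seq, "I" * len(seq))])
    assert clean == [] and stats.removed["polyA"] == 1


def test_low_quality_removed_before_other_filters(tmp_path):
    seq = "A" * 20 + A3  # would otherwise be polyA
    clean, stats = run(tmp_path, [(seq, "#" * len(seq))])
    assert stats.removed["low_quality"] == 1
    assert stats.removed["polyA"] == 0


def test_adapter5_contaminant(tmp_path):
    seq = A5 + INSERT21 + A3
    _, stats = run(tmp_path, [(seq, "I" * len(seq))])
    assert stats.removed["adapter5_contaminant"] == 1


def test_adapter_null_and_insert_null(tmp_path):
    no_adapter = "ACGTACGTACGTACGTACGTACGTA"
    adapter_only = A3 + "ACGTA"
    _, stats = run(
        tmp_path,
        [(no_adapter, "I" * len(no_adapter)), (adapter_only, "I" * len(adapter_only))],
    )
    assert stats.removed["adapter_null"] == 1
    assert stats.removed["insert_null"] == 1


def test_empty_file(tmp_path):
    clean, stats = run(tmp_path, [])
    assert clean == [] and stats.raw_reads == 0 and stats.clean_reads == 0


def test_malformed_record_raises(tmp_path):
    path = tmp_path / "bad.fastq"
    path.write_text("@r0\nACGT\n+\nIII\n")  # quality shorter than sequence
    with pytest.raises(ValueError):
        clean_reads(path, A3, A5)


def test_empty_adapter_rejected(tmp_path):
    with pytest.raises(ValueError):
        clean_reads(fastq(tmp_path, []), "", A5)


def test_conservation_invariant(tmp_path, small_libs):
    libs, _ = small_libs
    reads = [(s, q) for _t, s, q in libs["3dSL"][:2000]]
    _, stats = run(tmp_path, reads)
    assert stats.raw_reads == stats.clean_reads + sum(stats.removed.values())
    assert sum(stats.length_histogram.values()) == stats.clean_reads
    assert all(18 <= l <= 30 for l in stats.length_histogram)


def test_idempotent_on_clean_inserts(tmp_path):
    inserts = [INSERT21, "GGGTTTCCCAAAGGGTTTCC"]
    reads = [(s, "I" * len(s)) for s in inserts]
    clean, stats = run(tmp_path, reads, trim_adapter=False)
    assert clean == inserts
    assert stats.clean_reads == len(inserts)


# ---------------------------------------------------------------------------
# collapsing


def test_collapse_counts():
    tags = collapse_tags({"L1": ["S1TAGTAGTAGTAGTAGT", "S1TAGTAGTAGTAGTAGT", "S2AGTAGTAGTAGTAGTA"]})
    assert tags["S1TAGTAGTAGTAGTAGT"] == {"L1": 2}
    assert tags["S2AGTAGTAGTAGTAGTA"] == {"L1": 1}


def test_collapse_shared_tag_across_libraries():
    tags = collapse_tags({"L1": ["AAA"], "L2": ["AAA", "CCC"]})
    assert tags["AAA"] == {"L1": 1, "L2": 1}
    assert "L1" not in tags["CCC"]


def test_collapse_empty_library():
    tags = collapse_tags({"L1": ["AAA"], "L2": []})
    assert all("L2" not in c for c in tags.values())


def test_collapse_totals_match_clean_reads(small_libs, small_tags):
    tags, totals = small_tags["tags"], small_tags["totals"]
    for lib, total in totals.items():
        assert sum(c.get(lib, 0) for c in tags.values()) == total


# ---------------------------------------------------------------------------
# common/specific summary


def test_printed_leaf_percentages():
    table = summary_from_counts(
        "3dSL", "3dCKL",
        unique_common=536_735, unique_a_only=1_754_216, unique_b_only=1_632_212,
        total_common=27_911_344, total_a_only=2_092_797, total_b_only=2_006_437,
    )
    assert table.loc[0, "unique_srna"] == 3_923_163
    assert table.loc[0, "total_srna"] == 32_010_578
    assert table.loc[1, "unique_pct"] == 13.68
    assert table.loc[1, "total_pct"] == 87.19
    assert table.loc[2, "unique_pct"] == 44.71
    assert table.loc[2, "total_pct"] == 6.54
    assert table.loc[3, "unique_pct"] == 41.60
    assert table.loc[3, "total_pct"] == 6.27


def test_printed_root_percentages():
    table = summary_from_counts(
        "3dCKR", "3dSR",
        unique_common=850_624, unique_a_only=2_903_793, unique_b_only=3_107_476,
        total_common=25_568_498, total_a_only=3_534_735, total_b_only=3_796_980,
    )
    assert table.loc[1, "unique_pct"] == 12.40
    assert table.loc[1, "total_pct"] == 77.72
    assert table.loc[2, "unique_pct"] == 42.32
    assert table.loc[2, "total_pct"] == 10.74
    assert table.loc[3, "unique_pct"] == 45.29
    assert table.loc[3, "total_pct"] == 11.54


def test_identical_libraries_fully_common():
    tags = collapse_tags({"A": ["S1", "S2"], "B": ["S1", "S2", "S2"]})
    table = common_specific_summary(tags, "A", "B")
    assert table.loc[1, "unique_pct"] == 100.00
    assert table.loc[2, "unique_srna"] == 0 and table.loc[3, "unique_srna"] == 0


def test_unknown_library_raises():
    tags = collapse_tags({"A": ["S1"]})
    with pytest.raises(KeyError):
        common_specific_summary(tags, "A", "Z")


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.sampled_from(["s1", "s2", "s3", "s4", "s5"]), max_size=30),
    st.lists(st.sampled_from(["s1", "s2", "s3", "s4", "s5"]), max_size=30),
)
def test_summary_rows_sum_to_total(seq_a, seq_b):
    tags = collapse_tags({"A": seq_a, "B": seq_b})
    if not (any("A" in c for c in tags.values()) and any("B" in c for c in tags.values())):
        return
    t = common_specific_summary(tags, "A", "B")
    assert t.loc[1:, "unique_srna"].sum() == t.loc[0, "unique_srna"]
    assert t.loc[1:, "total_srna"].sum() == t.loc[0, "total_srna"]
    assert t.loc[0, "total_srna"] == len(seq_a) + len(seq_b)
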