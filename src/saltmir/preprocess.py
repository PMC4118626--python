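"""Raw FASTQ -> clean inserts -> collapsed unique tags with per-library counts.

Filter categories are mutually exclusive and applied in a fixed order:
low_quality -> adapter5_contaminant -> adapter_null -> insert_null -> polyA
-> length_out_of_range.  A read survives only if it passes every filter; the
surviving insert is the read prefix upstream of the 3' adapter match.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .config import CleanParams
from .io import iter_fastq

__all__ = [
    "CleanStats",
    "clean_reads",
    "collapse_tags",
    "common_specific_summary",
    "summary_from_counts",
]

REMOVAL_CATEGORIES = (
    "low_quality",
    "adapter5_contaminant",
    "adapter_null",
    "insert_null",
    "polyA",
    "length_out_of_range",
)


@dataclass
class CleanStats:
    raw_reads: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in REMOVAL_CATEGORIES}
    )
    clean_reads: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def check(self) -> None:
        assert self.raw_reads == self.clean_reads + sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("raw_reads", self.raw_reads)]
        rows += [(f"removed_{c}", n) for c, n in self.removed.items()]
        rows.append(("clean_reads", self.clean_reads))
        rows += [(f"len_{l}", n) for l, n in sorted(self.length_histogram.items())]
        return pd.DataFrame(rows, columns=["metric", "count"])


def _mean_quality(qual: str) -> float:
    return sum(map(ord, qual)) / len(qual) - 33.0


def _is_polya(seq: str, frac: float, run: int) -> bool:
    if seq.count("A") >= frac * len(seq):
        return True
    return "A" * run in seq


def clean_reads(
    fastq_path,
    adapter3: str,
    adapter5: str,
    params: CleanParams | None = None,
) -> tuple[list[str], CleanStats]:
    """Clean one FASTQ library; returns surviving insert sequences and stats.

    The 3' adapter is located by exact match of its first ``adapter_k`` nt;
    the insert is everything upstream of the match.  Reads whose first
    ``adapter_k`` nt equal the 5' adapter prefix are 5' adapter contaminants.
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    p = params or CleanParams()
    a3 = adapter3.upper()[: p.adapter_k]
    a5 = adapter5.upper()[: p.adapter_k]
    stats = CleanStats()
    clean: list[str] = []
    for idx, (title, seq, qual) in enumerate(iter_fastq(fastq_path)):
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record at index {idx}: {title}")
        stats.raw_reads += 1
        seq = seq.upper().replace("U", "T")
        if _mean_quality(qual) < p.min_mean_quality or seq.count("N") > p.max_n_bases:
            stats.removed["low_quality"] += 1
            continue
        if seq.startswith(a5):
            stats.removed["adapter5_contaminant"] += 1
            continue
        if p.trim_adapter:
            pos = seq.find(a3)
            if pos < 0:
                stats.removed["adapter_null"] += 1
                continue
            insert = seq[:pos]
        else:
            insert = seq
        if not insert:
            stats.removed["insert_null"] += 1
            continue
        if _is_polya(insert, p.polya_fraction, p.polya_run):
            stats.removed["polyA"] += 1
            continue
        if not (p.min_len <= len(insert) <= p.max_len):
            stats.removed["length_out_of_range"] += 1
            continue
        stats.clean_reads += 1
        stats.length_histogram[len(insert)] = (
            stats.length_histogram.get(len(insert), 0) + 1
        )
        clean.append(insert)
    stats.check()
    return clean, stats


def collapse_tags(clean_by_library: Mapping[str, Iterable[str]]) -> dict[str, dict[str, int]]:
    """Collapse cleaned sequences into unique tags keyed by exact sequence.

    Returns {sequence: {library_id: count}}; only libraries with count >= 1
    appear in a tag's count map.
    """
    tags: dict[str, dict[str, int]] = {}
    for lib, seqs in clean_by_library.items():
        for seq, n in Counter(seqs).items():
            tags.setdefault(seq, {})[lib] = n
    return tags


def _pct(part: int, whole: int) -> float:
    return round(part / whole * 100.0, 2) if whole else 0.0


def summary_from_counts(
    lib_a: str,
    lib_b: str,
    unique_common: int,
    unique_a_only: int,
    unique_b_only: int,
    total_common: int,
    total_a_only: int,
    total_b_only: int,
) -> pd.DataFrame:
    """Common/specific summary table from pre-tallied unique/total counts.

    Percentages are of the column total, rounded to 2 decimals.
    """
    uniq_total = unique_common + unique_a_only + unique_b_only
    tot_total = total_common + total_a_only + total_b_only
    rows = [
        ("total", uniq_total, tot_total),
        (f"{lib_a} & {lib_b}", unique_common, total_common),
        (f"{lib_a}-specific", unique_a_only, total_a_only),
        (f"{lib_b}-specific", unique_b_only, total_b_only),
    ]
    return pd.DataFrame(
        [
            {
                "class": name,
                "unique_srna": u,
                "unique_pct": _pct(u, uniq_total),
                "total_srna": t,
                "total_pct": _pct(t, tot_total),
            }
            for name, u, t in rows
        ]
    )


def common_specific_summary(
    tags: Mapping[str, Mapping[str, int]], lib_a: str, lib_b: str
) -> pd.DataFrame:
    """Tables-1/2-style summary of sequences shared between two libraries."""
    seen = {lib for counts in tags.values() for lib in counts}
    for lib in (lib_a, lib_b):
        if lib not in seen:
            raise KeyError(f"library {lib!r} not present in tags")
    uc = ua = ub = tc = ta = tb = 0
    for counts in tags.values():
        a, b = counts.get(lib_a, 0), counts.get(lib_b, 0)
        if a and b:
            uc += 1
            tc += a + b
        elif a:
            ua += 1
            ta += a
        elif b:
            ub += 1
            tb += b
    return summary_from_counts(lib_a, lib_b, uc, ua, ub, tc, ta, tb)


def tags_to_frame(tags: Mapping[str, Mapping[str, int]], libraries=None) -> pd.DataFrame:
    libs = list(libraries) if libraries else sorted(
        {lib for counts in tags.values() for lib in counts}
    )
    rows = [
        {"sequence": seq, **{lib: counts.get(lib, 0) for lib in libs}}
        for seq, counts in sorted(tags.items())
    ]
    return pd.DataFrame(rows, columns=["sequence", *libs])
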