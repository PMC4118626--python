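"""Plant-style miRNA target prediction by mismatch-limited complementarity.

The duplex is gapless: the miRNA (5'->3') is aligned against the target site
read 3'->5', i.e. miRNA position i faces transcript position
``site_end - 1 - i``.  Penalties follow the classic plant scoring lineage:
mismatch 1.0, G:U wobble 0.5, doubled at miRNA positions 2-13, and a full
mismatch at the cleavage-site positions 10-11 rejects the site outright
unless explicitly allowed.  A site is reported when its total penalty is
<= ``max_score`` (default 4.0).
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

import pandas as pd

from .io import to_rna

__all__ = ["TargetSite", "duplex_score", "predict_targets", "annotate_targets", "target_summary"]

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

SEED_START, SEED_END = 2, 13      # 1-based miRNA positions with doubled weight
CLEAVAGE_POSITIONS = (10, 11)


class TargetSite(NamedTuple):
    mirna_id: str
    transcript_id: str
    site_start: int   # 0-based on transcript sense strand
    site_end: int     # exclusive
    mismatches: int
    gu_wobbles: int
    score: float


def duplex_score(
    mirna: str,
    site: str,
    strict_hamming: bool = False,
    allow_cleavage_mm: bool = False,
) -> tuple[float, int, int]:
    """Penalty score, mismatch count, and wobble count for one duplex.

    Returns ``(inf, mm, gu)`` when a cleavage-site mismatch rejects the
    site.  ``strict_hamming`` counts G:U wobbles as full mismatches.
    """
    m = to_rna(mirna)
    s = to_rna(site)
    if len(m) != len(s):
        raise ValueError("site length must equal miRNA length")
    score = 0.0
    mm = gu = 0
    rejected = False
    for i, base in enumerate(m):
        tbase = s[len(s) - 1 - i]
        pos = i + 1
        if (base, tbase) in _PAIRS:
            continue
        if (base, tbase) in _WOBBLE and not strict_hamming:
            gu += 1
            penalty = 0.5
        else:
            mm += 1
            penalty = 1.0
            if pos in CLEAVAGE_POSITIONS and not allow_cleavage_mm:
                rejected = True
        if SEED_START <= pos <= SEED_END:
            penalty *= 2.0
        score += penalty
    if rejected:
        return float("inf"), mm, gu
    return score, mm, gu


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    max_score: float = 4.0,
    strict_hamming: bool = False,
    allow_cleavage_mm: bool = False,
) -> list[TargetSite]:
    """All qualifying binding sites of each miRNA on each transcript.

    Transcripts shorter than the miRNA are skipped.  Sites are sorted by
    score, then miRNA id, transcript id and coordinate.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    sites: list[TargetSite] = []
    for mid in sorted(mirnas):
        m = to_rna(mirnas[mid])
        L = len(m)
        for tid in sorted(transcripts):
            t = to_rna(transcripts[tid])
            if len(t) < L:
                continue
            for off in range(len(t) - L + 1):
                score, mm, gu = duplex_score(
                    m, t[off : off + L], strict_hamming, allow_cleavage_mm
                )
                if score <= max_score:
                    sites.append(TargetSite(mid, tid, off, off + L, mm, gu, score))
    sites.sort(key=lambda s: (s.score, s.mirna_id, s.transcript_id, s.site_start))
    return sites


def target_summary(sites: list[TargetSite]) -> pd.DataFrame:
    """Distinct-transcript target counts per miRNA."""
    df = pd.DataFrame(sites, columns=TargetSite._fields)
    if df.empty:
        return pd.DataFrame(columns=["mirna_id", "n_targets", "n_sites"])
    g = df.groupby("mirna_id")
    out = pd.DataFrame(
        {
            "n_targets": g["transcript_id"].nunique(),
            "n_sites": g.size(),
        }
    ).reset_index()
    return out


def annotate_targets(sites: list[TargetSite], annotation_path) -> pd.DataFrame:
    """Left-join user-supplied functional labels onto predicted sites.

    The annotation TSV maps transcript_id -> terms; duplicate rows are
    concatenated with ';' after de-duplication.  Unannotated transcripts
    keep empty labels.
    """
    labels: dict[str, list[str]] = {}
    with open(annotation_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed annotation TSV at line {lineno}")
            tid, term = parts[0], parts[1]
            bucket = labels.setdefault(tid, [])
            if term not in bucket:
                bucket.append(term)
    df = pd.DataFrame(sites, columns=TargetSite._fields)
    df["labels"] = [";".join(labels.get(t, [])) for t in df["transcript_id"]] if len(df) else []
    return df
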