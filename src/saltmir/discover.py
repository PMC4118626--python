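"""Conserved (reference-guided) and novel (genome-guided) miRNA calling.

Conserved calls require a mature-reference match within a mismatch budget,
a minimum total read count, and a qualifying hairpin precursor.  Novel calls
excise candidate precursor windows around unannotated genome-mapped tags,
fold them, walk the stem containing the candidate to its outermost enclosing
pair, refold the excised stem, and demand a single-stem hairpin plus
(optionally) a star-supporting tag on the opposite arm with a 1-3 nt 3'
overhang (2 nt canonical).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import GenomeHit, GenomeIndex, ReferenceMatcher
from .fold import HairpinFold, fold, is_hairpin, pair_table
from .io import revcomp, to_dna, to_rna

log = logging.getLogger(__name__)

__all__ = [
    "MiRNARecord",
    "DuplexCheck",
    "DiscoveryParams",
    "call_conserved",
    "call_novel",
    "family_summary",
    "catalog_frame",
]


@dataclass
class DiscoveryParams:
    min_reads: int = 5
    max_mm: int = 2
    min_stem_pairs: int = 16
    mfe_max: float = -18.0
    flanks: tuple[int, ...] = (30, 60, 100, 150)
    max_unpaired_mature: int = 5
    require_star: bool = True
    overhangs: tuple[int, ...] = (2, 1, 3)  # canonical first
    max_hits_per_tag: int = 4


@dataclass
class DuplexCheck:
    mature_range: tuple[int, int]
    star_range: tuple[int, int]
    paired_fraction: float
    duplex_mismatches: int
    overhang3: int


@dataclass
class MiRNARecord:
    id: str
    cls: str                       # conserved | novel
    mature_seq: str                # RNA space
    precursor_seq: str             # RNA space
    mfe: float
    counts: dict[str, int]
    family: str = ""
    star_seq: str = ""
    locus: GenomeHit | None = None
    arm: str = ""
    first_nt: str = ""
    structure: str = ""
    duplex: DuplexCheck | None = None
    support_tags: list[str] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def _family_from_ref(ref_id: str) -> str:
    m = re.search(r"(miR[0-9]+)", ref_id, flags=re.IGNORECASE)
    return m.group(1) if m else ref_id


def _projected_partner(pt: np.ndarray, pos: int, lo: int, hi: int) -> int | None:
    """Partner of ``pos`` projected through the nearest paired neighbour.

    In an antiparallel stem the partner index decreases by one for every
    step forward, so an unpaired position can borrow its neighbour's partner
    with an offset correction.
    """
    for d in range(hi - lo):
        for cand in (pos - d, pos + d):
            if lo <= cand < hi and pt[cand] >= 0:
                return int(pt[cand]) + (cand - pos)
    return None


def _duplex_geometry(
    hp: HairpinFold, mature: tuple[int, int], overhang: int
) -> tuple[tuple[int, int], DuplexCheck] | None:
    """Star coordinates for a mature arm under a given 3' overhang."""
    a, b = mature
    pt = pair_table(hp.structure)
    p_hi = _projected_partner(pt, a, a, b)
    p_lo = _projected_partner(pt, b - 1 - overhang, a, b)
    if p_hi is None or p_lo is None:
        return None
    s0, s1 = p_lo, p_hi + overhang + 1
    if not (0 <= s0 < s1 <= len(hp.sequence)):
        return None
    if s0 < b and s1 > a:  # arms must be disjoint
        return None
    paired = sum(1 for i in range(a, b) if pt[i] >= 0)
    check = DuplexCheck(
        mature_range=(a, b),
        star_range=(s0, s1),
        paired_fraction=paired / (b - a),
        duplex_mismatches=(b - a) - paired,
        overhang3=overhang,
    )
    return (s0, s1), check


def _find_star(
    hp: HairpinFold,
    mature: tuple[int, int],
    tag_counts: Mapping[str, Mapping[str, int]],
    params: DiscoveryParams,
):
    """Look for a sequenced tag occupying the opposite arm of the duplex."""
    pre_dna = to_dna(hp.sequence)
    for overhang in params.overhangs:
        geom = _duplex_geometry(hp, mature, overhang)
        if geom is None:
            continue
        (s0, s1), check = geom
        star = pre_dna[s0:s1]
        if star in tag_counts:
            return star, check
    return None, None


def _arm_of(hp: HairpinFold, mature: tuple[int, int], arms) -> str:
    if arms is None:
        return ""
    mid = (mature[0] + mature[1]) // 2
    lo, hi = arms["5p"]
    return "5p" if lo <= mid < hi else "3p"


def _locate_in(precursor: str, tag: str, max_mm: int) -> tuple[int, int] | None:
    """Best gapless placement of the tag inside the precursor."""
    pre, t = to_dna(precursor), to_dna(tag)
    best, pos = max_mm + 1, None
    for off in range(len(pre) - len(t) + 1):
        d = sum(x != y for x, y in zip(t, pre[off : off + len(t)]))
        if d < best:
            best, pos = d, off
    if pos is None:
        return None
    return pos, pos + len(t)


def call_conserved(
    tags: Mapping[str, Mapping[str, int]],
    mature_ref: Mapping[str, str],
    precursor_ref: Mapping[str, str],
    genome: GenomeIndex | None = None,
    params: DiscoveryParams | None = None,
) -> list[MiRNARecord]:
    """Reference-guided conserved miRNA calls.

    Each tag is counted toward at most one reference (its best hit); a
    record is emitted per reference with total support >= ``min_reads``
    whose precursor folds into a qualifying hairpin.
    """
    p = params or DiscoveryParams()
    matcher = ReferenceMatcher(mature_ref, p.max_mm)
    assigned: dict[str, list[str]] = {}
    for seq in sorted(tags):
        hits = matcher.find(seq)
        if hits:
            assigned.setdefault(hits[0].ref_id, []).append(seq)

    records: list[MiRNARecord] = []
    for ref_id in sorted(assigned):
        support = assigned[ref_id]
        counts: dict[str, int] = {}
        for seq in support:
            for lib, n in tags[seq].items():
                counts[lib] = counts.get(lib, 0) + n
        if sum(counts.values()) < p.min_reads:
            continue
        precursor = precursor_ref.get(ref_id)
        if precursor is None:
            log.warning("no precursor for matched mature %s; record skipped", ref_id)
            continue
        hp = fold(to_rna(precursor))
        ok, arms = is_hairpin(hp, p.min_stem_pairs, p.mfe_max)
        if not ok:
            continue
        mature = max(support, key=lambda s: sum(tags[s].values()))
        loc = _locate_in(precursor, mature, p.max_mm)
        if loc is None:
            continue
        star, duplex = _find_star(hp, loc, tags, p)
        locus = None
        if genome is not None:
            ghits = genome.find(mature)
            locus = ghits[0] if ghits else None
        records.append(
            MiRNARecord(
                id=ref_id,
                cls="conserved",
                family=_family_from_ref(ref_id),
                mature_seq=to_rna(mature),
                star_seq=to_rna(star) if star else "",
                precursor_seq=hp.sequence,
                mfe=hp.mfe,
                counts=counts,
                locus=locus,
                arm=_arm_of(hp, loc, arms),
                first_nt=to_rna(mature)[0],
                structure=hp.structure,
                duplex=duplex,
                support_tags=support,
            )
        )
    records.sort(key=lambda r: r.id)
    return records


def _enclosing_stem(pt: np.ndarray, a: int, b: int) -> tuple[int, int] | None:
    """Outermost pair of the stem containing positions [a, b)."""
    start = None
    for i in range(a, b):
        if pt[i] >= 0:
            start = i
            break
    if start is None:
        return None
    i, j = (start, int(pt[start])) if pt[start] > start else (int(pt[start]), start)
    while True:
        nxt = None
        for k in range(i - 1, -1, -1):
            if pt[k] > j:
                nxt = (k, int(pt[k]))
                break
            if pt[k] >= 0:
                break  # sibling stem: extending further would close a multiloop
        if nxt is None:
            return i, j
        # the enclosing pair must close a bulge/internal loop, not a multiloop
        if any(pt[m] >= 0 for m in range(j + 1, nxt[1])):
            return i, j
        i, j = nxt


def call_novel(
    tags: Mapping[str, Mapping[str, int]],
    candidates: Sequence[str],
    genome: Mapping[str, str],
    genome_index: GenomeIndex | None = None,
    params: DiscoveryParams | None = None,
    conserved_loci: Sequence[GenomeHit] = (),
) -> list[MiRNARecord]:
    """Genome-guided novel miRNA calls from unannotated mapped tags.

    ``candidates`` are tag sequences already categorized ``unknown``.  For
    each genomic hit, precursor windows of (flank, tag, flank) are excised
    for every configured flank; the best window passing the hairpin and
    duplex criteria (minimum MFE) wins.  Loci sharing a precursor interval
    are deduplicated keeping the most abundant mature; loci overlapping a
    conserved precursor are dropped.
    """
    p = params or DiscoveryParams()
    index = genome_index or GenomeIndex(genome)
    raw: list[MiRNARecord] = []
    for seq in sorted(candidates, key=lambda s: (-sum(tags[s].values()), s)):
        total = sum(tags[seq].values())
        if total < p.min_reads:
            continue
        best: MiRNARecord | None = None
        for hit in index.find(seq)[: p.max_hits_per_tag]:
            chrom_seq = genome[hit.chrom]
            for flank in p.flanks:
                ws = max(0, hit.start - flank)
                we = min(len(chrom_seq), hit.end + flank)
                if we - ws < len(seq) + 20:
                    log.info("window at %s:%d truncated by contig edge", hit.chrom, ws)
                window = chrom_seq[ws:we]
                if hit.strand == "-":
                    window = revcomp(window)
                    a = we - hit.end
                else:
                    a = hit.start - ws
                b = a + len(seq)
                whp = fold(to_rna(window))
                pt = pair_table(whp.structure)
                stem = _enclosing_stem(pt, a, b)
                if stem is None:
                    continue
                i0, j0 = stem
                if not (i0 <= a and b <= j0 + 1):
                    continue
                pre = window[i0 : j0 + 1]
                if len(pre) < 15:
                    continue
                hp = fold(to_rna(pre))
                ok, arms = is_hairpin(hp, p.min_stem_pairs, p.mfe_max)
                if not ok:
                    continue
                ma, mb = a - i0, b - i0
                ppt = pair_table(hp.structure)
                unpaired = sum(1 for k in range(ma, mb) if ppt[k] < 0)
                if unpaired > p.max_unpaired_mature:
                    continue
                star, duplex = _find_star(hp, (ma, mb), tags, p)
                if p.require_star and star is None:
                    continue
                if hit.strand == "+":
                    locus = GenomeHit(hit.chrom, ws + i0, ws + j0 + 1, "+")
                else:
                    locus = GenomeHit(hit.chrom, we - (j0 + 1), we - i0, "-")
                rec = MiRNARecord(
                    id="",
                    cls="novel",
                    mature_seq=to_rna(seq),
                    star_seq=to_rna(star) if star else "",
                    precursor_seq=hp.sequence,
                    mfe=hp.mfe,
                    counts=dict(tags[seq]),
                    locus=locus,
                    arm=_arm_of(hp, (ma, mb), arms),
                    first_nt=to_rna(seq)[0],
                    structure=hp.structure,
                    duplex=duplex,
                    support_tags=[seq],
                )
                if best is None or rec.mfe < best.mfe:
                    best = rec
        if best is not None:
            raw.append(best)

    def overlaps(l1: GenomeHit, l2: GenomeHit) -> bool:
        return l1.chrom == l2.chrom and l1.start < l2.end and l2.start < l1.end

    kept: list[MiRNARecord] = []
    for rec in raw:  # raw is sorted by descending abundance
        if any(overlaps(rec.locus, c) for c in conserved_loci):
            continue
        if any(overlaps(rec.locus, k.locus) for k in kept):
            continue
        kept.append(rec)
    kept.sort(key=lambda r: (r.locus.chrom, r.locus.start))
    for i, rec in enumerate(kept, 1):
        rec.id = f"peu-sM{i}"
    return kept


def family_summary(
    records: Sequence[MiRNARecord], libraries: Sequence[str] | None = None
) -> pd.DataFrame:
    """Family x library read fractions over conserved records."""
    conserved = [r for r in records if r.cls == "conserved"]
    if not conserved:
        raise ValueError("no conserved records")
    libs = list(libraries) if libraries else sorted(
        {lib for r in conserved for lib in r.counts}
    )
    fam_counts: dict[str, dict[str, int]] = {}
    for r in conserved:
        row = fam_counts.setdefault(r.family, {lib: 0 for lib in libs})
        for lib, n in r.counts.items():
            if lib in row:
                row[lib] += n
    totals = {lib: sum(row[lib] for row in fam_counts.values()) for lib in libs}
    rows = []
    for fam in sorted(fam_counts):
        entry = {"family": fam}
        for lib in libs:
            entry[f"reads_{lib}"] = fam_counts[fam][lib]
            entry[f"fraction_{lib}"] = (
                fam_counts[fam][lib] / totals[lib] if totals[lib] else 0.0
            )
        rows.append(entry)
    return pd.DataFrame(rows)


def catalog_frame(records: Sequence[MiRNARecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "class": r.cls,
                "family": r.family,
                "mature_seq": r.mature_seq,
                "star_seq": r.star_seq,
                "precursor_seq": r.precursor_seq,
                "locus": (
                    f"{r.locus.chrom}:{r.locus.start}-{r.locus.end}({r.locus.strand})"
                    if r.locus
                    else ""
                ),
                "arm": r.arm,
                "mfe": round(r.mfe, 2),
                "first_nt": r.first_nt,
                "star_found": bool(r.star_seq),
                **{f"count_{lib}": n for lib, n in sorted(r.counts.items())},
            }
        )
    return pd.DataFrame(rows)
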