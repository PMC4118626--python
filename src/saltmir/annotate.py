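"""Perfect-match genome mapping and hierarchical tag annotation.

Each mapped tag receives exactly one category by winner-takes-all priority:
known_miRNA > ncRNA > repeat > exon_sense > exon_antisense > intron_sense >
intron_antisense > unknown.  Unmapped tags are flagged ``unmapped`` and are
excluded from downstream discovery.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .io import revcomp, to_dna

__all__ = [
    "GenomeHit",
    "GenomeIndex",
    "RefHit",
    "map_perfect",
    "match_with_mismatches",
    "ReferenceMatcher",
    "AnnotationContext",
    "annotate_tags",
    "category_distribution",
    "CATEGORY_PRIORITY",
]

CATEGORY_PRIORITY = (
    "known_miRNA",
    "ncRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unknown",
)


class GenomeHit(NamedTuple):
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    strand: str


class RefHit(NamedTuple):
    ref_id: str
    offset: int
    distance: int


class GenomeIndex:
    """Seed-and-verify exact matcher over a genome (both strands)."""

    def __init__(self, genome: Mapping[str, str], k: int = 18):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in sorted(self.genome.items()):
            for i in range(len(seq) - k + 1):
                self._seeds[seq[i : i + k]].append((chrom, i))

    def find(self, tag: str) -> list[GenomeHit]:
        tag = to_dna(tag)
        if len(tag) < self.k:
            raise ValueError(f"tag shorter than index k={self.k}")
        hits = []
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            for chrom, i in self._seeds.get(query[: self.k], ()):
                if self.genome[chrom][i : i + len(query)] == query:
                    hits.append(GenomeHit(chrom, i, i + len(query), strand))
        hits.sort()
        return hits


def map_perfect(
    tags: Iterable[str], genome: Mapping[str, str] | GenomeIndex
) -> dict[str, list[GenomeHit]]:
    """All zero-mismatch occurrences of each tag on both genome strands."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    return {tag: index.find(tag) for tag in tags}


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_with_mismatches(
    tag: str, references: Mapping[str, str], max_mm: int
) -> list[RefHit]:
    """Gapless best-offset matches of a tag against reference sequences.

    The tag slides along each reference with full overlap; a hit is reported
    for every reference whose minimum Hamming distance over offsets is
    <= ``max_mm``.  Hits are sorted by distance then reference id.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    tag = to_dna(tag)
    hits = []
    for ref_id in sorted(references):
        ref = to_dna(references[ref_id])
        if len(tag) > len(ref):
            continue
        best, best_off = max_mm + 1, -1
        for off in range(len(ref) - len(tag) + 1):
            d = _hamming(tag, ref[off : off + len(tag)])
            if d < best:
                best, best_off = d, off
        if best <= max_mm:
            hits.append(RefHit(ref_id, best_off, best))
    hits.sort(key=lambda h: (h.distance, h.ref_id))
    return hits


class ReferenceMatcher:
    """Pigeonhole-seeded equivalent of :func:`match_with_mismatches`.

    For max_mm mismatches, a matching window must share at least one of
    ``max_mm + 1`` exact pieces of the tag; candidate (reference, offset)
    windows found through a piece index are then verified by full Hamming
    comparison, so results equal the brute-force scan.
    """

    def __init__(self, references: Mapping[str, str], max_mm: int = 2):
        self.references = {r: to_dna(s) for r, s in references.items()}
        self.max_mm = max_mm
        self._windows: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for_length(self, length: int):
        if length in self._windows:
            return self._windows[length]
        npieces = self.max_mm + 1
        bounds = [round(i * length / npieces) for i in range(npieces + 1)]
        idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for ref_id in sorted(self.references):
            ref = self.references[ref_id]
            for off in range(len(ref) - length + 1):
                win = ref[off : off + length]
                for b in range(npieces):
                    idx[f"{b}:{win[bounds[b]:bounds[b+1]]}"].append((ref_id, off))
        self._windows[length] = (idx, bounds)
        return self._windows[length]

    def find(self, tag: str) -> list[RefHit]:
        tag = to_dna(tag)
        idx, bounds = self._index_for_length(len(tag))
        npieces = self.max_mm + 1
        best: dict[str, tuple[int, int]] = {}
        seen: set[tuple[str, int]] = set()
        for b in range(npieces):
            key = f"{b}:{tag[bounds[b]:bounds[b+1]]}"
            for ref_id, off in idx.get(key, ()):
                if (ref_id, off) in seen:
                    continue
                seen.add((ref_id, off))
                ref = self.references[ref_id]
                d = _hamming(tag, ref[off : off + len(tag)])
                if d <= self.max_mm:
                    cur = best.get(ref_id)
                    if cur is None or (d, off) < cur:
                        best[ref_id] = (d, off)
        hits = [RefHit(r, off, d) for r, (d, off) in best.items()]
        hits.sort(key=lambda h: (h.distance, h.ref_id))
        return hits


def _derive_introns(exons: Sequence[tuple[str, int, int, str, str]]):
    """Intron intervals from gaps between exons of the same transcript."""
    by_tx: dict[str, list[tuple[str, int, int, str]]] = defaultdict(list)
    for chrom, start, end, strand, tx in exons:
        by_tx[tx].append((chrom, start, end, strand))
    introns = []
    for tx, exs in sorted(by_tx.items()):
        exs.sort(key=lambda e: e[1])
        for (c1, _, e1, s1), (_, s2, _, _) in zip(exs, exs[1:]):
            if s2 > e1:
                introns.append((c1, e1, s2, s1, tx))
    return introns


@dataclass
class AnnotationContext:
    """Reference material needed to categorize a mapped tag."""

    mature_ref: Mapping[str, str]
    ncrna_ref: Mapping[str, str]
    exons: Sequence[tuple[str, int, int, str, str]]       # chrom,start,end,strand,tx
    repeats: Sequence[tuple[str, int, int]] = ()          # chrom,start,end (BED)
    max_mm: int = 2

    def __post_init__(self):
        self.introns = _derive_introns(self.exons)
        self._mirna_matcher = ReferenceMatcher(self.mature_ref, self.max_mm)

    def mirna_hits(self, tag: str) -> list[RefHit]:
        return self._mirna_matcher.find(tag)

    def is_ncrna(self, tag: str) -> bool:
        # both orientations: rRNA/tRNA-derived fragments are binned into the
        # ncRNA class regardless of strand
        tag = to_dna(tag)
        rc = revcomp(tag)
        return any(
            tag in ref or rc in ref
            for ref in (to_dna(s) for s in self.ncrna_ref.values())
        )

    @staticmethod
    def from_gff(gff_path, **kw) -> "AnnotationContext":
        exons = []
        with open(gff_path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if f[2] != "exon":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                tx = attrs.get("Parent", attrs.get("ID", "tx"))
                # GFF3 is 1-based inclusive
                exons.append((f[0], int(f[3]) - 1, int(f[4]), f[6], tx))
        return AnnotationContext(exons=exons, **kw)


def _overlaps(hit: GenomeHit, feats, stranded: str | None = None) -> bool:
    for feat in feats:
        chrom, start, end = feat[0], feat[1], feat[2]
        if chrom != hit.chrom or hit.start >= end or hit.end <= start:
            continue
        if stranded is None:
            return True
        strand = feat[3]
        if (strand == hit.strand) == (stranded == "sense"):
            return True
    return False


def categorize(tag: str, hits: Sequence[GenomeHit], ctx: AnnotationContext) -> str:
    """Single winner-takes-all category for one mapped tag.

    Multi-locus tags are decided from the union of their hits' overlaps;
    the best (highest-priority) category wins and read counts are never
    split across loci.
    """
    if not hits:
        return "unmapped"
    if ctx.mirna_hits(tag):
        return "known_miRNA"
    if ctx.is_ncrna(tag):
        return "ncRNA"
    if any(_overlaps(h, ctx.repeats) for h in hits):
        return "repeat"
    for feats, name in ((ctx.exons, "exon"), (ctx.introns, "intron")):
        for orientation in ("sense", "antisense"):
            if any(_overlaps(h, feats, orientation) for h in hits):
                return f"{name}_{orientation}"
    return "unknown"


def annotate_tags(
    tags: Mapping[str, Mapping[str, int]],
    genome: Mapping[str, str] | GenomeIndex,
    ctx: AnnotationContext,
) -> pd.DataFrame:
    """Map and categorize every tag; returns one row per tag."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    rows = []
    for seq in sorted(tags):
        hits = index.find(seq)
        cat = categorize(seq, hits, ctx)
        rows.append(
            {
                "sequence": seq,
                "category": cat,
                "n_hits": len(hits),
                "hits": ";".join(f"{h.chrom}:{h.start}-{h.end}({h.strand})" for h in hits),
                **{f"count_{lib}": n for lib, n in tags[seq].items()},
            }
        )
    return pd.DataFrame(rows)


def category_distribution(
    tags: Mapping[str, Mapping[str, int]], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-library unique/total read tallies by annotation category."""
    libs = sorted({lib for c in tags.values() for lib in c})
    cat_by_seq = dict(zip(annotation["sequence"], annotation["category"]))
    rows = {}
    for seq, counts in tags.items():
        cat = cat_by_seq[seq]
        row = rows.setdefault(cat, {f"unique_{l}": 0 for l in libs} | {f"total_{l}": 0 for l in libs})
        for lib, n in counts.items():
            row[f"unique_{lib}"] += 1
            row[f"total_{lib}"] += n
    out = pd.DataFrame(
        [{"category": c, **row} for c, row in rows.items()]
    )
    order = {c: i for i, c in enumerate((*CATEGORY_PRIORITY, "unmapped"))}
    return out.sort_values("category", key=lambda s: s.map(order)).reset_index(drop=True)
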