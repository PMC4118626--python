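"""Synthetic genome, references, and four-library sRNA read simulation.

The simulator emulates a leaf/root x salt/control design: planted conserved
and novel hairpin loci (with mature/star duplexes carrying canonical 2-nt 3'
overhangs), planted ncRNA and exon/intron loci, a uniform random background,
planted per-locus fold-changes applied in the treated libraries, and
adapter/polyA/low-quality contaminant reads at configured rates.  Everything
is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import LIBRARIES, TREATED, ConfigError, SimulationConfig
from .fold import fold, is_hairpin
from .io import ensure_dir, revcomp, to_rna, write_fasta, write_fastq

__all__ = ["GroundTruthRecord", "SyntheticData", "build_genome", "simulate_libraries", "sample_counts"]

_BASES = np.array(list("ACGT"))
_NCRNA_TYPES = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA")

# layout constants for planted hairpin precursors (DNA coordinates)
_LEAD = 10
_MATURE_LEN = 21
_LOOP_LEN = 12


@dataclass
class GroundTruthRecord:
    locus_id: str
    cls: str                  # conserved | novel | ncRNA | exon | repeat
    chrom: str
    start: int                # 0-based half-open on the plus strand
    end: int
    strand: str
    mature_seq: str = ""      # DNA space, locus-sense orientation
    star_seq: str = ""
    precursor_seq: str = ""
    true_log2fc: float = 0.0
    arm: str = ""
    weight: float = 0.0       # relative expression weight (control condition)
    family: str = ""


@dataclass
class SyntheticData:
    config: SimulationConfig
    genome: dict[str, str]
    exons: list[tuple[str, int, int, str, str]]
    repeats: list[tuple[str, int, int]]
    ncrna_ref: dict[str, str]
    mature_ref: dict[str, str]        # RNA space
    precursor_ref: dict[str, str]     # RNA space
    transcripts: dict[str, str]
    truth: dict[str, GroundTruthRecord] = field(default_factory=dict)


def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _make_precursor(rng, arm: str) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """One planted hairpin precursor.

    Layout: lead(10) + arm5(21) + loop(12) + revcomp(arm5)(21) + revcomp(lead)(10)
    + tail(10).  The perfect 31-pair stem guarantees a single-stem fold; the
    loop uses only A/C so it cannot pair internally.  Mature and star occupy
    opposite arms with a 2-nt 3' overhang in the duplex.
    """
    lead = _rand_seq(rng, _LEAD)
    arm5 = _rand_seq(rng, _MATURE_LEN)
    loop = "".join(np.array(list("AC"))[rng.integers(0, 2, _LOOP_LEN)])
    tail = _rand_seq(rng, _LEAD)
    pre = lead + arm5 + loop + revcomp(arm5) + revcomp(lead) + tail
    a5 = (_LEAD, _LEAD + _MATURE_LEN)                      # 5' arm segment
    s0 = _LEAD + _MATURE_LEN + _LOOP_LEN + 2               # 3' arm, 2-nt 3' overhang
    a3 = (s0, s0 + _MATURE_LEN)
    if arm == "5p":
        return pre, a5, a3
    return pre, a3, a5


def _place_loci(cfg: SimulationConfig, sizes: list[tuple[str, int]], rng):
    """Assign (chrom, start) slots round-robin with even spacing."""
    per_chrom: dict[int, list[tuple[str, int]]] = {i: [] for i in range(cfg.n_chromosomes)}
    for i, item in enumerate(sizes):
        per_chrom[i % cfg.n_chromosomes].append(item)
    slots = {}
    for ci, items in per_chrom.items():
        used = sum(n for _, n in items)
        gap_total = cfg.chrom_length - used
        min_gap = 50
        if gap_total < min_gap * (len(items) + 1):
            raise ConfigError(
                f"chromosome length {cfg.chrom_length} too short to host "
                f"{len(items)} loci totalling {used} nt with {min_gap} nt gaps"
            )
        gap = gap_total // (len(items) + 1)
        pos = gap
        for locus_id, n in items:
            slots[locus_id] = (f"chr{ci + 1}", pos)
            pos += n + gap
    return slots


def build_genome(cfg: SimulationConfig) -> SyntheticData:
    """Build the toy genome plus every reference the pipeline consumes."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))

    # draft the planted sequences first
    plans: list[dict] = []
    for cls, n in (("conserved", cfg.n_conserved_loci), ("novel", cfg.n_novel_loci)):
        for i in range(n):
            locus_id = f"{'cons' if cls == 'conserved' else 'nov'}_{i + 1:02d}"
            arm = "5p" if rng.random() < cfg.frac_5p_arm else "3p"
            for _ in range(30):
                pre, mat, star = _make_precursor(rng, arm)
                hp = fold(to_rna(pre))
                ok, _arms = is_hairpin(hp, min_stem_pairs=16, mfe_max=-18.0)
                if ok:
                    break
            else:  # pragma: no cover - construction virtually never fails
                raise RuntimeError(f"could not build hairpin for {locus_id}")
            plans.append(
                dict(locus_id=locus_id, cls=cls, seq=pre, mature=mat, star=star,
                     arm=arm, mfe=hp.mfe)
            )
    for i in range(cfg.n_ncrna_loci):
        plans.append(
            dict(locus_id=f"ncrna_{i + 1:02d}", cls="ncRNA",
                 seq=_rand_seq(rng, int(rng.integers(80, 150))))
        )
    for i in range(cfg.n_exon_loci):
        exon1 = _rand_seq(rng, 150)
        intron = _rand_seq(rng, 80)
        exon2 = _rand_seq(rng, 150)
        plans.append(
            dict(locus_id=f"exon_{i + 1:02d}", cls="exon", seq=exon1 + intron + exon2,
                 exon_len=(150, 80, 150))
        )
    for i in range(cfg.n_repeat_loci):
        plans.append(dict(locus_id=f"repeat_{i + 1:02d}", cls="repeat",
                          seq=_rand_seq(rng, 200)))

    slots = _place_loci(cfg, [(p["locus_id"], len(p["seq"])) for p in plans], rng)

    # background genome then overwrite planted loci in place
    chroms = {
        f"chr{i + 1}": np.array(list(_rand_seq(rng, cfg.chrom_length)))
        for i in range(cfg.n_chromosomes)
    }
    data = SyntheticData(
        config=cfg, genome={}, exons=[], repeats=[], ncrna_ref={},
        mature_ref={}, precursor_ref={}, transcripts={},
    )

    # expression weights over expressed loci (miRNA + ncRNA + exon)
    expressed = [p for p in plans if p["cls"] in ("conserved", "novel", "ncRNA", "exon")]
    weights = rng.lognormal(0.0, 0.7, len(expressed))
    if len(expressed):
        weights /= weights.sum()
    wmap = {p["locus_id"]: float(w) for p, w in zip(expressed, weights)}

    for k, plan in enumerate(plans):
        locus_id, cls, seq = plan["locus_id"], plan["cls"], plan["seq"]
        chrom, start = slots[locus_id]
        strand = "-" if k % 4 == 3 else "+"
        placed = revcomp(seq) if strand == "-" else seq
        chroms[chrom][start : start + len(seq)] = list(placed)
        rec = GroundTruthRecord(
            locus_id=locus_id, cls=cls, chrom=chrom, start=start,
            end=start + len(seq), strand=strand,
            true_log2fc=float(cfg.planted_log2fc.get(locus_id, 0.0)),
            weight=wmap.get(locus_id, 0.0),
        )
        if cls in ("conserved", "novel"):
            (a, b), (s0, s1) = plan["mature"], plan["star"]
            rec.mature_seq = seq[a:b]
            rec.star_seq = seq[s0:s1]
            rec.precursor_seq = seq
            rec.arm = plan["arm"]
            if cls == "conserved":
                fam_no = 156 + (int(locus_id.split("_")[1]) - 1) // 2
                member = "ab"[(int(locus_id.split("_")[1]) - 1) % 2]
                rec.family = f"miR{fam_no}"
                ref_id = f"peu-miR{fam_no}{member}"
                data.mature_ref[ref_id] = to_rna(rec.mature_seq)
                data.precursor_ref[ref_id] = to_rna(seq)
        elif cls == "ncRNA":
            i = int(locus_id.split("_")[1]) - 1
            data.ncrna_ref[f"{_NCRNA_TYPES[i % len(_NCRNA_TYPES)]}_{i + 1:02d}"] = seq
        elif cls == "exon":
            e1, ilen, e2 = plan["exon_len"]
            tx = f"tx_{locus_id}"
            if strand == "+":
                data.exons.append((chrom, start, start + e1, "+", tx))
                data.exons.append((chrom, start + e1 + ilen, start + e1 + ilen + e2, "+", tx))
            else:
                data.exons.append((chrom, start, start + e2, "-", tx))
                data.exons.append((chrom, start + e2 + ilen, start + e2 + ilen + e1, "-", tx))
            data.transcripts[tx] = seq[:e1] + seq[e1 + ilen :]
        elif cls == "repeat":
            data.repeats.append((chrom, start, start + len(seq)))
        data.truth[locus_id] = rec

    data.genome = {c: "".join(a) for c, a in chroms.items()}

    # one transcript per planted mature carrying an exact complementary site
    for rec in data.truth.values():
        if rec.cls in ("conserved", "novel"):
            site = revcomp(rec.mature_seq)
            left = _rand_seq(rng, 150)
            right = _rand_seq(rng, 130)
            data.transcripts[f"target_{rec.locus_id}"] = left + site + right
    return data


def sample_counts(mean: float, dispersion: float, rng) -> int:
    """Negative-binomial (Gamma-Poisson) count; dispersion 0 is Poisson."""
    if mean <= 0:
        return 0
    if dispersion > 0:
        lam = rng.gamma(1.0 / dispersion, mean * dispersion)
        return int(rng.poisson(lam))
    return int(rng.poisson(mean))


def _mixture_lengths(cfg: SimulationConfig, rng, n: int) -> np.ndarray:
    lengths = np.array(sorted(cfg.length_mixture))
    probs = np.array([cfg.length_mixture[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    return rng.choice(lengths, size=n, p=probs)


def _random_fragment(data: SyntheticData, cfg, rng, length: int) -> str:
    chrom = f"chr{int(rng.integers(1, cfg.n_chromosomes + 1))}"
    seq = data.genome[chrom]
    pos = int(rng.integers(0, len(seq) - length))
    frag = seq[pos : pos + length]
    return frag if rng.random() < 0.5 else revcomp(frag)


def _locus_fragment(data: SyntheticData, rec, rng, length: int, antisense_rate=0.2) -> str:
    seq = data.genome[rec.chrom][rec.start : rec.end]
    length = min(length, len(seq))
    pos = int(rng.integers(0, len(seq) - length + 1))
    frag = seq[pos : pos + length]
    if rec.strand == "-":
        frag = revcomp(frag)
    if rng.random() < antisense_rate:
        frag = revcomp(frag)
    return frag


def simulate_libraries(
    data: SyntheticData, cfg: SimulationConfig | None = None
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Sample the four FASTQ libraries plus the expected-count table.

    Returns ``(reads_by_library, expected_counts)`` where each read is a
    (title, sequence, quality) triple; titles encode the read's origin so
    tests can audit every downstream stage.  Treated-library locus means are
    scaled by ``2**true_log2fc``.
    """
    cfg = (cfg or data.config).validate()
    a3 = cfg.adapter3
    expected_rows = []
    libraries: dict[str, list[tuple[str, str, str]]] = {}
    for li, lib in enumerate(LIBRARIES):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000 + li]))
        total = cfg.reads_per_library
        n_cont = {
            cat: int(rng.binomial(total, rate))
            for cat, rate in sorted(cfg.contamination_rates.items())
        }
        n_genuine = total - sum(n_cont.values())
        n_background = int(round(n_genuine * cfg.background_fraction))
        locus_budget = n_genuine - n_background

        inserts: list[tuple[str, str]] = []  # (origin, insert DNA)
        for locus_id in sorted(data.truth):
            rec = data.truth[locus_id]
            if rec.weight <= 0:
                continue
            mean = locus_budget * rec.weight
            if TREATED[lib]:
                mean *= 2.0 ** rec.true_log2fc
            if rec.cls in ("conserved", "novel"):
                n_mat = sample_counts(mean, cfg.dispersion, rng)
                n_star = sample_counts(mean * cfg.star_fraction, cfg.dispersion, rng)
                inserts.extend((locus_id, rec.mature_seq) for _ in range(n_mat))
                inserts.extend((f"{locus_id}.star", rec.star_seq) for _ in range(n_star))
                expected_rows.append((lib, locus_id, n_mat, n_star))
            else:
                n_frag = sample_counts(mean, cfg.dispersion, rng)
                for L in _mixture_lengths(cfg, rng, n_frag):
                    inserts.append((locus_id, _locus_fragment(data, rec, rng, int(L))))
                expected_rows.append((lib, locus_id, n_frag, 0))

        for L in _mixture_lengths(cfg, rng, n_background):
            inserts.append(("background", _random_fragment(data, cfg, rng, int(L))))

        reads: list[tuple[str, str, str]] = []
        for origin, insert in inserts:
            seq = insert + a3
            reads.append((origin, seq, "I" * len(seq)))
        for _ in range(n_cont["adapter_null"]):
            seq = _rand_seq(rng, 25)
            reads.append(("adapter_null", seq, "I" * len(seq)))
        for _ in range(n_cont["insert_null"]):
            seq = a3 + _rand_seq(rng, 5)
            reads.append(("insert_null", seq, "I" * len(seq)))
        for _ in range(n_cont["polyA"]):
            seq = "A" * int(rng.integers(cfg.min_len, 27)) + a3
            reads.append(("polyA", seq, "I" * len(seq)))
        for _ in range(n_cont["low_quality"]):
            seq = _random_fragment(data, cfg, rng, 21) + a3
            reads.append(("low_quality", seq, "#" * len(seq)))

        order = rng.permutation(len(reads))
        libraries[lib] = [
            (f"{lib}:{i}:{reads[j][0]}", reads[j][1], reads[j][2])
            for i, j in enumerate(order)
        ]
    expected = pd.DataFrame(
        expected_rows, columns=["library", "locus_id", "count", "star_count"]
    )
    return libraries, expected


# ---------------------------------------------------------------------------
# writers

def write_outputs(data: SyntheticData, outdir) -> dict[str, Path]:
    """Write genome + references + ground truth as plain-text files."""
    out = ensure_dir(outdir)
    paths = {}
    write_fasta(out / "genome.fa", sorted(data.genome.items()))
    paths["genome"] = out / "genome.fa"
    with open(out / "annotation.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, strand, tx in sorted(data.exons):
            fh.write(
                f"{chrom}\tsaltmir\texon\t{start + 1}\t{end}\t.\t{strand}\t.\tParent={tx}\n"
            )
    paths["gff"] = out / "annotation.gff3"
    with open(out / "repeats.bed", "w") as fh:
        for chrom, start, end in sorted(data.repeats):
            fh.write(f"{chrom}\t{start}\t{end}\trepeat\n")
    paths["repeats"] = out / "repeats.bed"
    write_fasta(out / "ncrna.fa", sorted(data.ncrna_ref.items()))
    paths["ncrna"] = out / "ncrna.fa"
    write_fasta(out / "mature_mirna.fa", sorted(data.mature_ref.items()))
    paths["mature"] = out / "mature_mirna.fa"
    write_fasta(out / "precursor_mirna.fa", sorted(data.precursor_ref.items()))
    paths["precursor"] = out / "precursor_mirna.fa"
    write_fasta(out / "transcripts.fa", sorted(data.transcripts.items()))
    paths["transcripts"] = out / "transcripts.fa"
    rows = []
    for locus_id in sorted(data.truth):
        r = data.truth[locus_id]
        rows.append(
            {
                "locus_id": r.locus_id, "class": r.cls, "chrom": r.chrom,
                "start": r.start, "end": r.end, "strand": r.strand,
                "mature_seq": r.mature_seq, "star_seq": r.star_seq,
                "precursor_seq": r.precursor_seq, "true_log2fc": r.true_log2fc,
                "arm": r.arm, "weight": r.weight, "family": r.family,
            }
        )
    pd.DataFrame(rows).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "ground_truth.tsv"
    return paths


def write_libraries(libraries: Mapping[str, list], expected: pd.DataFrame, outdir):
    out = ensure_dir(outdir)
    paths = {}
    for lib, reads in libraries.items():
        write_fastq(out / f"{lib}.fastq", reads)
        paths[lib] = out / f"{lib}.fastq"
    expected.to_csv(out / "expected_counts.tsv", sep="\t", index=False)
    paths["expected"] = out / "expected_counts.tsv"
    return paths
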