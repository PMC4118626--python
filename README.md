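# saltmir

A small RNA-seq analysis toolkit modelled on a four-library salt-stress
design (treated/control x leaf/root). It provides, as importable modules and
as a `saltmir` command line:

- **simulate** — a synthetic-data generator: toy genome, gene-model GFF3,
  repeat BED, ncRNA/mature/precursor references, transcripts, and four FASTQ
  libraries with planted conserved/novel hairpin loci (mature/star duplexes
  with canonical 2-nt 3' overhangs), planted fold-changes, a configurable
  18–30 nt length mixture peaking at 21 nt, and adapter/polyA/low-quality
  contaminants. Fully deterministic per seed.
- **preprocess** — FASTQ cleaning (low-quality, 5' adapter contaminant,
  3'-adapter-null, insert-null, polyA, length filters in a fixed order),
  tag collapsing with per-library counts, and common/specific
  unique-vs-total summary tables.
- **annotate** — perfect-match genome mapping (both strands) and
  winner-takes-all category assignment: known_miRNA > ncRNA > repeat >
  exon (sense/antisense) > intron (sense/antisense) > unknown.
- **fold** — a self-contained minimum-free-energy folding engine
  (nearest-neighbor stacks, logarithmic loop penalties, multibranch loops;
  numba-accelerated interval DP) plus a single-stem hairpin qualifier.
- **discover** — conserved miRNA calling against a mature/precursor
  reference (≤2 mismatches, ≥5 reads, hairpin precursor, star detection)
  and genome-guided novel miRNA calling (precursor window excision, stem
  walking, duplex/star support with 1–3 nt 3' overhang).
- **targets** — plant-style gapless target prediction (mismatch 1.0,
  G:U wobble 0.5, doubled weights at positions 2–13, cleavage-site guard,
  score ≤ 4 by default) and a functional-label join hook.
- **de** — reads-per-million normalization, the exact conditional
  count-ratio test p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1))
  computed in log space, lower/upper tails, two-sided p = 2·min(C, D),
  and up/down calls (|log2fc| > 0.5, p < 0.05, RPM ≥ 1 by default; optional
  Benjamini–Hochberg flag).
- **pipeline** — `run-all` orchestration with a SHA-256 manifest,
  stage caching, and report tables (length distribution, category
  distribution, common/specific, family abundance, DE summary).

## CLI

```bash
saltmir simulate --seed 1 --outdir run/              # synthetic inputs
saltmir clean run/reads/3dSL.fastq --adapter3 ... --adapter5 ... \
    --library 3dSL --outdir run/clean
saltmir summarize-libs run/clean/tags.tsv --lib-a 3dSL --lib-b 3dCKL --out t.tsv
saltmir annotate tags.tsv --genome genome.fa --gff annotation.gff3 \
    --ncrna ncrna.fa --mature mature.fa --outdir run/annot
saltmir fold precursors.fa --out structures.txt
saltmir targets catalog.tsv --transcripts transcripts.fa --out sites.tsv
saltmir de counts.tsv --treatment 3dSL --control 3dCKL \
    --total-treatment 16300000 --total-control 15700000 --out de.tsv
saltmir run-all --config cfg.yaml --outdir run/      # whole pipeline
```

`run-all` takes a single YAML file; every threshold named above is a key
with the stated default, e.g.:

```yaml
seed: 1
simulate:
  n_conserved_loci: 20
  n_novel_loci: 10
  reads_per_library: 100000
  planted_log2fc: {cons_01: 2.0}
discover: {min_reads: 5, require_star: true}
de: {pairs: [[3dSL, 3dCKL], [3dSR, 3dCKR]], fc: 0.5, p: 0.05}
```

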