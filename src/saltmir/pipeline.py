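"""End-to-end orchestration: simulate -> clean -> annotate -> discover ->
targets -> de -> report, with a checksum manifest and stage-level caching.

Each stage writes plain-text outputs into the run directory and records
their SHA-256 in ``manifest.json``.  On rerun, a stage whose recorded
outputs all exist with matching checksums is loaded from disk instead of
recomputed; an output that exists with a different checksum halts the run
naming the corrupted file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (
    AnnotationContext,
    GenomeIndex,
    annotate_tags,
    category_distribution,
)
from .config import LIBRARIES, CleanParams, SimulationConfig
from .de import call_de
from .discover import (
    DiscoveryParams,
    call_conserved,
    call_novel,
    catalog_frame,
    family_summary,
)
from .io import ensure_dir, read_fasta, sha256, write_fasta
from .preprocess import clean_reads, collapse_tags, common_specific_summary, tags_to_frame
from .simulate import build_genome, simulate_libraries, write_libraries, write_outputs

log = logging.getLogger(__name__)

DEFAULT_DE_PAIRS = [("3dSL", "3dCKL"), ("3dSR", "3dCKR")]


class StageError(RuntimeError):
    pass


def _records_from_catalog(catalog: pd.DataFrame):
    """Rebuild lightweight miRNA records from a cached catalog TSV."""
    from .discover import MiRNARecord

    records = []
    count_cols = [c for c in catalog.columns if c.startswith("count_")]
    for row in catalog.to_dict("records"):
        counts = {
            c.removeprefix("count_"): int(row[c])
            for c in count_cols
            if pd.notna(row[c]) and int(row[c]) > 0
        }
        records.append(
            MiRNARecord(
                id=row["id"],
                cls=row["class"],
                family=row.get("family", "") or "",
                mature_seq=row["mature_seq"],
                star_seq=row.get("star_seq", "") or "",
                precursor_seq=row["precursor_seq"],
                mfe=float(row["mfe"]),
                counts=counts,
                arm=row.get("arm", "") or "",
                first_nt=row.get("first_nt", "") or "",
            )
        )
    return records


class PipelineRun:
    def __init__(self, config: dict, outdir):
        self.config = config
        self.outdir = ensure_dir(outdir)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = {
            "version": __version__,
            "seed": config.get("seed", 0),
            "config": config,
            "stages": {},
        }
        self.previous = {}
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                self.previous = json.load(fh).get("stages", {})
        self.state: dict = {}

    # -- caching machinery -------------------------------------------------
    def _cached(self, stage: str) -> bool:
        prev = self.previous.get(stage)
        if not prev:
            return False
        for rel, digest in prev["outputs"].items():
            path = self.outdir / rel
            if not path.exists():
                return False
            if sha256(path) != digest:
                raise StageError(
                    f"stage {stage}: checksum mismatch for {path.name}"
                )
        return True

    def _record(self, stage: str, files: list[Path], counts: dict | None = None):
        self.manifest["stages"][stage] = {
            "outputs": {str(f.relative_to(self.outdir)): sha256(f) for f in files},
            "counts": counts or {},
        }

    def _finish(self):
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)

    # -- stages ------------------------------------------------------------
    def stage_simulate(self):
        sim_cfg = SimulationConfig.from_dict(
            {"seed": self.config.get("seed", 0), **self.config.get("simulate", {})}
        )
        self.state["sim_cfg"] = sim_cfg
        refdir = self.outdir / "refs"
        libdir = self.outdir / "reads"
        if self._cached("simulate"):
            log.info("simulate: cached")
            data = None
        else:
            data = build_genome(sim_cfg)
            paths = write_outputs(data, refdir)
            libraries, expected = simulate_libraries(data)
            lpaths = write_libraries(libraries, expected, libdir)
            self._record(
                "simulate",
                [*paths.values(), *lpaths.values()],
                {"loci": len(data.truth)},
            )
            self.manifest["stages"]["simulate"]["counts"]["reads_per_library"] = (
                sim_cfg.reads_per_library
            )
        self.state["genome"] = read_fasta(refdir / "genome.fa")
        self.state["mature_ref"] = read_fasta(refdir / "mature_mirna.fa")
        self.state["precursor_ref"] = read_fasta(refdir / "precursor_mirna.fa")
        self.state["ncrna_ref"] = read_fasta(refdir / "ncrna.fa")
        self.state["transcripts"] = read_fasta(refdir / "transcripts.fa")
        self.state["gff"] = refdir / "annotation.gff3"
        repeats = []
        for line in open(refdir / "repeats.bed"):
            f = line.split("\t")
            repeats.append((f[0], int(f[1]), int(f[2])))
        self.state["repeats"] = repeats
        self.state["fastqs"] = {lib: libdir / f"{lib}.fastq" for lib in LIBRARIES}
        self.state["truth"] = pd.read_csv(refdir / "ground_truth.tsv", sep="\t")

    def stage_clean(self):
        ccfg = CleanParams(**self.config.get("clean", {}))
        sim_cfg = self.state["sim_cfg"]
        cdir = ensure_dir(self.outdir / "clean")
        tags_path = cdir / "tags.tsv"
        stats_path = cdir / "clean_stats.tsv"
        if self._cached("clean"):
            log.info("clean: cached")
            tdf = pd.read_csv(tags_path, sep="\t")
            tags = {
                row["sequence"]: {
                    lib: int(row[lib]) for lib in LIBRARIES if row[lib] > 0
                }
                for row in tdf.to_dict("records")
            }
            sdf = pd.read_csv(stats_path, sep="\t")
            totals = {
                lib: int(
                    sdf.loc[(sdf.library == lib) & (sdf.metric == "clean_reads"), "count"].iloc[0]
                )
                for lib in LIBRARIES
            }
            self.state["stats_frame"] = sdf
        else:
            clean_by_lib, stats_frames, totals = {}, [], {}
            for lib in LIBRARIES:
                seqs, stats = clean_reads(
                    self.state["fastqs"][lib], sim_cfg.adapter3, sim_cfg.adapter5, ccfg
                )
                clean_by_lib[lib] = seqs
                totals[lib] = stats.clean_reads
                sf = stats.to_frame()
                sf.insert(0, "library", lib)
                stats_frames.append(sf)
            tags = collapse_tags(clean_by_lib)
            tags_to_frame(tags, LIBRARIES).to_csv(tags_path, sep="\t", index=False)
            sdf = pd.concat(stats_frames, ignore_index=True)
            sdf.to_csv(stats_path, sep="\t", index=False)
            self.state["stats_frame"] = sdf
            self._record("clean", [tags_path, stats_path], {"unique_tags": len(tags)})
        self.state["tags"] = tags
        self.state["clean_totals"] = totals

    def stage_annotate(self):
        acfg = self.config.get("annotate", {})
        adir = ensure_dir(self.outdir / "annotate")
        annot_path = adir / "tag_annotation.tsv"
        dist_path = adir / "category_distribution.tsv"
        ctx = AnnotationContext.from_gff(
            self.state["gff"],
            mature_ref=self.state["mature_ref"],
            ncrna_ref=self.state["ncrna_ref"],
            repeats=self.state["repeats"],
            max_mm=int(acfg.get("max_mm", 2)),
        )
        index = GenomeIndex(self.state["genome"])
        self.state["genome_index"] = index
        if self._cached("annotate"):
            log.info("annotate: cached")
            annot = pd.read_csv(annot_path, sep="\t", keep_default_na=False)
        else:
            annot = annotate_tags(self.state["tags"], index, ctx)
            annot.to_csv(annot_path, sep="\t", index=False)
            dist = category_distribution(self.state["tags"], annot)
            dist.to_csv(dist_path, sep="\t", index=False)
            self._record(
                "annotate",
                [annot_path, dist_path],
                {"mapped_tags": int((annot.category != "unmapped").sum())},
            )
        self.state["annotation"] = annot

    def stage_discover(self):
        dcfg = self.config.get("discover", {})
        params = DiscoveryParams(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in dcfg.items()
            }
        )
        ddir = ensure_dir(self.outdir / "discover")
        cat_path = ddir / "mirna_catalog.tsv"
        pre_path = ddir / "precursors.fa"
        str_path = ddir / "structures.txt"
        if self._cached("discover"):
            log.info("discover: cached")
            catalog = pd.read_csv(cat_path, sep="\t", keep_default_na=False)
            self.state["catalog"] = catalog
            self.state["records"] = _records_from_catalog(catalog)
            return
        conserved = call_conserved(
            self.state["tags"],
            self.state["mature_ref"],
            self.state["precursor_ref"],
            genome=self.state["genome_index"],
            params=params,
        )
        annot = self.state["annotation"]
        unknown = annot.loc[annot.category == "unknown", "sequence"].tolist()
        novel = call_novel(
            self.state["tags"],
            unknown,
            self.state["genome"],
            genome_index=self.state["genome_index"],
            params=params,
            conserved_loci=[r.locus for r in conserved if r.locus],
        )
        records = [*conserved, *novel]
        catalog = catalog_frame(records)
        catalog.to_csv(cat_path, sep="\t", index=False)
        write_fasta(pre_path, [(r.id, r.precursor_seq) for r in records])
        with open(str_path, "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n{r.precursor_seq}\n{r.structure} ({r.mfe:.2f})\n")
        self._record(
            "discover",
            [cat_path, pre_path, str_path],
            {"conserved": len(conserved), "novel": len(novel)},
        )
        self.state["records"] = records
        self.state["catalog"] = catalog

    def stage_targets(self):
        from .targets import predict_targets, target_summary

        tcfg = self.config.get("targets", {})
        tdir = ensure_dir(self.outdir / "targets")
        sites_path = tdir / "target_sites.tsv"
        if self._cached("targets"):
            log.info("targets: cached")
            self.state["target_sites"] = pd.read_csv(sites_path, sep="\t")
            return
        mirnas = {r.id: r.mature_seq for r in self.state["records"]}
        sites = predict_targets(
            mirnas,
            self.state["transcripts"],
            max_score=float(tcfg.get("max_score", 4.0)),
        )
        sdf = pd.DataFrame(sites, columns=["mirna_id", "transcript_id", "site_start",
                                           "site_end", "mismatches", "gu_wobbles", "score"])
        sdf.to_csv(sites_path, sep="\t", index=False)
        summary = target_summary(sites)
        summary.to_csv(tdir / "target_summary.tsv", sep="\t", index=False)
        self._record(
            "targets", [sites_path, tdir / "target_summary.tsv"],
            {"sites": len(sites)},
        )
        self.state["target_sites"] = sdf

    def stage_de(self):
        decfg = self.config.get("de", {})
        pairs = [tuple(p) for p in decfg.get("pairs", DEFAULT_DE_PAIRS)]
        dedir = ensure_dir(self.outdir / "de")
        counts = {r.id: r.counts for r in self.state["records"]}
        outputs = []
        de_frames = {}
        if self._cached("de"):
            log.info("de: cached")
            for treatment, control in pairs:
                path = dedir / f"de_{treatment}_vs_{control}.tsv"
                de_frames[(treatment, control)] = pd.read_csv(path, sep="\t")
            self.state["de"] = de_frames
            return
        for treatment, control in pairs:
            df = call_de(
                counts,
                treatment,
                control,
                self.state["clean_totals"],
                fc_cut=float(decfg.get("fc", 0.5)),
                p_cut=float(decfg.get("p", 0.05)),
                min_norm=float(decfg.get("min_norm", 1.0)),
                bh_correction=bool(decfg.get("bh", False)),
            )
            path = dedir / f"de_{treatment}_vs_{control}.tsv"
            df.to_csv(path, sep="\t", index=False)
            outputs.append(path)
            de_frames[(treatment, control)] = df
        self._record("de", outputs, {"pairs": len(pairs)})
        self.state["de"] = de_frames

    def stage_report(self):
        rdir = ensure_dir(self.outdir / "report")
        outputs = []
        # length distribution per library
        sdf = self.state["stats_frame"]
        lens = sdf[sdf.metric.str.startswith("len_")].copy()
        lens["length"] = lens.metric.str.removeprefix("len_").astype(int)
        ldist = lens.pivot_table(index="length", columns="library", values="count",
                                 fill_value=0).reset_index()
        p = rdir / "length_distribution.tsv"
        ldist.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        # common/specific tables per tissue pair (Tables-1/2-style)
        for a, b in (("3dSL", "3dCKL"), ("3dCKR", "3dSR")):
            libs_present = {l for c in self.state["tags"].values() for l in c}
            if a not in libs_present or b not in libs_present:
                log.info("common/specific table for %s vs %s skipped: library absent", a, b)
                continue
            table = common_specific_summary(self.state["tags"], a, b)
            p = rdir / f"common_specific_{a}_{b}.tsv"
            table.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        # conserved family abundance
        if any(r.cls == "conserved" for r in self.state["records"]):
            fam = family_summary(self.state["records"], LIBRARIES)
            p = rdir / "family_abundance.tsv"
            fam.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        # DE call counts per comparison
        rows = []
        for (t, c), df in self.state["de"].items():
            rows.append(
                {
                    "treatment": t,
                    "control": c,
                    "n_tested": int((df.call != "filtered").sum()),
                    "n_up": int((df.call == "up").sum()),
                    "n_down": int((df.call == "down").sum()),
                }
            )
        p = rdir / "de_summary.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        outputs.append(p)
        self._record("report", outputs)

    def run(self) -> dict:
        stages = [
            ("simulate", self.stage_simulate),
            ("clean", self.stage_clean),
            ("annotate", self.stage_annotate),
            ("discover", self.stage_discover),
            ("targets", self.stage_targets),
            ("de", self.stage_de),
            ("report", self.stage_report),
        ]
        for name, fn in stages:
            try:
                fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name} failed: {exc}") from exc
            if name not in self.manifest["stages"] and name in self.previous:
                self.manifest["stages"][name] = self.previous[name]
        self._finish()
        return self.manifest


def run_all(config: dict, outdir) -> dict:
    """Run the full pipeline into ``outdir``; returns the manifest."""
    return PipelineRun(config, outdir).run()
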