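import numpy as np
import pytest

from saltmir.annotate import AnnotationContext, GenomeIndex, annotate_tags
from saltmir.config import LIBRARIES, SimulationConfig
from saltmir.io import write_fastq
from saltmir.preprocess import clean_reads, collapse_tags
from saltmir.simulate import build_genome, simulate_libraries


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        seed=7,
        n_chromosomes=1,
        chrom_length=12_000,
        n_conserved_loci=4,
        n_novel_loci=2,
        n_ncrna_loci=2,
        n_exon_loci=2,
        n_repeat_loci=1,
        reads_per_library=3_000,
        planted_log2fc={"cons_01": 2.0, "cons_02": -2.0},
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return build_genome(small_cfg)


@pytest.fixture(scope="session")
def small_libs(small_data):
    return simulate_libraries(small_data)


@pytest.fixture(scope="session")
def small_tags(small_data, small_libs, tmp_path_factory):
    """Cleaned + collapsed tags, clean totals, and annotation for the small run."""
    libs, _expected = small_libs
    cfg = small_data.config
    tmp = tmp_path_factory.mktemp("small_fastq")
    clean_by, totals = {}, {}
    for lib in LIBRARIES:
        path = tmp / f"{lib}.fastq"
        write_fastq(path, libs[lib])
        seqs, stats = clean_reads(path, cfg.adapter3, cfg.adapter5)
        clean_by[lib] = seqs
        totals[lib] = stats.clean_reads
    tags = collapse_tags(clean_by)
    index = GenomeIndex(small_data.genome)
    ctx = AnnotationContext(
        mature_ref=small_data.mature_ref,
        ncrna_ref=small_data.ncrna_ref,
        exons=small_data.exons,
        repeats=small_data.repeats,
    )
    annot = annotate_tags(tags, index, ctx)
    return {"tags": tags, "totals": totals, "annotation": annot, "index": index}


@pytest.fixture(scope="session")
def e2e_cfg():
    """Scaled recovery configuration: 20 conserved + 10 novel loci, 1e5 reads/library."""
    return {
        "seed": 11,
        "simulate": {
            "n_chromosomes": 2,
            "chrom_length": 50_000,
            "n_conserved_loci": 20,
            "n_novel_loci": 10,
            "n_ncrna_loci": 8,
            "n_exon_loci": 8,
            "n_repeat_loci": 4,
            "reads_per_library": 100_000,
            "planted_log2fc": {"cons_01": 2.0, "cons_02": -2.0, "nov_01": 2.0},
        },
    }


@pytest.fixture(scope="session")
def e2e_run(e2e_cfg, tmp_path_factory):
    from saltmir.pipeline import run_all

    outdir = tmp_path_factory.mktemp("e2e_run")
    manifest = run_all(e2e_cfg, outdir)
    return {"outdir": outdir, "manifest": manifest}


def rng(seed=0):
    return np.random.default_rng(seed)
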