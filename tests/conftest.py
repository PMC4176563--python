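import logging
from pathlib import Path

import pytest

from mirstack import pipeline as pl
from mirstack.synthetic_data import (SimulationSpec, build_genome,
                                     simulate_reads, write_simulation)

logging.disable(logging.INFO)

DATA = Path(__file__).parent / "data"

#: adapters used throughout the fixtures (Illumina TruSeq small-RNA)
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


@pytest.fixture(scope="session")
def toy_fastq() -> Path:
    """12-read fixture covering every discard rule, hand-verified truth.

    Reads (in file order): 2 kept + 1 kept duplicate + 1 kept at maximum
    adapter flank; 1 with a 5' adapter; 1 without any 3' adapter; 1 with
    only a 5 nt adapter flank (below the 6 nt minimum); 1 with an N in
    the insert; 1 all-A insert and 1 insert 80% A; 1 insert of 10 nt
    (below 18) and 1 of 30 nt (above 26).
    """
    return DATA / "toy12.fastq"


#: hand-verified truth for the fixture above
TOY_TRUTH = {
    "input_reads": 12,
    "discarded": {"adapter5": 1, "no_adapter3": 2, "ambiguous": 1,
                  "polya": 2, "length": 2},
    "kept_reads": 4,
    "tags": [("ACGTACGTACGTACGTACGTAC", 2),
             ("CCGGTTAACCGGTTAACC", 1),
             ("GCATGCATGCATGCATGCAT", 1)],
}


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A reduced-depth simulated study plus a full pipeline run over it.

    5,000 reads per sample keeps the whole-suite runtime low while
    exercising every stage; the full-depth study conditions are run in
    the dedicated acceptance test.
    """
    outdir = tmp_path_factory.mktemp("sim_small")
    spec = SimulationSpec(seed=1, reads_per_sample=5_000)
    data = build_genome(spec)
    libraries = simulate_reads(data)
    paths = write_simulation(data, outdir, libraries)
    cfg_dict = {
        "paths": {
            **{k: str(paths[k]) for k in ("genome_fasta", "mrna_fasta",
                                          "mirna_fasta", "mirna_gff3")},
            "samples": {c: str(p) for c, p in paths["samples"].items()},
        },
        "filter": {"adapter3": spec.adapter3},
        "patterns": {"cell_order": list(spec.cell_types)},
        "run": {"output_dir": str(outdir / "results"), "seed": 1},
    }
    cfg, errors = pl.validate_config(cfg_dict)
    assert not errors, errors
    results = pl.run_all(cfg)
    return {
        "spec": spec,
        "data": data,
        "libraries": libraries,
        "paths": paths,
        "cfg_dict": cfg_dict,
        "cfg": cfg,
        "results": results,
    }
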