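import pandas as pd
import pytest

from chordaseq import io as cio
from chordaseq import simdata


@pytest.fixture(scope="session")
def sim_config():
    return simdata.SimulationConfig(
        seed=7, n_contigs=3, contig_length=30_000, n_genes=12,
        reads_per_library=2000,
        de_genes=(
            simdata.DEGene("gene0011", "T1-vs-T3", 6.0),
            simdata.DEGene("gene0012", "A-vs-P", 6.0),
        ),
    )


@pytest.fixture(scope="session")
def dataset(sim_config, tmp_path_factory):
    """A full synthetic dataset written to disk once per session."""
    outdir = tmp_path_factory.mktemp("simdata")
    paths = simdata.generate_dataset(sim_config, outdir)
    return {"dir": outdir, "paths": paths, "config": sim_config}


@pytest.fixture(scope="session")
def truth(dataset):
    return simdata.GroundTruth.from_json(dataset["paths"]["truth"])


@pytest.fixture(scope="session")
def models(dataset):
    return cio.load_gene_models(dataset["paths"]["gff"])


@pytest.fixture(scope="session")
def design(dataset):
    return cio.load_design(dataset["paths"]["design"])


@pytest.fixture(scope="session")
def sam_reads(dataset, design):
    return {lib: list(cio.iter_sam_reads(dataset["dir"] / f"{lib}.sam"))
            for lib in design["library"]}


@pytest.fixture(scope="session")
def quantified(models, sam_reads, sim_config):
    from chordaseq.quantify import quantify_libraries

    return quantify_libraries(models, sam_reads,
                              read_length=sim_config.read_length)


@pytest.fixture(scope="session")
def nine_library_design():
    return pd.DataFrame(
        [{"library": f"{t}{s}", "stage": t, "segment": s}
         for t in ("T1", "T2", "T3") for s in ("A", "M", "P")])
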