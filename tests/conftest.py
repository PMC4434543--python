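import numpy as np
import pytest

from ligsel.genes import GeneModel
from ligsel.simulate import SimConfig, generate_dataset
from ligsel.tracks import CoverageTrack


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset shared across read-only tests."""
    cfg = SimConfig(
        seed=11,
        n_genes_per_class={
            "shared_up": 16, "bcr_pref_up": 16, "lps_pref_up": 16, "unchanged": 16
        },
        library_size=2e6,
    )
    return generate_dataset(cfg)


@pytest.fixture
def uniform_track():
    """Flat coverage of 3 counts/bp on a 60 kb chromosome, library 3e6
    (so the RPM value is exactly 1.0 everywhere)."""
    return CoverageTrack({"chr1": np.full(60_000, 3.0)}, total_mapped_reads=3e6)


def make_gene(gene_id="g1", chrom="chr1", tss=30_000, strand="+", length=4_000,
              extra_tss=()):
    if strand == "+":
        start, end = tss, tss + length
    else:
        start, end = tss - length + 1, tss + 1
    return GeneModel(gene_id, chrom, start, end, strand, (tss, *extra_tss))


@pytest.fixture
def plus_gene():
    return make_gene("plus1", tss=30_000, strand="+")


@pytest.fixture
def minus_gene():
    return make_gene("minus1", tss=30_000, strand="-")
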