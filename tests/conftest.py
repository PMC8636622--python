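import numpy as np
import pytest

from nucarray.core import GenomeLayout, GeneAnnotation
from nucarray.fragments import Fragment, FragmentSet, dyad_track
from nucarray.synthetic_data import GroundTruth, make_annotation, simulate_mnase


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout(("chrA", "chrB"), (50_000, 30_000))


@pytest.fixture(scope="session")
def toy_annotation():
    """20 alternating-strand genes on one toy chromosome."""
    return make_annotation(n_genes=20, chrom_length=200_000,
                           gene_length_range=(1800, 2600),
                           intergenic_gap=600, seed=11)


@pytest.fixture(scope="session")
def mnase_set(toy_annotation):
    """Phased-array fragment set with moderate jitter and background."""
    layout, genes = toy_annotation
    truth = GroundTruth(true_nrl=165, jitter_sd=10.0, depth=5000,
                        background_rate=0.05, seed=11)
    return simulate_mnase(genes, layout, truth), layout, genes, truth


@pytest.fixture(scope="session")
def mnase_track(mnase_set):
    frags, layout, genes, truth = mnase_set
    return dyad_track(frags, layout), genes


def make_frags(rows, **prov):
    return FragmentSet([Fragment(c, s, e) for c, s, e in rows],
                       provenance=prov)
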