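import numpy as np
import pytest

from famrisk.io_formats import Locus
from famrisk.pedigrees import nuclear_family
from famrisk.synthetic import FounderModel, build_genetic_map, gene_drop


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def single_chrom_map():
    return build_genetic_map([("1", 100_000_000)], 1.0)


@pytest.fixture
def dense_marker_loci():
    """2000 evenly spaced biallelic markers at frequency 0.5 on chromosome 1."""
    L = 100_000_000
    return [Locus(f"M{i}", "1", int(p), "A", "G", 0.5)
            for i, p in enumerate(np.linspace(50_000, L - 50_000, 2000))]


@pytest.fixture
def quartet():
    return nuclear_family(n_children=2)


@pytest.fixture
def quartet_drop(quartet, single_chrom_map, dense_marker_loci, rng):
    """One seeded gene drop of a quartet with dense markers."""
    fm = FounderModel(dense_marker_loci)
    return gene_drop(quartet, single_chrom_map, fm, rng=rng)
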