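import numpy as np
import pytest

import isomirome as iso
from isomirome import pipeline as pl


@pytest.fixture(scope="session")
def bundle():
    """Default toy reference: 12 loci, one minus-strand, one decoy,
    one blacklisted SNP site."""
    return iso.make_reference(iso.default_config(), seed=11)


@pytest.fixture(scope="session")
def index(bundle):
    return iso.GenomeIndex(bundle.genome, bundle.loci)


@pytest.fixture(scope="session")
def small_run():
    """A small but complete three-cohort run shared across tests."""
    data = iso.simulate_cohorts(iso.small_config(n_pairs=6, n_reads=4000), seed=3)
    result = pl.run_pipeline(data, min_sample_reads=500)
    return data, result
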