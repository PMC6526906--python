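"""Shared fixtures: simulated genomes and the discovery/assembly products
built from them.  Session scope keeps the heavier simulations to one run."""

import pytest

from drivefam.simulate import FamilyParams, MatePairParams
from drivefam.workflow import assemble_one_locus, discovery_chain

SEED = 1

__all__ = ["discovery_chain", "assemble_one_locus"]


@pytest.fixture(scope="session")
def six_locus_run():
    """Six loci covering gene counts 0-3 at 80x mate-pair coverage."""
    fam = FamilyParams(n_loci=6, locus_gene_counts=[0, 1, 2, 3, 1, 2],
                       seed=SEED)
    return discovery_chain(fam, MatePairParams(coverage=80), SEED + 1)


@pytest.fixture(scope="session")
def assembled_locus_errorfree():
    return assemble_one_locus(0.0)


@pytest.fixture(scope="session")
def assembled_locus_err002():
    return assemble_one_locus(0.002)
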