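import numpy as np
import pandas as pd
import pytest

from clonesoma import simulate
from clonesoma.discovery import VariantObservation


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(
        genome_length=100_000,
        n_chroms=2,
        n_genes=6,
        n_donors=2,
        ages=(25, 70),
        clones_per_donor=2,
        n_germline_het=40,
        n_culture_mutations=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def reference(sim_config):
    return simulate.simulate_reference(sim_config)


@pytest.fixture(scope="session")
def cohort(sim_config, reference):
    _, clones, truths, metadata = simulate.simulate_cohort(sim_config, reference)
    return clones, truths, metadata


def make_obs(chrom="chr1", pos=100, ref="A", alt="T", alt_fwd=5, alt_rev=5,
             clone_depth=20, blood_alt=0, blood_depth=30,
             callers=frozenset({"haplotypecaller"}), individual="D1", clone="D1_c1"):
    return VariantObservation(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        clone_alt_fwd=alt_fwd, clone_alt_rev=alt_rev, clone_depth=clone_depth,
        blood_alt=blood_alt, blood_depth=blood_depth,
        callers=callers, individual=individual, clone=clone)


@pytest.fixture
def obs_factory():
    return make_obs
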