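"""Shared fixtures: one default-scale simulated population reused across tests.

The default study design is 184 RILs, nine chromosomes at 1/100 physical
scale, 1.2 SNPs/kb, F10 selfing and 2x mean depth.  Simulating it once per
session keeps the suite fast while letting every stage be tested on the same
realistic dataset.
"""

from __future__ import annotations

import numpy as np
import pytest

import binmapper as bm
from binmapper.binmap import build_bins
from binmapper.genotyping import call_population, detect_population_breakpoints


@pytest.fixture(scope="session")
def sim_config():
    return bm.SimConfig(seed=1)


@pytest.fixture(scope="session")
def parents(sim_config):
    snps, seqs = bm.simulate_parents(sim_config, with_sequences=False)
    return snps


@pytest.fixture(scope="session")
def truth(sim_config):
    return bm.simulate_ril_population(sim_config)


@pytest.fixture(scope="session")
def observations(sim_config, truth, parents):
    return bm.simulate_observations(truth, parents, sim_config)


@pytest.fixture(scope="session")
def tracks(observations, parents):
    calls, _ = call_population(observations, parents)
    return calls


@pytest.fixture(scope="session")
def breakpoints(tracks, parents):
    return detect_population_breakpoints(tracks, parents)


@pytest.fixture(scope="session")
def binset(breakpoints, tracks, parents, truth):
    return build_bins(breakpoints, tracks, parents, truth.chrom_lengths)


@pytest.fixture(scope="session")
def truth_binset(truth):
    from binmapper.binmap import bins_from_segments

    return bins_from_segments(truth)


@pytest.fixture(scope="session")
def random_donor():
    rng = np.random.default_rng(77)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {"chr1": bases[rng.integers(0, 4, 300_000)].tobytes().decode()}
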