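"""Shared fixtures: one full-scale simulated study, reused across tests."""

from __future__ import annotations

import pytest

from pirnaterm import annotation_io as aio
from pirnaterm import cleavage_fragments as cf
from pirnaterm import precursor_quant as pq
from pirnaterm import synthetic_data as sd

SIM_SEED = 1


@pytest.fixture(scope="session")
def config():
    return sd.SimulationConfig(seed=SIM_SEED)


@pytest.fixture(scope="session")
def sim(config):
    """(genome, loci) under the default wild-type study conditions."""
    return sd.simulate_loci(config)


@pytest.fixture(scope="session")
def genome(sim):
    return sim[0]


@pytest.fixture(scope="session")
def loci(sim):
    return sim[1]


@pytest.fixture(scope="session")
def wt_chromatin_records(config, loci):
    reads = sd.simulate_capped_reads(loci, config, "wild_type", "chromatin")
    return pq.identify_precursors(reads, loci, sample_id="wt_chromatin", compartment="chromatin")


@pytest.fixture(scope="session")
def wt_nucleoplasm_records(config, loci):
    reads = sd.simulate_capped_reads(loci, config, "wild_type", "nucleoplasm")
    return pq.identify_precursors(reads, loci, sample_id="wt_nucleoplasm", compartment="nucleoplasm")


@pytest.fixture(scope="session")
def fivep_pipeline(config, sim):
    """The full 5'P filter cascade on a wild-type library."""
    genome, loci = sim
    reads = sd.simulate_5p_reads(loci, config, "wild_type")
    filtered = cf.remove_mature_reads(reads, loci)
    sites = cf.detect_unannotated_21u(filtered, loci, genome)
    filtered = cf.remove_unannotated_mature(filtered, sites)
    fragments = cf.collect_fragments(filtered, loci)
    return {
        "raw": reads,
        "filtered": filtered,
        "sites": sites,
        "fragments": fragments,
        "normalizer": sum(r.count for r in reads),
    }


@pytest.fixture
def tiny_locus_plus():
    return aio.PiRNALocus("p1", "chrIV", "+", 1000)


@pytest.fixture
def tiny_locus_minus():
    return aio.PiRNALocus("p2", "chrIV", "-", 1020)
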