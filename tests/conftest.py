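import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile(
    "suite", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

_BASES = np.frombuffer(b"ACGT", np.uint8)


def random_seq(rng, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


@pytest.fixture(scope="session")
def toy():
    """The contained-read worked example (12 accurate + 7 ultra-long reads)."""
    from dgasm.examples import contained_read_example
    return contained_read_example(seed=0)


@pytest.fixture(scope="session")
def toy_graphs(toy):
    """Toy overlaps, graphs and UL alignments shared across tests."""
    from dgasm import hifi_graph, ul_align
    from dgasm.overlap import classify_contained, find_overlaps

    ovs = find_overlaps(toy.reads, toy.overlap_params)
    contained, containers = classify_contained(ovs)
    g_keep = hifi_graph.build_string_graph(toy.reads, ovs, keep_contained=True)
    hifi_graph.transitive_reduction(g_keep)
    g_drop = hifi_graph.build_string_graph(toy.reads, ovs, keep_contained=False)
    hifi_graph.transitive_reduction(g_drop)
    aligns, unaligned = ul_align.align_ul(toy.ul_reads, g_keep, toy.align_params)
    return {
        "overlaps": ovs, "contained": contained, "containers": containers,
        "keep": g_keep, "drop": g_drop,
        "alignments": aligns, "unaligned": unaligned,
    }


@pytest.fixture(scope="session")
def incorporation():
    from dgasm.examples import incorporation_example
    return incorporation_example(seed=0)


@pytest.fixture(scope="session")
def small_diploid():
    """A small repeat-free diploid simulation used by several modules."""
    from dgasm.simulate import (SimGenomeSpec, SimReadSpec, records,
                                simulate_genome, simulate_reads)
    genome = simulate_genome(SimGenomeSpec(
        ploidy=2, chrom_lengths=[60_000], het_rate=0.005, seed=101))
    hifi = simulate_reads(genome, SimReadSpec(
        "accurate", 8_000, 2_000, 3_000, 12.0, seed=102))
    ul = simulate_reads(genome, SimReadSpec(
        "ultralong", 35_000, 6_000, 20_000, 10.0, seed=103))
    return {"genome": genome, "hifi": hifi, "ul": ul,
            "hifi_records": records(hifi), "ul_records": records(ul)}
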