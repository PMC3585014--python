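import numpy as np
import pytest

from mnasefrag import simulate as sim
from mnasefrag.io import Fragment, FragmentSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_fragments(triples, chrom_lengths=None, role="input"):
    return FragmentSet(
        [Fragment(c, s, e) for c, s, e in triples], dict(chrom_lengths or {}), role=role
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """A moderately sized simulated experiment shared across tests:
    genome, chromatin state, digestion, calibrated enrichment, and
    matched IP/input fragment sets."""
    spec = sim.demo_genome_spec(chrom_length=200_000, n_tfbs=8, n_orfs=40, seed=11)
    genome = sim.build_genome(spec, 11)
    state = sim.place_chromatin(genome, 165, 90, 11)
    digestion = sim.DigestionModel(extent=5.0)
    enrichment = sim.design_enrichment(state, digestion, 2.5)
    ip = sim.emit_fragments(state, digestion, enrichment, 60_000, "IP", 11,
                            genome.chrom_lengths)
    inp = sim.emit_fragments(state, digestion, enrichment, 60_000, "input", 11,
                             genome.chrom_lengths)
    return {
        "genome": genome,
        "state": state,
        "digestion": digestion,
        "enrichment": enrichment,
        "ip": ip,
        "input": inp,
    }
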